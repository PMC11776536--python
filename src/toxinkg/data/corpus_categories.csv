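use_category,count
hair dye,62
preservative/disinfectant,9
UV filter,5
fragrance,2
solvent,2
multiple,4
other,4
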