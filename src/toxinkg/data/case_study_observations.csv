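compound_id,parameter,direction,qualifiers,source
basic-red-51,hepatic necrosis,increase,,histopathology
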