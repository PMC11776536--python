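compound_id,ingredient_name,function,use_category,inci_name,cas_number,ec_number,smiles,is_polymer,is_placeholder
5-amino-6-chloro-o-cresol,5-Amino-6-chloro-o-cresol,Precursor for hair dyeing products,hair dye,,,,,false,false
acetylated-vetiver-oil-avo-vetiveryl-acetate,Acetylated vetiver oil - AVO = vetiveryl acetate,Fragrance,fragrance,,,,,false,false
basic-brown-17,Basic Brown 17,Direct dye,hair dye,,,,,false,false
basic-red-51,Basic Red 51,Hair dye,hair dye,,,,,false,false
basic-violet-2,Basic violet 2,Hair coloring agent,hair dye,,,,,false,false
bis-butylbenzoate-diaminotriazine-aminopropyltrisiloxane,Bis(butylbenzoate) diaminotriazine aminopropyltrisiloxane,UV filter,UV filter,,,,,false,false
butylphenyl-methylpropional,Butylphenyl methylpropional,Fragrance,fragrance,,,,,false,false
cetylpyridinium-chloride,Cetylpyridinium chloride,Desinfectant,preservative/disinfectant,,,,,false,false
decamethylcyclopentasiloxane-cyclopentasiloxane-d5,"Decamethylcyclopentasiloxane (cyclopentasiloxane, D5)","Antistatic, emollient, humectant, solvent, viscosity controlling, and hair conditioning",multiple,,,,,false,false
ecog,ecoG+,"Preservative, packaging",preservative/disinfectant,,,,,false,false
hc-blue-no-15,HC blue No. 15,Dye,hair dye,,,,,false,false
hc-yellow-no-13,HC yellow No. 13,Hair coloring agent,hair dye,,,,,false,false
hydroxyethyl-2-nitro-p-toluidine,Hydroxyethyl-2-nitro-p-toluidine,Direct dye,hair dye,,,,,false,false
hydroxyethyl-3-4-methylenedioxyaniline-hcl,"Hydroxyethyl-3,4-methylenedioxyaniline HCl",Oxidative hair dye,hair dye,,,,,false,false
hydroxyethyl-p-phenylenediamine-sulfate,Hydroxyethyl-p-phenylenediamine sulfate,Oxidative hair coloring agent,hair dye,,,,,false,false
hydroxypropyl-p-phenylenediamine-and-its-dihydrochloride-salt-a165,Hydroxypropyl p-phenylenediamine and its dihydrochloride salt (A165),Oxidative agent,hair dye,,,,,false,false
methylimidazoliumpropyl-p-phenylenediamine-hcl-a166,Methylimidazoliumpropyl p-phenylenediamine HCl (A166),Oxidative agent,hair dye,,,,,false,false
n-n-bis-2-hydroxyethyl-2-nitro-p-phenylenediamine,"N,N'-Bis-(2-hydroxyethyl)-2-nitro-p-phenylenediamine",Hair dye,hair dye,,,,,false,false
n-methyl-2-pyrrolidone,N-Methyl-2-pyrrolidone,Solvent and surfactant,solvent,,,,,false,false
o-aminophenol,o-Aminophenol,Oxidative agent,hair dye,,,,,false,false
phenoxyethanol,Phenoxyethanol,Preservative,preservative/disinfectant,,,,,false,false
toluene-2-5-diamine-and-its-sulfate-colipa-no-a5,"Toluene-2,5-diamine and its sulfate (COLIPA No. A5)",Oxidative hair coloring agent,hair dye,,,,,false,false
1-hexyl-4-5-diamino-pyrazole-sulfate,"1-Hexyl 4,5-diamino pyrazole sulfate",Oxidative hair coloring agent,hair dye,,,,,false,false
2-6-dihydroxyethylaminotoluene,"2,6-Dihydroxyethylaminotoluene",Precursor for hair colors,hair dye,,,,,false,false
2-7-naphthalenediol,"2,7-Naphthalenediol",Hair dye formulation,hair dye,,,,,false,false
citric-acid-and-silver-citrate,Citric acid (and) silver citrate,Preservative,preservative/disinfectant,,,,,false,false
diethylene-glycol-monoethyl-ether,Diethylene glycol monoethyl ether,Solvent,solvent,,,,,false,false
methoxypropylamino-cyclohexenylidene-ethoxyethylcyanoacetate-s87,Methoxypropylamino cyclohexenylidene ethoxyethylcyanoacetate (S87),UV filter,UV filter,,,,,false,false
triclosan,Triclosan,Antibacterial,preservative/disinfectant,,,,,false,false
disperse-black-9,Disperse black 9,Coloring agent,hair dye,,,,,false,false
hc-red-no-13,HC red No.13,Direct dye,hair dye,,,,,false,false
disperse-blue-377,Disperse blue 377,Hair dye,hair dye,,,,,false,false
polysilicone-15,Polysilicone-15,UV filter,UV filter,,,,,false,false
o-phenylphenol-sodium-o-phenylphenate-and-potassium-o-phenylphenate,"o-Phenylphenol, sodium o-phenylphenate, and potassium o-phenylphenate",Preservative,preservative/disinfectant,,,,,false,false
basic-yellow-57,Basic yellow 57,Direct dye,hair dye,,,,,false,false
hc-red-no-7,HC red No. 7,Hair dye,hair dye,,,,,false,false
2-hydroxyethylamino-5-nitroanisole,2-Hydroxyethylamino-5-nitroanisole,Semi-permanent hair dye,hair dye,,,,,false,false
acid-orange-7,Acid orange 7,Direct dye,hair dye,,,,,false,false
basic-red-76,Basic red 76,Direct dye,hair dye,,,,,false,false
1-2-4-trihydroxybenzene,"1,2,4-Trihydroxybenzene",Coloring agent,hair dye,,,,,false,false
basic-yellow-87,Basic yellow 87,Dye,hair dye,,,,,false,false
2-6-diamino-3-pyridin-3-yl-azo-pyridine,"2,6-Diamino-3-((pyridin-3-yl)azo)pyridine",Direct dye,hair dye,,,,,false,false
2-amino-4-hydroxyethylaminoanisole-sulfate,2-Amino-4-hydroxyethylaminoanisole sulfate,Oxidative hair dye,hair dye,,,,,false,false
2-amino-5-ethylphenol-hcl,2-Amino-5-ethylphenol HCl,Oxidative hair coloring agent precursor,hair dye,,,,,false,false
hc-yellow-no-9,HC yellow No. 9,Hair coloring,hair dye,,,,,false,false
vitamin-a,Vitamin a,Antiwrinkle,other,,,,,false,false
zinc-pyrithione,Zinc pyrithione,Preservative,preservative/disinfectant,,,,,false,false
hc-orange-no-6,HC orange No. 6,Hair colorign agent,hair dye,,,,,false,false
basic-orange-31,Basic orange 31,Hair dye,hair dye,,,,,false,false
acid-red-92,Acid red 92,Direct dye,hair dye,,,,,false,false
disperse-violet-1,Disperse violet 1,Coloring agent,hair dye,,,,,false,false
acid-black-1,Acid black 1,Coloring agent,hair dye,,,,,false,false
hc-blue-no-14,HC blue No. 14,Coloring agent,hair dye,,,,,false,false
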