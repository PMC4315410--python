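name,molecular_weight,pka_values,ionization_class,fa_percent,water_solubility_mg_per_L
Amoxicillin,419.46,2.6;7.31;9.53,ampholyte,93,3430
Atenolol,266.39,9.54,base,54,13300
Chloramphenicol,323.13,4.3,acid,90,2500
Cimetidine,252.34,7.23,base,85,9380
Famotidine,337.45,7.24;11.19,base,40,1000
Ibuprofen,206.28,4.59,acid,95,21
Metformin,165.63,12.4,base,55,
Metoprolol,682.82,9.56,base,95,16900
Norfloxacin,319.34,6.26;8.63,ampholyte,35,178000
Ranitidine,314.37,8.2,base,55,24.7
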