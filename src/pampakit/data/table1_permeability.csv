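name,lipid,pe_cm_per_s,sd_cm_per_s
Amoxicillin,C8,4.6e-6,0.4e-6
Amoxicillin,C10,5.3e-6,0.3e-6
Amoxicillin,C12,5.7e-6,0.4e-6
Atenolol,C8,3.8e-6,0.4e-6
Atenolol,C10,5.2e-6,0.4e-6
Atenolol,C12,5.9e-6,0.5e-6
Chloramphenicol,C8,8.8e-6,0.2e-6
Chloramphenicol,C10,9.8e-6,0.3e-6
Chloramphenicol,C12,14.6e-6,0.3e-6
Cimetidine,C8,2.6e-6,0.4e-6
Cimetidine,C10,2.8e-6,0.3e-6
Cimetidine,C12,3.2e-6,0.3e-6
Famotidine,C8,2.7e-6,0.3e-6
Famotidine,C10,2.8e-6,0.2e-6
Famotidine,C12,3.2e-6,0.4e-6
Ibuprofen,C8,13.9e-6,0.5e-6
Ibuprofen,C10,14.5e-6,0.5e-6
Ibuprofen,C12,16.7e-6,0.4e-6
Metformin,C8,2.4e-6,0.4e-6
Metformin,C10,2.9e-6,0.3e-6
Metformin,C12,3.4e-6,0.2e-6
Metoprolol,C8,9.2e-6,0.6e-6
Metoprolol,C10,10.3e-6,0.5e-6
Metoprolol,C12,11.7e-6,0.5e-6
Norfloxacin,C8,0.9e-6,0.1e-6
Norfloxacin,C10,1.0e-6,0.1e-6
Norfloxacin,C12,1.0e-6,0.1e-6
Ranitidine,C8,1.2e-6,0.1e-6
Ranitidine,C10,1.4e-6,0.1e-6
Ranitidine,C12,1.5e-6,0.1e-6
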