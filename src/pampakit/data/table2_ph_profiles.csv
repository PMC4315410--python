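name,lipid,ph,pe_cm_per_s,sd_cm_per_s
Amoxicillin,C8,4.6,1.9e-7,0.2e-7
Amoxicillin,C10,4.6,1.9e-7,0.2e-7
Amoxicillin,C12,4.6,1.9e-7,0.2e-7
Amoxicillin,C8,4.98,2.1e-7,0.2e-7
Amoxicillin,C10,4.98,2.1e-7,0.1e-7
Amoxicillin,C12,4.98,2.1e-7,0.1e-7
Amoxicillin,C8,6.57,2.6e-7,0.2e-7
Amoxicillin,C10,6.57,2.5e-7,0.2e-7
Amoxicillin,C12,6.57,2.6e-7,0.2e-7
Amoxicillin,C8,8.2,2.4e-7,0.2e-7
Amoxicillin,C10,8.2,2.3e-7,0.2e-7
Amoxicillin,C12,8.2,2.3e-7,0.2e-7
Amoxicillin,C8,9.32,2.2e-7,0.2e-7
Amoxicillin,C10,9.32,2.2e-7,0.2e-7
Amoxicillin,C12,9.32,2.0e-7,0.2e-7
Atenolol,C8,4.98,2.5e-6,0.4e-6
Atenolol,C10,4.98,1.7e-6,0.1e-6
Atenolol,C12,4.98,1.5e-6,0.1e-6
Atenolol,C8,6.57,3.0e-6,0.5e-6
Atenolol,C10,6.57,3.2e-6,0.2e-6
Atenolol,C12,6.57,3.3e-6,0.4e-6
Atenolol,C8,8.2,3.8e-6,0.4e-6
Atenolol,C10,8.2,3.5e-6,0.4e-6
Atenolol,C12,8.2,3.5e-6,0.2e-6
Atenolol,C8,9.32,4.4e-6,0.1e-6
Atenolol,C10,9.32,4.4e-6,0.3e-6
Atenolol,C12,9.32,4.4e-6,0.5e-6
Chloramphenicol,C8,4.6,4.3e-6,0.4e-6
Chloramphenicol,C10,4.6,4.2e-6,0.5e-6
Chloramphenicol,C12,4.6,4.4e-6,0.4e-6
Chloramphenicol,C8,4.98,4.2e-6,0.5e-6
Chloramphenicol,C10,4.98,4.0e-6,0.3e-6
Chloramphenicol,C12,4.98,4.2e-6,0.6e-6
Chloramphenicol,C8,6.57,1.7e-6,0.4e-6
Chloramphenicol,C10,6.57,1.0e-6,0.2e-6
Chloramphenicol,C12,6.57,1.5e-6,0.4e-6
Chloramphenicol,C8,8.2,0.6e-6,0.1e-6
Chloramphenicol,C10,8.2,0.7e-6,0.1e-6
Chloramphenicol,C12,8.2,0.7e-6,0.1e-6
Chloramphenicol,C8,9.32,0.5e-6,0.1e-6
Chloramphenicol,C10,9.32,0.5e-6,0.1e-6
Chloramphenicol,C12,9.32,0.5e-6,0.1e-6
Cimetidine,C8,4.6,1.8e-6,0.3e-6
Cimetidine,C10,4.6,1.8e-6,0.3e-6
Cimetidine,C12,4.6,1.8e-6,0.4e-6
Cimetidine,C8,4.98,1.6e-6,0.2e-6
Cimetidine,C10,4.98,1.9e-6,0.1e-6
Cimetidine,C12,4.98,1.9e-6,0.3e-6
Cimetidine,C8,6.57,2.6e-6,0.1e-6
Cimetidine,C10,6.57,2.6e-6,0.2e-6
Cimetidine,C12,6.57,2.7e-6,0.2e-6
Cimetidine,C8,8.2,3.2e-6,0.2e-6
Cimetidine,C10,8.2,3.1e-6,0.3e-6
Cimetidine,C12,8.2,3.2e-6,0.2e-6
Cimetidine,C8,9.32,3.7e-6,0.2e-6
Cimetidine,C10,9.32,3.4e-6,0.3e-6
Cimetidine,C12,9.32,3.4e-6,0.1e-6
Famotidine,C8,4.6,1.1e-6,0.2e-6
Famotidine,C10,4.6,1.2e-6,0.2e-6
Famotidine,C12,4.6,1.2e-6,0.2e-6
Famotidine,C8,4.98,2.2e-6,0.1e-6
Famotidine,C10,4.98,2.2e-6,0.1e-6
Famotidine,C12,4.98,1.2e-6,0.1e-6
Famotidine,C8,6.57,5.0e-6,0.4e-6
Famotidine,C10,6.57,5.7e-6,0.4e-6
Famotidine,C12,6.57,6.0e-6,0.1e-6
Famotidine,C8,9.32,5.1e-6,0.2e-6
Famotidine,C10,9.32,5.5e-6,0.1e-6
Famotidine,C12,9.32,6.1e-6,0.2e-6
Ibuprofen,C8,4.6,23.0e-6,1.5e-6
Ibuprofen,C10,4.6,23.0e-6,1.0e-6
Ibuprofen,C12,4.6,22.5e-6,2.0e-6
Ibuprofen,C8,4.98,23.5e-6,2.0e-6
Ibuprofen,C10,4.98,22.0e-6,2.0e-6
Ibuprofen,C12,4.98,23.0e-6,2.5e-6
Ibuprofen,C8,6.57,8.5e-6,0.2e-6
Ibuprofen,C10,6.57,7.0e-6,0.1e-6
Ibuprofen,C12,6.57,7.5e-6,0.2e-6
Ibuprofen,C8,8.2,3.0e-6,0.1e-6
Ibuprofen,C10,8.2,1.5e-6,0.1e-6
Ibuprofen,C12,8.2,1.5e-6,0.1e-6
Ibuprofen,C8,9.32,2.6e-6,0.1e-6
Ibuprofen,C10,9.32,2.6e-6,0.1e-6
Ibuprofen,C12,9.32,2.6e-6,0.1e-6
Metformin,C8,4.6,1.5e-7,0.1e-7
Metformin,C10,4.6,1.5e-7,0.2e-7
Metformin,C12,4.6,1.6e-7,0.2e-7
Metformin,C8,4.98,1.6e-7,0.1e-7
Metformin,C10,4.98,1.6e-7,0.1e-7
Metformin,C12,4.98,1.7e-7,0.2e-7
Metformin,C8,6.57,3.2e-7,0.1e-7
Metformin,C10,6.57,3.2e-7,0.2e-7
Metformin,C12,6.57,3.1e-7,0.1e-7
Metformin,C8,8.2,4.9e-7,0.1e-7
Metformin,C10,8.2,5.8e-7,0.2e-7
Metformin,C12,8.2,4.9e-7,0.1e-7
Metformin,C8,9.32,7.4e-7,0.1e-7
Metformin,C10,9.32,7.2e-7,0.2e-7
Metformin,C12,9.32,7.3e-7,0.1e-7
Metoprolol,C8,4.6,1.5e-5,0.1e-5
Metoprolol,C10,4.6,1.4e-5,0.2e-5
Metoprolol,C12,4.6,1.6e-5,0.2e-5
Metoprolol,C8,4.98,2.7e-5,0.2e-5
Metoprolol,C10,4.98,2.5e-5,0.2e-5
Metoprolol,C12,4.98,2.6e-5,0.2e-5
Metoprolol,C8,6.57,5.1e-5,0.3e-5
Metoprolol,C10,6.57,5.3e-5,0.3e-5
Metoprolol,C12,6.57,5.0e-5,0.2e-5
Metoprolol,C8,8.2,8.0e-5,0.1e-5
Metoprolol,C10,8.2,7.5e-5,0.3e-5
Metoprolol,C12,8.2,8.0e-5,0.4e-5
Metoprolol,C8,9.32,8.9e-5,0.2e-5
Metoprolol,C10,9.32,9.3e-5,0.3e-5
Metoprolol,C12,9.32,9.1e-5,0.3e-5
Norfloxacin,C8,4.6,1.9e-6,0.0e-6
Norfloxacin,C10,4.6,1.9e-6,0.1e-6
Norfloxacin,C12,4.6,1.8e-6,0.1e-6
Norfloxacin,C8,4.98,2.3e-6,0.1e-6
Norfloxacin,C10,4.98,2.2e-6,0.1e-6
Norfloxacin,C12,4.98,2.2e-6,0.1e-6
Norfloxacin,C8,6.57,2.6e-6,0.0e-6
Norfloxacin,C10,6.57,2.5e-6,0.1e-6
Norfloxacin,C12,6.57,2.6e-6,0.0e-6
Norfloxacin,C8,8.2,2.5e-6,0.1e-6
Norfloxacin,C10,8.2,2.5e-6,0.1e-6
Norfloxacin,C12,8.2,2.6e-6,0.1e-6
Norfloxacin,C8,9.32,2.2e-6,0.1e-6
Norfloxacin,C10,9.32,2.3e-6,0.1e-6
Norfloxacin,C12,9.32,2.2e-6,0.1e-6
Ranitidine,C8,4.6,1.6e-7,0.1e-7
Ranitidine,C10,4.6,1.6e-7,0.3e-7
Ranitidine,C12,4.6,1.6e-7,0.2e-7
Ranitidine,C8,4.98,1.8e-7,0.2e-7
Ranitidine,C10,4.98,1.8e-7,0.2e-7
Ranitidine,C12,4.98,1.8e-7,0.2e-7
Ranitidine,C8,6.57,3.2e-7,0.1e-7
Ranitidine,C10,6.57,3.1e-7,0.1e-7
Ranitidine,C12,6.57,3.2e-7,0.2e-7
Ranitidine,C8,8.2,4.9e-7,0.1e-7
Ranitidine,C10,8.2,5.8e-7,0.7e-7
Ranitidine,C12,8.2,4.9e-7,0.2e-7
Ranitidine,C8,9.32,5.5e-7,0.2e-7
Ranitidine,C10,9.32,5.5e-7,0.3e-7
Ranitidine,C12,9.32,5.4e-7,0.4e-7
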