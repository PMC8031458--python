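{
 "T_fus_K": 412.95,
 "dH_fus_kJ_mol": 28.38,
 "dCp_J_mol_K": 68.72
}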