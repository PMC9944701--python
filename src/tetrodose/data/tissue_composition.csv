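tissue,f_extracellular_water,f_intracellular_water,f_neutral_lipid,f_neutral_phospholipid,acidic_phospholipid_mg_g
adipose,0.135,0.017,0.790,0.0016,0.40
muscle,0.118,0.630,0.0100,0.0072,1.53
gi,0.282,0.475,0.0380,0.0125,2.41
spleen,0.207,0.579,0.0077,0.0136,3.18
pancreas,0.120,0.664,0.0403,0.0090,0.405
plasma,0.945,0.0,0.0035,0.00225,0.0
blood_cells,0.0,0.603,0.0017,0.0029,0.5
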