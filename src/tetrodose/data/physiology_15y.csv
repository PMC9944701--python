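organ,volume_L,flow_L_per_min
body_weight,56.0,
arterial_blood,0.87,
venous_blood,3.17,
lung,0.35,5.4
heart_vascular,0.035,0.216
heart_extravascular,0.195,
heart_chambers,0.31,
brain_vascular,0.068,0.81
muscle,24.0,0.81
liver,1.30,1.35
hepatic_artery,,0.324
gallbladder,0.040,
gi,0.90,0.81
spleen,0.130,0.162
pancreas,0.110,0.054
kidney_vascular,0.050,1.026
kidney_extravascular,0.200,
adipose,11.5,0.27
thyroid,0.012,0.081
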