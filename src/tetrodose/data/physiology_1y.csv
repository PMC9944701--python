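organ,volume_L,flow_L_per_min
body_weight,10.0,
arterial_blood,0.079,
venous_blood,0.285,
lung,0.068,1.5
heart_vascular,0.0075,0.0675
heart_extravascular,0.0425,
heart_chambers,0.068,
brain_vascular,0.046,0.45
muscle,1.9,0.12
liver,0.33,0.375
hepatic_artery,,0.075
gallbladder,0.010,
gi,0.22,0.24
spleen,0.029,0.045
pancreas,0.020,0.015
kidney_vascular,0.0144,0.255
kidney_extravascular,0.0576,
adipose,3.7,0.075
thyroid,0.0018,0.0195
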