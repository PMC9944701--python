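organ,volume_L,flow_L_per_min
body_weight,32.0,
arterial_blood,0.45,
venous_blood,1.64,
lung,0.21,3.5
heart_vascular,0.021,0.14
heart_extravascular,0.119,
heart_chambers,0.19,
brain_vascular,0.065,0.70
muscle,11.0,0.42
liver,0.83,0.875
hepatic_artery,,0.21
gallbladder,0.030,
gi,0.55,0.525
spleen,0.090,0.105
pancreas,0.060,0.035
kidney_vascular,0.036,0.63
kidney_extravascular,0.144,
adipose,8.0,0.175
thyroid,0.0079,0.049
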