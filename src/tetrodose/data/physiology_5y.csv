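organ,volume_L,flow_L_per_min
body_weight,19.0,
arterial_blood,0.26,
venous_blood,0.93,
lung,0.125,2.4
heart_vascular,0.013,0.108
heart_extravascular,0.072,
heart_chambers,0.115,
brain_vascular,0.060,0.60
muscle,5.6,0.24
liver,0.57,0.60
hepatic_artery,,0.132
gallbladder,0.020,
gi,0.37,0.372
spleen,0.055,0.072
pancreas,0.035,0.024
kidney_vascular,0.022,0.432
kidney_extravascular,0.088,
adipose,5.3,0.12
thyroid,0.0034,0.0312
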