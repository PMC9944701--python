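organ,volume_L,flow_L_per_min
body_weight,73.0,
arterial_blood,1.00,
venous_blood,3.67,
lung,0.50,6.5
heart_vascular,0.050,0.26
heart_extravascular,0.28,
heart_chambers,0.45,
brain_vascular,0.070,0.78
muscle,29.0,1.105
liver,1.80,1.6575
hepatic_artery,,0.4225
gallbladder,0.050,
gi,1.20,0.975
spleen,0.150,0.195
pancreas,0.140,0.065
kidney_vascular,0.062,1.235
kidney_extravascular,0.248,
adipose,14.0,0.325
thyroid,0.020,0.0975
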