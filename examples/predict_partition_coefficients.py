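"""Predict tissue:plasma partition coefficients mechanistically.

For the tissues without usable imaging data (muscle, adipose, GI,
spleen, pancreas) the model's Kp inputs are predicted from the drug's
physicochemistry (logP 1.14, pKa 8.3, fu 0.7353, blood:plasma ratio
0.8, monoprotic base) and fractional tissue composition.  A Kp of 1.28
for pancreas means that at distribution equilibrium the pancreas
concentration is 1.28 times the plasma concentration.
"""

from tetrodose import load_drug_params, load_tissue_composition, rodgers_rowland_kp

drug = load_drug_params()
comp = load_tissue_composition()
print(f"compound: {drug.name} (logP {drug.logp}, pKa {drug.pka}, "
      f"fu {drug.fu}, B:P {drug.blood_plasma_ratio})")
for tissue in ("muscle", "adipose", "gi", "spleen", "pancreas"):
    kp = rodgers_rowland_kp(drug, comp, tissue)
    print(f"  Kp {tissue:<9s} = {kp:.3f}")
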