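"""Run the full paediatric dosimetry chain and derive activity limits.

For each age the tetrofosmin kinetics are decayed with the Tc99m
half-life (6.02 h), the bladder is voided every 3 h and the GI contents
emptied every 24 h, residence times are integrated per source region,
and absorbed doses are combined into the ICRP-103 effective dose E
(mSv per MBq administered).  The maximum administered activity is the
amount that gives a child the same effective dose as 1200 MBq gives an
adult; between the tabulated ages it is interpolated linearly.

The bundled S-value tables are synthetic (an absorbed-fraction
approximation), so the absolute doses are indicative, not reference
values.
"""

from tetrodose import interpolate_max_activity, reference_dose_reports

reports = reference_dose_reports()
print(f"{'age':>6s} {'E (mSv/MBq)':>12s} {'ratio':>6s} {'max activity (MBq)':>19s}")
e_adult = reports["adult"].effective_dose_msv_per_mbq
for age in ("adult", "15y", "10y", "5y", "1y"):
    rep = reports[age]
    e = rep.effective_dose_msv_per_mbq
    print(f"{age:>6s} {e:>12.4f} {e / e_adult:>6.2f} {rep.max_activity_mbq:>19.0f}")

anchors = {1: reports["1y"].max_activity_mbq, 5: reports["5y"].max_activity_mbq,
           10: reports["10y"].max_activity_mbq,
           15: reports["15y"].max_activity_mbq,
           18: reports["adult"].max_activity_mbq}
print(f"\ninterpolated limit for a 7.5-year-old: "
      f"{interpolate_max_activity(7.5, anchors):.0f} MBq")
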