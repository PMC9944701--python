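# Methods

This note documents the model, the estimation machinery, the synthetic
data generators and the numerical choices in `tetrodose`, including the
places where the design was genuinely open and what the bundled
defaults do and do not represent.

## Kinetic model

The tracer is described by 19 linear, time-invariant mass-balance ODEs
over anatomically defined compartments, in units of *fraction of
administered dose* (imaging data report organ fractions, not
concentrations).  Time is in minutes throughout; flows and clearances
are in L/min.  Because every transfer moves an amount from exactly one
compartment to exactly one other (or to a cumulative sink — urine, GI
contents), the rate matrix has zero column sums and total mass is
conserved identically.

Structural choices:

* **Perfusion-limited tissues** (lung, muscle, adipose, thyroid, GI
  tissue, spleen, pancreas, lumped "other") are single well-stirred
  compartments.  Their venous outflow term is `Q·R·A/(Kp·V)` with the
  blood:plasma ratio `R = 0.8` appearing in the numerator; the lung
  (venous inflow, arterial outflow) and the vascular sub-compartments
  carry no `R`.  These rate expressions are implemented exactly as the
  model was originally specified; PBPK conventions vary on where `R`
  sits, and no "correction" is applied.
* **Permeability-limited organs** (heart, kidney) have vascular and
  extravascular sub-compartments coupled by a permeability–surface
  product `PS` with driving force `R·A_ev/(Kp·V_ev) − A_v/V_v`.
* **Brain** is vascular-only: the tracer does not cross the blood–brain
  barrier (`PS_brain = 0`), so no extravascular brain state exists.
* **Hepatic system**: the liver receives the hepatic artery plus the
  venous outflow of GI tissue, spleen and pancreas; `CL_liver` excretes
  into the gallbladder, which empties into the GI contents with
  effective rate `K_gb/V_gb` (the printed formulation; `K_gb` is in
  min⁻¹ and the gallbladder volume enters the denominator).
* **Observables**: blood is the venous amount (the residual-error model
  is attached to venous blood); heart includes chamber blood,
  `V_chambers·(A_ven/V_ven + A_art/V_art)`; kidney is vascular +
  extravascular; GI is tissue + contents; urine is cumulative.
* **Closure**: `Q_other` is the cardiac output minus all named venous
  returns and `V_other` the body volume (body weight / 1.05 kg/L) minus
  all named volumes; both are recorded in metadata.

The bundled physiology tables (adult, 15, 10, 5, 1 years; body weights
73/56/32/19/10 kg) are compiled from standard reference-man and
reference-child anatomy and haemodynamics.  They satisfy both flow
balances exactly and can be overridden with a CSV of the same layout
for sensitivity work or to reproduce a specific source exactly.

### Drug parameters (defaults)

| parameter | value | unit | role |
|---|---|---|---|
| Kp lung/heart/kidney/liver/thyroid/other | 1.56 / 8.17 / 29.1 / 1.88 / 13.4 / 19.0 | – | fitted adult estimates |
| Kp muscle/adipose/GI/spleen/pancreas | 1.19 / 1.04 / 0.26 / 1.18 / 1.28 | – | mechanistic / reported inputs |
| PS heart / kidney | 0.016 / 0.247 | L/min | vascular–extravascular exchange |
| CL renal / liver | 0.156 / 0.0683 | L/min | urinary / biliary clearance |
| K_gb | 0.005 | min⁻¹ | gallbladder emptying |
| R | 0.8 | – | blood:plasma ratio |

The default set represents a fitted adult tetrofosmin analysis and is
the generating truth of the synthetic-data studies.

## Mechanistic Kp prediction

For tissues without usable imaging data, Kp is predicted with the
Rodgers–Rowland equations for moderate-to-strong monoprotic bases
(pKa 8.3 ≫ plasma pH): extracellular water, pH-partitioned
intracellular water (`pH_iw = 7.0`, `pH_p = 7.4`), neutral lipid and
phospholipid partitioning via `P = 10^logP`, plus electrostatic
association with acidic phospholipids whose affinity is back-calculated
from blood-cell partitioning (haematocrit 0.45, `pH_bc = 7.22`).  Two
documented choices:

* With `R = 0.8` and `fu = 0.7353` the implied blood-cell unbound
  partition (0.756) is *below* the water+lipid prediction, which would
  make the association constant negative; a binding constant cannot be
  negative, so it is clamped at zero.  The clamp is recorded in the
  function's documented behaviour and means the acidic-phospholipid
  term vanishes for this drug.
* Composition constants are a config choice (`TissueComposition`
  edition): the bundled table uses the method's standard rat-derived
  fractions, except adipose neutral lipid (0.79), which follows the
  human adipose composition commonly used by PBPK platforms.

The returned quantity is `Kpu·fu`, the tissue:plasma partition
coefficient, the scale on which the model's fixed Kp inputs are given.
The bundled GI value (0.26) is retained as a reported model input; the
mechanistic prediction for gut tissue is ≈1.1 under every variant of
the method we could construct, so the two should not be expected to
agree.

## Estimation

Two stages mirror standard practice for organ-level imaging data:

1. **Open loop.**  The venous blood series is fitted by a biexponential
   forcing function `C_ven(t) = c1·e^(−k1 t) + c2·e^(−k2 t)` (rates per
   hour by default; configurable and recorded).  Passing it through the
   lung equation yields the arterial input, which drives each organ
   sub-model in isolation; each tissue is fitted by proportional-error
   least squares, choosing perfusion vs permeability variants.  A
   profile-flatness diagnostic flags practically unidentifiable
   parameters (a parameter that can grow tenfold without degrading the
   fit), which is how the permeability variant signals collapse onto
   the perfusion limit.  One structural fact discovered here and
   honoured by the protocol: the liver amount depends on
   (Kp_liver, CL_liver) only through the total exit rate
   `Q_liver·R/Kp + CL`, a perfect ridge, so the open-loop liver step
   holds Kp_liver at its prior and calibrates CL_liver; the closed loop
   separates them through the blood feedback.
2. **Closed loop.**  All tissues are fitted simultaneously by maximum
   likelihood under `Y = F(1 + ε)`, `ε ~ N(0, σ_T²)`, a separate σ per
   tissue.  Gallbladder observations are excluded (erratic in this data
   class).  The per-tissue σ are profiled analytically
   (`σ̂_T² = mean(((Y−F)/F)²)`), so the search runs over the 11
   log-transformed structural parameters; the concentrated objective is
   algebraically identical to the full −2 log-likelihood at the
   profiled σ (property-tested).  Optimisation: L-BFGS-B from seeded
   multistarts (default first start at the supplied initial estimates)
   followed by a Nelder–Mead polish; candidates where the simulation
   fails are rejected and counted.  Parameters whose informing tissues
   are absent from the dataset are flagged non-identifiable and held at
   their initial values.

**Standard errors** come from the central-difference Hessian of the
profile −2LL on the natural parameter scale (covariance `2·H⁻¹`); a
non-positive-definite Hessian is reported and handled with a
pseudo-inverse.  **Goodness of fit** is the pooled coefficient of
determination over all tissues' observations.

The scan-midpoint lag (default 10 min, configurable) shifts every
nominal scan-start time to the middle of the acquisition window; a
guard prevents accidental double application.

## Paediatric scaling

Kp values are held constant across ages (for a drug with limited plasma
protein binding the Kp-constant and Kpu-constant conventions nearly
coincide; only the former is implemented).  `PS` scales with the total
organ-volume ratio to the power 2/3 (membrane surface ∝ volume^(2/3) at
constant permeability) and clearances to the power 3/4 (metabolic
allometry).  The total-organ-volume reading of the ratio was chosen
over a vascular-subvolume reading because the latter would tie
clearance scaling to compartments that are not defined for all organs
involved.  `K_gb` is a first-order rate constant, not a clearance, and
is left unscaled.

## Dosimetry chain

* **Decay**: `a_organ(t) = A_organ(t)·e^(−λt)` with
  `λ = ln 2 / 361.2 min⁻¹` derived from the 6.02 h Tc99m half-life; λ is
  a configurable argument so alternative conventions can be forced.
* **Emptying**: in the activity simulation the cumulative-urine state
  is reinterpreted as urinary-bladder contents and reset to zero every
  3 h; GI contents are reset every 24 h.  Voided activity leaves the
  system.  Between events the shifted linear system is propagated by
  exact matrix exponentials.
* **Residence times**: for λ > 0 each inter-event segment's
  time-integral is computed exactly as `A⁻¹(y_end − y_start)` (the
  shifted rate matrix is invertible); trapezoidal quadrature over the
  event-aware grid is the fallback and the brute-force oracle in tests.
  Beyond the 60 h horizon an analytic pure-decay tail `a(T)/λ` is
  added; a tail above 0.1 % of the integral raises a warning, and the
  total is checked against the 1/λ total-decay bound.
* **Source mapping**: model compartments map onto S-value source
  regions (configurable; splits with weights are supported and the
  total residence time is preserved).  By default blood, muscle,
  adipose and the lumped remainder pool into "rest of body".
* **Doses**: `H_T = Σ_S N_S·S(T←S)` and `E = Σ_T W_T·H_T` with ICRP-103
  weights (checked to sum to 1).  1 mGy is taken as 1 mSv (low-LET
  emissions).  The maximum administered activity is
  `1200·E_adult/E_child`, which makes `A_max·E` constant across ages by
  construction; age interpolation is piecewise linear between the
  anchor ages, with no extrapolation below 1 year.

## Synthetic data

`generate_dataset` simulates the closed-loop model, samples at the
design's offset times (5, 30, 60, 120, 240, 480, 1440 min + 48 h for
urine; 10-min lag) and multiplies by `(1 + ε)` with per-tissue
proportional SDs defaulting to the fitted adult residual errors
(blood 0.409 … lung 0.785, urine 0.045).  Draws that would be negative
are truncated at zero and the truncation count is recorded — at the
largest σ values roughly a tenth of lung observations are affected,
which slightly biases high-noise recovery studies.  All generators are
deterministic given a seed.

**Synthetic S-value tables.**  The bundled per-age S matrices are *not*
Monte-Carlo phantom results; they are a labelled synthetic stand-in
built from a simple absorbed-fraction model: per decay Tc99m emits
≈16.2 keV of non-penetrating radiation (absorbed locally) and
≈125 keV of 140 keV photons, of which a region of mass *m* self-absorbs
`φ(m) = min(0.35, 0.130·m^(1/3))` (a fit through phantom
self-absorbed fractions at 140 keV); all cross-irradiation is
approximated by the whole-body mean dose rate; targets contained in a
source region receive its uniform self dose; wall targets of content
regions (colon ← GI contents, bladder wall ← bladder contents) receive
half the interior dose.  This reproduces the right scale for the adult
effective dose but overstates the age-dependence: its self/wall terms
are electron-dominated for small organs and scale close to 1/m, whereas
phantom photon cross-fire flattens the true paediatric increase.
Absolute paediatric doses from the bundled tables should therefore be
read as indicative; measured S-value CSVs (`{target, source, svalue,
unit}`) can be supplied to the `dose` stage for reference-quality
results.  A separate toy fixture generator (random, self-dose-dominant,
mass-scaled) exists for property tests.

`recovery_experiment` runs generate → closed-loop refit → summarise
(relative bias, RMSE, 2-SE coverage) over seeded replicates, excluding
and counting failed fits.

## Numerical choices

* Simulation default is exact matrix-exponential propagation (the
  system is linear); `LSODA`/`BDF` via `solve_ivp` are available behind
  the same interface (default tolerances rtol 1e-8, atol 1e-10) and are
  cross-checked in tests.  Non-negativity is asserted post hoc within
  tolerance, not enforced.
* Likelihood guards: predictions floored at 1e-10 before logs; profiled
  σ² floored at 1e-14 (noise-free fits would otherwise degenerate).
* Optimisation budgets (maxiter, starts, polish) default to values that
  recover noise-free parameters to ≲0.01 % and are arguments
  throughout; the recovery study defaults to 50 replicates with a
  single start at the initial estimates.
* Hessian steps are relative (1e-3) with an absolute floor; ties and
  degenerate inputs (constant observed vector in R², zero doses, empty
  registries) raise named errors rather than returning NaNs.

## Known limitations

* Linear kinetics only: no binding saturation, no inter-individual
  variability (the estimation targets mean profiles).
* The bundled physiology and S-value tables are literature-compiled and
  synthetic respectively; exact reproduction of any specific published
  dosimetry table requires supplying that source's tables.
* Asymptotic SEs under-cover at the default (large) noise levels with
  only 7–8 observations per tissue — the recovery study reports ~83 %
  2-SE coverage rather than the nominal ~95 % — and `K_gb` can run to
  weakly identified extremes in noisy replicates.
* Periodic voiding is the only bladder model; no dynamic filling.
* No imaging physics: the scan-duration effect is reduced to the fixed
  midpoint lag.
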