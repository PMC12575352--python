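# Methods

## Model structure

The body is a closed circulatory loop of 13 tissue compartments — lung,
adipose, muscle, liver, spleen, heart, brain, kidney, skin, reproductive
organs, red marrow, yellow marrow and a mass-balance-closing "rest of
body" — plus arterial and venous blood pools. Drug enters the venous pool,
passes through the lung (which receives the entire cardiac output), and
perfuses the remaining tissues in parallel from the arterial pool. Spleen
outflow drains through the liver (standard splanchnic routing; inert at
steady state for perfusion-limited, non-eliminating tissues, but kept for
topological fidelity).

Each tissue is perfusion-rate-limited: uptake is assumed instantaneous
relative to blood delivery, so

    V_i dC_i/dt = Q_i (C_art − C_i / Kp_i),

with `Kp_i` the tissue:blood partition coefficient and `C_i/Kp_i` the
emergent venous concentration of tissue i. This is appropriate for small,
lipophilic, membrane-permeant molecules such as the fentanyls; it is wrong
for compounds whose tissue uptake is permeability- or transporter-limited.

Elimination defaults to the venous pool referenced to plasma:
rate = `CL_sys · C_ven / R_bp`, where `CL_sys` is the plasma-referenced
systemic clearance and `R_bp` the blood:plasma ratio. This matches the
semantics of a measured systemic clearance without inventing hepatic
extraction data; an optional hepatic mode (well-stirred, extraction capped
at 0.99 of liver flow) is available for sensitivity analyses. Because
dosing, sampling and elimination all sit in venous blood, two identities
hold exactly and serve as permanent oracles for the implementation:

* `AUC₀₋∞ · CL_sys = Dose` (plasma-referenced),
* `Vss = R_bp (V_blood + Σ_i Kp_i V_i)` equals CL·MRT from a noise-free
  simulated profile.

The system is linear and time-invariant, so concentrations scale exactly
with dose.

## Physiology

The source publications for this workflow do not print compartment volumes
or perfusion flows (commercial platforms carry them internally), so the
package ships explicit reference tables as versioned CSV package data
(compendium-style values after Brown et al. 1997 / ICRP 89): a 70 kg adult
human with cardiac output 336 L/h and a 0.25 kg rat with cardiac output
5.0 L/h. Bone mineral and gut contents are not modelled; compartment
volumes sum to ~95% of body weight at density 1 kg/L, and `rest_of_body`
closes both the volume and the flow balance so venous return always equals
cardiac output regardless of the compendium used. Users can substitute
their own tables (`get_physiology(..., table=...)`); validation (positive
volumes/flows, lung flow = cardiac output, flow closure within 1%, volume
≤ body weight) runs on every construction.

Rescaling to a different body weight scales volumes linearly with weight
and flows with weight^exponent (default exponent 1; 0.75 gives conventional
allometric perfusion scaling). Linear scaling makes the algebraic Vss
scale exactly with body weight, which the tests assert.

## Partition coefficients

Three provenances, kept explicit in every `KpSet`:

* **table** — bundled fixtures with the literature values for
  β-hydroxythiofentanyl (rat QSAR) and fentanyl (rat report, rat QSAR,
  human interspecies extrapolation, human QSAR), or user CSVs. These are
  the canonical route for reproducing published outputs.
* **extrapolated** — the printed interspecies formula
  `Kp_human = (fup_human/fup_rat)(BP_rat/BP_human) Kp_rat`, implemented
  exactly as stated: tissue-wise linear, invertible by reciprocal scalars
  to machine precision. Note a documented inconsistency in the source
  material: applying the formula with the printed unbound fractions
  (25.5%/8.3%, BP ratio 1) gives a scale factor ≈ 3.07, while the printed
  extrapolated human table is a uniform ≈ 0.837 × the rat report table
  (coefficient of variation across tissues < 0.1%). The package implements
  the formula as printed and ships the published table as a separate
  fixture; it does not attempt to reconcile the two.
* **composition_qsar** — a tissue-composition predictor in the
  Rodgers–Rowland family. Unbound drug partitions into tissue water,
  neutral lipid and neutral phospholipid according to logP and ionization
  at pH 7.4 (plasma) / 7.0 (intracellular) / 7.22 (red cells); for
  moderate-to-strong bases (basic pKa ≥ 7, the fentanyl case) cation
  affinity for acidic phospholipids is calibrated from red-cell
  partitioning via `R_bp`, `f_up` and hematocrit; for neutrals, acids and
  weak bases a tissue:plasma binding-protein ratio carries the
  protein-bound term. Adipose-like tissues (adipose, yellow marrow) use a
  vegetable-oil:water surrogate for neutral lipid
  (log P_vo = 1.115·logP − 1.35). Tissue composition fractions ship as a
  documented CSV (adapted from published rat compendia and applied to both
  species — a standard simplification); tissues without published rows use
  labelled stand-ins (reproductive organs ~ thymus, red marrow ~ spleen,
  yellow marrow ~ adipose, rest of body ~ lean-tissue mean).

  This predictor is *not* a reimplementation of any commercial QSAR engine,
  and the package makes no claim of numerically matching such outputs; the
  tests pin qualitative structure (lipophilic bases concentrate in fat and
  brain, adipose Kp monotone in logP, adipose/yellow marrow at the top of
  the fentanyl ranking) plus a frozen closed-form regression reference for
  a fully neutral compound.

Unbound plasma fractions appear percent-scaled in parts of the source
tables; readers store fractions in (0, 1] and convert percent-scale inputs
with an explicit warning to prevent silent 100× errors.

## Simulation numerics

Internal units are litres, hours and picograms; concentrations are
reported in pg/mL. States are compartment amounts plus a cumulative
eliminated-amount bookkeeping state. The system matrix is constant, so the
integrator (LSODA, rtol 1e-8, atol 1e-10 scaled to the dose) gets the
exact Jacobian. An IV bolus is delivered as a 0.005 h infusion to avoid a
Dirac input (configurable; reported Cmax therefore refers to the end of
that short infusion). Output lands on a fixed grid — 481 points over 24 h
(human), 241 over 4 h (rat) by default; `dense_early=True` augments the
grid with ~200 log-spaced points through the venous mixing transient
(time constant V_ven/CO ≈ 40 s human, 9 s rat) so that trapezoidal
quadrature on the *output* resolves the early spike. Exposure-identity
checks need this: on the plain 1-min grid the unresolved spike biases
AUC by several percent. Pipeline workflows always enable it and, when no
horizon is configured, simulate ~12 predicted terminal half-lives
(predicted from the algebraic Vss and CL) so the extrapolated tail is
negligible even for large-Vss analogs.

A mass-balance audit (in-body + eliminated vs delivered) runs on every
simulation and must close within 0.1% of dose; in practice it closes to
~1e-12. Sub-tolerance negative amounts are clipped; larger ones raise an
integration-quality error rather than being hidden.

## Non-compartmental analysis

AUC and AUMC use linear-up/log-down trapezoids by default (pure linear
available); the log-down rule integrates a mono-exponential segment
exactly. The terminal slope λz is fitted by log-linear regression over
every contiguous terminal window of ≥ 3 positive points strictly after
Tmax, keeping the window with the highest adjusted R² (ties favour more
points) — the rule family of standard NCA software. Flat or rising tails
raise an explicit estimation failure. For bolus profiles the time-zero
concentration is back-extrapolated log-linearly from the first two
positive points. Tail extrapolation uses `C_last/λz` (AUC) and
`C_last·t_last/λz + C_last/λz²` (AUMC); an extrapolated fraction above 20%
is flagged in the result, not hidden. CL = Dose/AUC₀₋∞,
MRT = AUMC/AUC − τ/2 for a τ-infusion, Vss = CL·MRT, T½ = ln2/λz.

Brain/plasma penetration is reported on both Cmax and AUC bases. The Cmax
basis is the conventional default but is sampling-grid-dependent for IV
bolus data (an infinitely fine grid pegs plasma Cmax to the unobservable
mixing spike); the AUC basis is grid-robust and, for a non-eliminating
tissue in this model, equals `Kp_brain · R_bp` exactly. Both are always
co-reported and the threshold basis is configurable.

## Validation conventions

Fold error is the symmetric `max(p/o, o/p) ≥ 1`; reports also carry the
directional p/o ratio as publications print it. Band membership
(`within_2fold`, `within_range(lo, hi)`) uses closed intervals — a ratio
sitting exactly on the bound passes, matching how the source literature
treats boundary values. Ratios are rounded to 2 d.p. in reports with full
precision retained internally. Supported unit conversions: min↔h,
L/kg↔L and µg|mg/kg↔absolute (body weight required), pg·h/mL↔ng·h/mL,
mg↔µg↔pg.

One documented quirk: the source's alfentanil clearance ratio is printed
as 1.71 although 53.931/31.44 = 1.7154 rounds to 1.72 (its other ratios
round normally), and its alfentanil T½ ratio is printed as "1.75
(1.63/0.93)" although the stated observed T½ is 1.21 h. The package
reproduces self-consistent arithmetic only; comparisons against printed
ratios are made to one unit in the last printed digit.

## Synthetic data

`gen_compound_panel` draws seeded analog parameter sets spanning the
fentanyl-class ranges (logP uniform on [1.4, 4.5], f_up log-uniform on
[0.05, 0.35], R_bp uniform on [0.8, 1.1], basic pKa uniform on [7.5, 9.5]),
sharing one reference systemic clearance (62.66 L/h) as the batch workflow
prescribes. `gen_observed_study` samples a noise-free simulation at the
sparse rat schedule (0, 15, 45, 60, 90, 120, 180, 240 min) and applies
multiplicative lognormal noise with median 1 and configurable CV
(σ² = ln(1+CV²)), independent across points and subjects — an LC-MS/MS
assay-error stand-in. Below-LLOQ values are dropped, not zeroed.
Everything regenerates bit-identically from its seed.

The nominal time-zero sample is treated as a *post-dosing* draw (that is
how such schedules are reported for bolus studies) and is sampled at a
1-min draw latency — the earliest time a real specimen reflects a
circulatory-mixed concentration rather than the ideal-bolus venous spike.
With that design the 8-point schedule recovers the true clearance within
~3% noise-free; the residual bias is the genuinely unobservable
distribution-phase area before the first samples, quantified in the tests
against a dense-grid quadrature oracle.

The generator models assay noise only: no inter-subject physiological
variability, no covariates, no sampling-time jitter. Passing recovery
tests therefore demonstrates estimator correctness under the stated error
model, not robustness to population heterogeneity.

### Parameter choices not fixed by the source material

* β-hydroxythiofentanyl systemic clearance: measured in vivo in the
  original study but never tabulated; the fixture carries 0.45 L/h, a
  representative fentanyl-class rat value giving a terminal half-life
  ≈ 0.94 h so the 4 h sampling window spans ~4 half-lives (a sensible
  bioanalytical design). Marked in the fixture's own notes.
* Fentanyl human CL_sys = 62.66 L/h: the analog batch shares fentanyl's
  measured clearance, and the bundled analog table prints 62.66 L/h under
  that shared-clearance design; Dose/CL then reproduces the printed
  exposure (1595.9 pg·h/mL at 0.1 mg). Rat fentanyl CL 0.9 L/h by
  allometric scaling (62.66 × (0.25/70)^0.75).
* Human body weight defaults to 70 kg (the modelling convention) although
  the clinical comparator cohort averaged 67.1 kg; weight is an explicit
  parameter everywhere.

## Problem sizes used in tests and the acceptance script

Human runs use 72 h horizons with 1441-point grids (plus the dense-early
augmentation) — about 11 terminal half-lives for fentanyl, keeping the
extrapolated tail below 0.1%; equilibrium checks integrate a
clearance-free model to 400 h. Monte-Carlo recovery uses 500 synthetic
subjects; the batch workflow runs the full 34-analog panel. The whole
suite runs in well under a minute on one core.

## Known limitations

* IV dosing only; no absorption, transporters, metabolite kinetics or
  multiple-dose superposition.
* Perfusion-limited tissues throughout; CNS exposure ignores blood–brain
  barrier efflux, so brain ratios are upper-bound-flavoured surrogates.
* One composition table for both species; marrow/reproductive/rest rows
  are stand-ins.
* Healthy-adult reference physiology; no age, disease or obesity scaling
  beyond simple body-weight rescaling.
* The composition predictor is a published-equation stand-in for the
  proprietary QSAR used in the original workflow; its absolute Kp values
  are not expected to match that engine, only its qualitative structure.
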