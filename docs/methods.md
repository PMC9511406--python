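# Methods

## The assay and its response statistic

The reporter system is a human U2OS osteosarcoma line carrying four tandem
electrophile-response elements upstream of firefly luciferase; oxidative or
electrophilic stress stabilizes NRF2, which drives luciferase expression.
Cells are seeded in 96-well plates without the outer frame (rows A/H,
columns 1/12 are never used, which `rrassay` enforces structurally: an outer
well can never hold a role). The response statistic is the induction factor

    IF(well) = RLU(well) / mean RLU(solvent-control wells of the same plate).

The denominator is strictly per plate. This is both the field convention and
a statistical necessity for interlaboratory work: luminometer gain,
injector volume and cell number differ between laboratories and between
plates, and all of these act multiplicatively on RLU, so per-plate
normalization removes them exactly (IF is invariant under any positive
rescaling of a plate's signals). A consequence worth noting is that purely
additive "lab offsets" on the raw scale cannot survive normalization; what
can differ between laboratories after normalization is the *magnitude* of
the induced response.

## Study design

One experiment = one reference plate (curcumin series rows B–D; dichlorvos
and mannitol series rows E–G) plus three experimental plates (curcumin rows
B–D, one test material rows E–G). Each laboratory runs three independent
experiments. Defaults: curcumin 9 geometric points 10⁻⁴–10⁻⁸ M (the stated
decade spacing is arithmetically inconsistent with 9 points over 4 decades,
so half-decade spacing is used; `make_log_dilution_series` is general),
dichlorvos 4 points 10⁻⁵–7·10⁻⁷ M, mannitol 4 points 10⁻³–10⁻⁵ M,
nanomaterials 9 half-decade points 0.01–100 µg/ml. Chemical concentrations
are molar, nanomaterial concentrations mass-per-volume; units are carried
explicitly and never converted. Every plate keeps at least one free column
per half for solvent controls (≥ 6 per plate, ≥ 2 enforced).

## Gating, classification, thresholds

- Plate effectiveness: maximum per-concentration mean IF of the curcumin
  series must be **strictly greater than 8** ("over 8"). Invalid plates are
  excluded from every downstream statistic and logged; exclusion is the
  conservative reading of an effectiveness gate.
- Inducer call: per-condition mean IF across experiments **≥ 1.5,
  inclusive** ("1.5 fold or higher"). A substance is an inducer for a
  laboratory when any of its concentrations is.
- The decline of IF at cytotoxic top doses is *not* corrected in
  classification — calls use raw means. Cytotoxicity enters only as an
  optional mask for dose–response fitting (default viability cutoff 70% of
  the unexposed control, the common convention, e.g. ISO 10993-5; the
  protocol itself fixes no number, so it is configurable and masking is
  opt-in).

## Dose–response model

Four-parameter logistic in log₁₀ dose (the standard agonist-vs-response
model): bottom, top, log₁₀ EC50, Hill slope. The vehicle control is excluded
(log of zero); bottom may be pinned at 1 (the solvent IF) via
`FitConstraints(fix_bottom=1)`. Fitting is unweighted least squares on
condition means (1/SD² weighting optional), with a data-driven start
(bottom = min, top = max, EC50 at the dose nearest half-maximum, slope 1)
plus four jittered restarts from a fixed seed; the best residual sum of
squares wins, and `converged` reports the optimizer status honestly.
log₁₀ EC50 is bounded to the data range ± 3 decades to keep degenerate
(flat) fits finite. If the optimizer lands in the mirrored parameterization
(bottom > top with negative slope) the equivalent curve is reported in
canonical orientation. Bell-shaped responses are handled only by masking,
never by a biphasic model — mirroring how such data are interpreted in
practice rather than extending the analysis.

## ISO 5725 precision decomposition

The "values" entering a precision cell are per-experiment condition-mean
IFs, three per laboratory by design (a pooled-well mode exists via the
`within_experiment`/`across_experiments` scope choice, since reports rarely
state which was used). For labs i = 1..p with nᵢ replicates:

    s_r² = Σ (nᵢ−1) sᵢ² / Σ (nᵢ−1)          (repeatability, df-weighted)
    s_d² = var(lab means)                     (unweighted, p−1 df)
    s_L² = max(0, s_d² − s_r²/n̄)             (between-lab; n̄ = harmonic mean nᵢ)
    s_R² = s_r² + s_L²                        (reproducibility)

For balanced designs this is exactly the one-way random-effects ANOVA
estimator (verified against a brute-force mean-squares oracle to 1e-10 in
the tests, including the s_L² = 0 truncation branch). Laboratories with a
single value contribute to the lab means but not to s_r, and are flagged.
The heatmap and the "inter-laboratory SD" default to s_R, which contains
both components; s_L is available (`metric="between_lab"`) since the phrase
is ambiguous in common usage. The headline `mean_intra_lab_sd` is the
unweighted mean over all (lab × cell) SDs; `mean_inter_lab_sd` the
unweighted mean over cells. By default only the test materials' cells enter
these means (chemical controls optional via
`include_controls_in_precision`).

Consistency tests are flag-only (no automatic removal): Cochran's
C = max sᵢ²/Σ sᵢ² and the single Grubbs statistic on lab means, both at the
1% level. Critical values are frozen data tables (Cochran p ≤ 30, n ≤ 6;
Grubbs p ≤ 40) generated once from the exact constructions — Cochran via
the union bound through the F distribution at α/p, Grubbs via the two-sided
t construction at α/(2p) — which reproduce the published ISO 5725-2 1%
tables to printed precision. Lookup is exact; out-of-range (p, n) is an
error, never interpolated. Under a homoscedastic Gaussian null at p = 7,
n = 3, both empirical flag rates are ≈ 1% (the tests bound them by
0.01 + 3 Monte-Carlo s.e. at 10,000 replicates).

## Synthetic study generator

`simulate_study` draws, for each treated well,

    IF = 1 + (hill(c) − 1) · (viab(c)/100)^coupling · A + δ_lab + δ_exp + ε_well

with `hill` the substance's true 4PL, `viab` a logistic viability decline
(floor, log₁₀ LC50, slope), coupling ∈ [0, 1] controlling how strongly
cytotoxicity suppresses the reporter (IF is pulled toward 1, not 0 — dead
wells lose *induced* signal, producing the bell shape of cytotoxic inducers
without claiming mechanism), and A a lognormal response-amplitude factor
with a per-(lab, substance) and a per-(experiment, substance) component.
δ_lab ~ N(0, σ_lab) and δ_exp ~ N(0, σ_exp) are additive effects on the IF
scale (the scale on which assay precision is quoted), ε_well is well noise.
Raw RLU = IF × plate solvent level; solvent wells are drawn around
`rlu_baseline` with CV `rlu_cv`, so with all noise at zero the induction
pipeline recovers the truth to 1e-12. Negative RLU is clipped at 0 and
counted. Viability plates put untreated controls in rows B–D and the test
series in rows E–G and are generated for a single laboratory, as such
assays are typically run once before the ring trial. A single root seed
drives a hierarchical SeedSequence scheme (study → lab → experiment →
plate), so subsets reproduce independently; identical seeds give
bit-identical studies.

**Why amplitude-multiplicative lab effects in the default study.** An
additive between-lab shift large enough to produce a reproducibility SD of
≈ 0.28 on flat responses would make an inert material cross the 1.5
threshold in some laboratory in a third of studies — incompatible with the
reported outcome that no laboratory ever called the TiO₂-like material an
inducer, and physically implausible given that per-plate normalization
removes additive offsets. The default truth therefore sets σ_lab = 0 and
expresses between-lab differences as amplitude heterogeneity (lognormal σ
0.30–0.35 for the nanomaterials, 0.12 for curcumin, reflecting the
harmonized reference protocol), which reproduces the reported structure:
laboratories differ in the magnitude of induced responses, inter-laboratory
SD is large exactly where the response is large, and flat conditions agree
closely. Additive σ_lab remains a first-class parameter and is what the
variance-recovery experiments exercise.

**Default truth parameters** (IF units unless noted): Ag-like — Hill
(1, 6.5, EC50 1 µg/ml, slope 1.5), viability (floor 5%, LC50 20 µg/ml,
slope 3), coupling 1; TiO₂-like — flat at IF 1, viability (floor 40%, LC50
≈ 89 µg/ml, slope 4), i.e. non-cytotoxic except at the top dose;
Fe₃O₄-PEG-PLGA-like — Hill (1, 1.55, EC50 20 µg/ml, slope 1.5), mild
viability loss only near 100 µg/ml, coupling 0.5, so the top doses hover at
the 1.5 threshold; curcumin — Hill (1, 14, EC50 1 µM, slope 1.3) with
viability loss from ~10 µM so the IF peaks ≈ 12 near 10⁻⁵ M and declines at
10⁻⁴ M; dichlorvos induces (top 3.5), mannitol is flat. Within-lab noise
σ_exp = 0.13 and σ_well = 0.16 combine to an SD of ≈ 0.16 on per-experiment
means of well triplicates, matching the assay's reported intra-laboratory
precision; solvent wells have baseline 20,000 RLU with 8% CV (typical
luminometer scale). These are the study conditions; they are set once, not
tuned.

**What the generator does not emulate:** plate-position (edge) effects
beyond outer-well exclusion, luminescence drift across injector cycles,
optical interference of particles with the readout, endotoxin or
dissolution effects, and non-Gaussian outlier laboratories. Passing the
simulation-based checks therefore demonstrates the correctness and
calibration of the *analysis* under the stated noise model, not robustness
of the wet-lab assay to artefacts outside it.

## Validation experiments and problem sizes

`rrassay.validation` (used by the tests and `scripts/acceptance.py`):

- `variance_component_recovery` — 500 studies of 7 labs × 3 experiments
  with truth σ_intra = 0.16 and between-lab component √(0.28² − 0.16²), so
  the cell reproducibility SD is 0.28; the pipeline's mean intra/inter
  estimates land within a few percent (the residual bias is the familiar
  E[s] < σ small-sample effect of SDs estimated from 3 and 7 values).
- `preset_reproduction` — 200 default studies; measures how often all 7
  labs show the Ag signature (inducer + dose dependence + top-dose decline,
  operationalized as lowest-dose mean < 1.5 and top-dose mean < 0.8 × peak),
  how often the TiO₂-like material stays below threshold everywhere, and how
  often the Fe₃O₄-like material splits the laboratories.
- `fit_recovery` — noiseless 4PL recovery to < 1e-6 relative error; median
  |Δlog₁₀ EC50| under IF noise SD 0.1 (9 doses × 3 replicates, 200 fits).
- `consistency_test_calibration` — 10,000 null replicates at p = 7, n = 3.
- `false_inducer_rate` — 1,000 flat-truth studies at well noise SD 0.1.

These sizes keep the whole suite and the reproduction script to a few
minutes on one CPU while leaving Monte-Carlo error well below the asserted
margins.

## Known limitations

- The ISO 5725 decomposition assumes exchangeable Gaussian effects; heavy
  tails are only *flagged* (Cochran/Grubbs), not accommodated.
- Unbalanced cells use the harmonic-mean-n̄ moment estimator, which is
  consistent but not the REML estimate; for the mildly unbalanced designs
  produced by occasional plate exclusions the difference is negligible.
- EC50s from masked bell-shaped curves describe the monotone portion only;
  no biphasic or benchmark-dose modelling is offered.
- Whether published headline precision means average over labs, cells, or
  both is generally under-specified; the package documents its choice
  (unweighted over lab × cell for intra, over cells for inter) and exposes
  both metrics rather than claiming equivalence to any one report.
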