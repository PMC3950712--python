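# Methods

This note documents the models, parameter tables, numerical conventions and
known limitations of `psimelt`.  Nothing here asserts an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Two-state melting model

A non-self-complementary bimolecular duplex is assumed to populate only two
states, full duplex and free single strands, so a single (ΔH°, ΔS°) pair
describes the transition and ΔG°(T) = ΔH° − T·ΔS° (no ΔCp term).  With α the
fraction of strands in duplex at total single-strand concentration CT,

    K(T) = 2α / ((1 − α)² CT),

solved in the closed, numerically stable form α = 2κ / (2κ + 2 + √(8κ + 4))
with κ = K·CT (exact at α = ½ when K = 4/CT; the exponent of K is clipped at
±700 to avoid overflow, which only affects temperatures where α has already
saturated in double precision).  Setting α = ½ gives

    Tm⁻¹ = (R/ΔH°) ln(CT/4) + ΔS°/ΔH°.

The factor 4 is the non-self-complementary molecularity; a
`molecularity` switch exposes the self-complementary CT/1 case, which no
shipped fixture exercises.  Units: kcal/mol for ΔH° and ΔG°, eu
(cal mol⁻¹ K⁻¹) for ΔS°, R = 1.9872 cal mol⁻¹ K⁻¹, Kelvin internally and
°C at every API boundary.  ΔG°₃₇ is evaluated at 310.15 K; reported Tm
values refer to CT = 10⁻⁴ M unless stated.

### Single-curve fits (`fit_curve`)

Observed absorbance is modelled as
A(T) = α·(m_ds·T + b_ds) + (1 − α)·(m_ss·T + b_ss), six free parameters
(ΔH°, ΔS°, four baseline coefficients), fit by `scipy.optimize.least_squares`
(tolerances 1e-12, iteration cap 500·7 function evaluations).  Conventions
chosen where the classic melt-fitting programs leave them unstated:

- initial Tm from the extremum of a smoothed (boxcar ~len/15) numerical
  derivative; baseline starts from linear fits to the outer 15% of the grid;
  ΔH° multi-start at −50/−80/−120 kcal/mol, best final cost kept;
- a curve is rejected ("no transition detected") when its absorbance span is
  zero or a straight line already explains it to 2% rms of the span;
- parameter covariance from the SVD of the final Jacobian scaled by residual
  variance; ΔG°₃₇ uncertainty by first-order propagation through the full
  2×2 (ΔH°, ΔS°) block, which preserves their ~0.9999 correlation and hence
  the characteristically small ΔG°₃₇ errors.

On noiseless simulated curves the generating parameters are recovered to
better than 0.1% (the suite asserts it), so the estimator itself contributes
nothing visible at experimental noise levels.

### Concentration-dependence route (`fit_tm_plot`)

Per-curve Tm values are taken at each curve's *fitted* α = ½ point, not at
the derivative maximum, which for a bimolecular melt sits systematically
~1 °C above α = ½ (a test demonstrates the offset).  Tm⁻¹ is regressed on
ln(CT/4) by ordinary least squares (`numpy.polyfit`, covariance scaled by
residuals); ΔH° = R/slope, ΔS° = R·intercept/slope, with standard deviations
by first-order propagation from the regression covariance.  How the original
analyses computed per-duplex errors for this route is not documented;
regression covariance is this package's stated convention.

### Two-state criterion

The melt is flagged two-state when the ΔH° from the two routes agree within
15% relative difference, |Δ|/mean(|ΔH°|).  The threshold is fixed; the one
published duplex that shows two transitions (central U-G in the
5'CUG/3'GGC context, curve-average −105.9 vs plot −76.8 kcal/mol, a 32%
disagreement) is flagged, not modelled — no multi-state fitting is provided.

## Nearest-neighbor engine

ΔG°₃₇ = initiation + Σ stacks + Σ terminal-pair penalties + Σ dangling ends.
Stack keys are dinucleotide fragments `XY/WZ` (top 5'→3' over bottom 3'→5'),
stored under the lexicographic minimum of the key and its 180° rotation
`ZW/YX`, so each physical stack parameterizes exactly once; predictions are
invariant under reading the duplex from the other strand (property-tested).

Sign convention: energies are formation values (negative = stabilizing)
everywhere in the API; report writers emit printed-table magnitudes (−ΔG°)
with ΔH°/ΔS°/Tm rounded to 1 decimal and ΔG°₃₇ to 2.

Parameter tables (TSV under `psimelt/data/`, one provenance tag per entry,
overridable via same-format user files):

- **Watson–Crick** (`nn_wc.tsv`): the Xia-1998 ΔG°₃₇ set — 10 stacks,
  initiation +4.09, terminal A-U penalty +0.45 kcal/mol.  Orientation
  conventions were cross-checked against the Turner-2004 stack matrix
  distributed with ViennaRNA.
- **Ψ-A** (`nn_psi_a.tsv`): from the published Ψ-A nearest-neighbor study
  (Hudson/Znosko 2013), whose full table is not reprinted in the source
  analysis.  Four stacks are pinned directly: ΨC/AG = −2.49 and
  GΨ/CA = −3.29 (quoted), AΨ/UA = −2.80 and ΨU/AA = −2.74 (the quoted Ψ
  enhancements −1.70/−1.81 over their U-A analogs, taken in listed order).
  The remaining four appear in the study's constructs only in two fixed
  sums (CΨ/GA + ΨG/AC = −4.90; UΨ/AA + ΨA/AU = −3.55), recovered from the
  published duplex-level predictions and split evenly; because those stacks
  only ever co-occur, the split cannot affect any duplex prediction.  The
  `reconstructed-sum` provenance tag marks them.  Terminal Ψ-A penalty
  +0.31 kcal/mol.
- **G-U** (`nn_gu.tsv`): the revised wobble set, likewise reconstructed from
  the published duplex-level predictions it produced (two stacks pinned by
  terminal extensions, three even-split pair sums).  Solving those
  predictions jointly is only consistent with a **zero terminal G-U
  penalty**, so the table carries an explicit 0.00 entry — a deliberate
  departure from the older convention of charging G-U ends the A-U penalty.
- **Dangling ends** (`nn_dangling.tsv`): Turner-2004 5'/3' single-nucleotide
  dangles (0.1 kcal/mol precision).  No Ψ dangling parameters exist; a Ψ
  overhang raises the named unparameterized error.

Internal Ψ-G/Ψ-U/Ψ-C pairs raise `UnparameterizedContextError` naming the
offending context.  `predict_dG37_with_corrections` offers a provisional
alternative: predict the U analog and add the *measured* substitution
increment for the central motif, with the correction term flagged
`this-study-measured` in the breakdown — measured increments, not fitted
parameters, and valid only for the motifs actually measured.

Engine predictions carry sd = 0: the source tables publish no parameter
uncertainties, and inventing them would misstate the error budget.
Measured-vs-predicted comparisons flag agreement at |Δ| ≤ 1 kcal/mol plus
the measurement sd ("within 1 kcal/mol when experimental error is
considered").

### Residual discrepancies against published predictions

The published per-duplex Ψ-A NN predictions cannot all be reconciled with
the same study's quoted stack arithmetic (e.g. the quoted 3' increment
−3.29 + 0.31 = −2.98 is inconsistent with the bracketed prediction printed
for the corresponding duplex).  The fixture set therefore stores the printed
predictions verbatim for comparison purposes, while the engine follows the
quoted arithmetic; tests gate only the quantities the quoted arithmetic
pins.  Similarly, two printed WC predictions differ from the full-precision
Xia sums by up to 0.18 kcal/mol (consistent with 0.1-rounded tables in the
original prediction software); the corresponding sweep test allows ±0.2.
Three printed increment sds differ by ≤0.04 from root-sum-square of their
inputs; the increment *values* all reproduce exactly to 2 decimals.

## Error propagation

All ΔΔG°₃₇ increments (terminal additions, U→Ψ substitutions) are simple
differences of measured energies with root-sum-square sds,
σ = √(σa² + σb²), computed in full precision and rounded only at reporting
time (2 decimals for energies, 1 for °C).

## Synthetic data generator

`SyntheticSpec` defaults emulate the study's experimental design: nine
log-spaced concentrations over 10⁻⁶–10⁻³ M, absorbance sampled every 1 °C
from 0 to 90 °C, additive Gaussian absorbance noise with sd 0.002 on a
normalized (~unit) absorbance scale, and default true parameters
ΔH° = −80 kcal/mol, ΔS° = −220 eu, placing every Tm inside the grid across
the concentration range.  The source reports no absorbance amplitudes or
baseline slopes, so the defaults are conventions: double-strand baseline
1.0 + 3·10⁻⁴·T, single-strand 1.22 + 5·10⁻⁴·T (~20% hyperchromicity,
typical of RNA UV melts); recovered thermodynamics are insensitive to them
by construction since the fit estimates baselines freely.  Same seed ⇒
byte-identical datasets (numpy `default_rng`).

What passing synthetic tests shows: the estimators are unbiased and
consistent under the model's own assumptions at realistic noise.  What it
does not show: robustness to baseline curvature, instrument drift, ΔCp ≠ 0,
aggregation, or genuinely multi-state melts — none of which the generator
emulates (the two-transition fixture is carried as printed values only).

## Fixtures

The published per-duplex thermodynamics ship as a packaged TSV at printed
precision: 22 duplex systems (20 Ψ test duplexes + 2 cores), each with both
estimation routes and, where printed, the external NN predictions; separate
TSVs carry the printed terminal-addition and substitution increments.
Fixture-based tests use table-precision tolerances (0.1 kcal/mol on ΔG°
identities, 0.5 °C on Tm recomputed from 1-decimal ΔH°/ΔS°), never exact
floats.

## Problem sizes

The test suite and acceptance script run synthetic experiments at the
study's own scale (nine concentrations × 91 temperature points); replicate
counts are 20–25 where scatter or worst-case statistics are measured, enough
for stable results at the asserted tolerances.

## Known limitations

- No loops, bulges, hairpins, multi-helix folding or secondary-structure
  prediction; duplexes only, with at most one single-nucleotide overhang
  per end.
- No ΔH°/ΔS° nearest-neighbor prediction (ΔG°₃₇ only), matching the scope
  of the embedded tables.
- Ψ parameters cover Ψ-A propagation only; other Ψ pairs are measured
  increments, not transferable parameters.
- The even splits inside the `reconstructed-sum` table entries are exact
  for every construct measured here but must not be used as individual
  stack values elsewhere.
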