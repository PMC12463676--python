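# Methods

This note records the models implemented in granulizer, the assumptions
behind them, the defaults and why they were chosen, and the limits of what
the synthetic-data tests demonstrate.

## Thermal stability scoring

The scoring deliberately avoids melting-curve sigmoid fitting. With FC_T
the treatment/control reporter-intensity ratio at temperature T, the
abundance score is the mean log2 FC at the two lowest grid temperatures
and the thermal stability score is Σ_T (log2 FC_T − abundance score).
Two algebraic identities follow and are enforced by tests: adding a
constant to every log2 FC leaves the stability score unchanged (it moves
the abundance score by exactly that constant), and negating all log2 FC
negates both scores. The construction assumes the two lowest grid
temperatures are below the onset of melting for essentially all proteins;
on a 37.0–66.3 °C grid for human cells that holds for all but the most
labile proteins.

Zero or missing intensities make a log ratio undefined and are treated as
missing (counted, warned about, never imputed). The stability score
requires `min_points` quantified temperatures, default 10 — on the
canonical 10-point grid that means complete rows; the threshold is
configurable for other grids.

Significance is assigned per contrast. Scores are standardized using the
sample standard deviation (n−1 denominator, so that [1,2,3] maps exactly
to [−1,0,1]); the z-transform is computed over all proteins of one
contrast, not pooled across contrasts. The empirical null for the
moderated test is centred at the median and scaled by the normal-
consistent MAD so that a minority of real effects does not widen the
null. Each protein's null variance is scaled by mean(w)/w_i with w_i the
number of quantified temperatures (fewer observations, noisier score) and
then shrunk half-way toward the pooled robust variance — an empirical-
Bayes compromise whose `shrink` weight (default 0.5) interpolates between
fully per-protein and fully pooled error models. Two FDR variants are
exposed: Benjamini–Hochberg tail-area FDR (default) and a local FDR from
a half-normal null-density fit; the default was chosen because the
tail-area quantity is what the |z| > 1.5 / FDR < 0.05 decision surface
consumes. Classification uses strict inequalities on both arms.

With fewer than 10 proteins the null is not estimable and the test
refuses rather than returning unstable values.

## NMR uptake and partitioning model

All relations derive from two assumptions: the amide-proton signal is
proportional to free compound concentration (valid at low temperature and
pH below ~8.6, where chemical exchange and hydrolysis are negligible),
and material is conserved between compartments. The uptake equations
additionally assume the total cell volume is negligible against the
medium volume (V_out = V_add; V_out stays an explicit field so the
approximation can be dropped). The membrane-bound ratio R is an upper
bound argument, not a measurement: it asks how many compound molecules
each plasma-membrane lipid would have to host if the entire lost signal
were membrane-bound, using a 0.5 nm² lipid footprint and a spherical
cell; values far above 1 make the membrane an implausible sink.

Internally every function takes SI-coherent scalars (m, m², m³, mol/L, L);
the CLI parses field units (µM, µl, nm², mm, µm). The single explicit
conversion — single-cell volume in m³ entering a concentration in mol/L —
is isolated in one constant (`M3_TO_L`), because a silent m³/L slip is
the likeliest failure mode of this arithmetic. Signal pairs with
S₊cells marginally above S₋cells (≤ 2% relative, configurable) are
clipped to U = 0; larger excesses raise an error instead of being
silently truncated.

The condensate pellet is modelled as the spherical cap subtending
θ = asin(a/r) in the hemispherical tube bottom; the closed form is tested
against direct quadrature of the solid of revolution and against its
limits (hemisphere at a = r, zero at a = 0). Mass conservation of the
phase concentrations is asserted to 1e-9 relative on randomized inputs.

## Image quantification

"5-pixel Gaussian blur" is read as σ = 5 px and "10-pixel weight 0.9
unsharp" as the standard unsharp form (image − w·blur)/(1−w) with
σ = 10 px, w = 0.9; both are stated conventions rather than derivable
facts. Thresholding defaults to Otsu (with a fixed-value override)
because the upstream protocol says only "intensity thresholding"; Otsu
makes noiseless counts invariant to global intensity rescaling, which is
tested. Minimum region areas (nuclei ≥ 50 px, granules ≥ 2 px,
configurable) suppress single-pixel noise; the granule mask is made
disjoint from the nuclei mask by construction — any connected component
overlapping a nucleus is removed, implementing the rule that intranuclear
puncta are not cytoplasmic granules. Fields are 2-D; z-stacks must be
projected before input. The nuclear partition p = a/(1−a) is computed
from per-field summed intensities (per-cell aggregation is available but
not the default).

## Screen scoring and dose responses

Mahalanobis distances are computed on control-referenced z-scores with a
per-plate control covariance, because plates differ systematically and
the control wells are the only shared reference. With ~15 features and
few dozen controls the sample covariance is ill-conditioned, so
Ledoit–Wolf shrinkage is the default; the plain inverse remains available
and is used by the tests as the independent linear-algebra oracle on
well-conditioned instances. Features constant across a plate's controls
are dropped with a warning. Hit selection is rank-based (top-N) rather
than a fixed D threshold.

Dose-response curves use the four-parameter logistic (the standard
reading of a "Rodbard sigmoidal"), parameterized on the log-concentration
axis and fitted by least squares with multistart initialisation (EC50
starts at the concentration quartiles, both slope signs). Because the
assay readouts carry multiplicative error, responses are fitted
log-transformed whenever they are strictly positive (`fit_scale="auto"`);
raw-scale fitting is used otherwise or on request. A fitted EC50 outside
[min conc/10, max conc·10], a fitted amplitude below 5% of the response
magnitude, or non-convergence flags the fit unreliable — flagged, never
silently clamped. Monotonicity of a dose series is operationalized as
|Spearman ρ| ≥ 0.8 (direction-aware on request), a deliberate
quantification of a qualitative criterion.

Time-drift correction assumes the drift is linear over a plate row and
multiplicative by default (sedimentation reduces signal proportionally);
an additive mode exists. Values are rescaled to the row's mean control
level so equal start/end controls leave data untouched.

## IDR calling and composition

Both consensus thresholds are strict, taken literally from their
definitions: a residue needs strictly more than 75% of predictors (3 of 4
does not qualify) and an interval needs strictly more than ten residues
(≥ 11). Both are configurable because upstream databases do not document
their own boundary conventions. Intervals are 1-based inclusive
everywhere, stated in output headers.

Class comparisons of IDR proportions default to the two-sample rank-sum
test with Holm adjustment: the stability classes are unpaired groups of
unequal size, so a signed-rank test is not applicable; the paired variant
is exposed for genuinely paired designs. Classes with fewer than three
members are summarised but excluded from testing.

The composition score per amino acid is the relative frequency difference
(f_group − f_bg)/f_bg on pooled residue counts, so (1 + score)·f_bg
reconstructs the observed group frequency exactly (a tested identity).
Dispersion is the bootstrap SD over group proteins (resampling proteins,
not residues, respects within-protein composition correlation);
significance is an unpaired Welch t-test on per-sequence frequencies with
Bonferroni correction across the 20 residue types. Amino acids absent
from the background have an undefined ratio and are reported as missing.

## Synthetic data: what it emulates, and what it does not

Generators derive their random streams from (seed, generator-name), so
every output is bit-reproducible and adding a generator never perturbs
another's stream.

- `gen_tpp` draws melting points uniform on 45–55 °C with slope 2 °C and
  plateau 0.05 — resembling published human meltome ranges — and applies
  multiplicative log-normal noise (default CV 5%). It emulates the
  experiment's shape (thousands of proteins × 10 temperatures ×
  conditions, sigmoidal soluble-fraction decay, treatment-induced Tm and
  abundance shifts) but not TMT-specific artefacts: no co-isolation
  interference, no missing-not-at-random dropout, no protein-correlated
  noise. Passing recovery tests therefore shows the scoring machinery is
  correct and calibrated under the stated noise model, not that real TPP
  data will yield the same recovery rates.
- `gen_field_image` renders Gaussian nuclei and puncta with known
  coordinates plus optional additive noise; it does not emulate uneven
  illumination, cell crowding or out-of-focus light, so exact-count tests
  certify the operator chain, not segmentation robustness on real fields.
- `gen_plate` draws control and treatment wells from a common multivariate
  normal with mild feature correlation and plants hits as additive shifts
  in feature-SD units; real screens add row/column and edge effects that
  are out of scope here.
- `gen_dose_response` is the 4PL forward model with multiplicative noise —
  matching the fitter's assumption, which is what a self-consistency and
  recovery study requires.
- `gen_disorder` plants one IDR per protein (longer in the "stabilized"
  class, with R/Y/F enriched ~2×) and corrupts predictor tracks by
  independent per-residue disagreement; real predictor errors are
  correlated along the sequence.

The synthetic stand-ins for SFPQ and SRSF1 (`synthetic_sfpq`,
`synthetic_srsf1`) are constructed sequences reproducing only the
documented length and methionine count of the canonical proteins
(707 aa / 28 Met and 248 aa / 3 Met); they are labelled synthetic in code
and must not be used as the real sequences.

## Problem sizes

The validation suite uses sizes chosen to make distributional checks
meaningful while staying desk-scale: 1,000-protein TPP simulations for
recovery and calibration, a 1,536-well screen (four 384-well plates,
32 controls each, 20 planted hits) for hit ranking, 200 replicate
12-point dose-response fits for EC50 recovery, and 200-residue random
profiles for IDR oracle agreement.

## Known limitations

- The moderated-significance model reproduces the decision surface
  (|z| and FDR cutoffs) of the original limma/fdrtool-based analysis but
  not its exact numbers, which are not reproducible from published
  information alone; both FDR variants are exposed for sensitivity
  checks.
- The empirical null assumes most proteins are unaffected; screens of
  compounds with proteome-wide effects would violate it.
- EC50 confidence intervals are not implemented; the residual norm and
  reliability flags are the only fit diagnostics.
- Compartment partition coefficients use mean intensities; background
  subtraction and bleed-through correction are assumed done upstream.
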