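# Methods

## Lateralization model

All connectivity is the Fisher z-transform of the Pearson correlation
between parcel time series. Correlations are clipped to ±(1 − 1e−7)
before `atanh`, so perfectly correlated parcels yield a large finite z
(≈ 8.4) rather than infinity; unbounded values would otherwise dominate
the edge sums. No thresholding, sign censoring or absolute value is
applied anywhere in the connectivity: the laterality index operates on
raw signed sums, with the absolute value only in the denominator, exactly
as the index is defined.

For a homotopic pair (ℓ, r) on a P-parcel bilateral scheme, the
heterotopic sums `heL`, `heR` each contain P/2 − 1 terms (opposite
hemisphere, homotopic partner excluded), and the intrahemispheric sums
`intraL`, `intraR` each contain P/2 − 1 terms (own hemisphere, self
excluded). The index (L − R)/|L + R| is undefined when |L + R| < 1e−12;
because signed z sums can cancel, such pairs are flagged and excluded
from network means rather than raised as errors or propagated as ±∞,
keeping the aggregate finite and the exclusions countable. Network
aggregation is the unweighted mean of pair indices over homotopic pairs
whose members **both** carry the network label; pairs with asymmetric
network membership are listed by `ParcelScheme.asymmetric_network_pairs`
so that their exclusion is visible rather than silent. Pair-level is the
only granularity at which the index exists, so no other weighting is
meaningful.

The mean whole-brain connectivity covariate (mFC) is the arithmetic mean
of z over all P(P−1)/2 unique parcel pairs — inter- and intrahemispheric
alike, the most literal reading of "whole brain".

Volume censoring is accepted as a boolean mask on the input time series
(True = retained) and applied before the correlation; computing the
censoring from motion traces is upstream preprocessing and out of scope.
Head motion enters the analyses only as the per-scan mean framewise
displacement (mFD) covariate.

## Parcellation bookkeeping

A scheme is valid when P is even with exactly P/2 parcels per hemisphere
and the homotopic-partner map is an involution that always crosses
hemispheres. When a scheme file lacks a partner column, the conventional
bilateral packing partner[i] = i + P/2 is assumed (left block first);
files indexed from 1 are accepted behind an explicit flag to avoid
off-by-one ambiguity between atlas distributions. The bundled 360-parcel
scheme (`hemilat/data/scheme360_synthetic.csv`) is generated by
`make_synthetic_scheme` and mimics the shape of a bilateral multimodal
atlas with a 24-pair FPN subset; it makes no claim about any real atlas's
network membership, which varies between distributions.

## Synthetic cohort generator

The generator's default design is the reference trial's analysable
sample: control/training/healthy arms of 28/28/26 at baseline, patients
re-measured after the intervention (week 7, 25/24 retained) and at
follow-up (month 6, 21/14), healthy adults at baseline only; 180-volume
scans; a 60-parcel scheme with 10 FPN pairs (desk-scale; a 360-parcel
mode exists through `AsymmetrySpec(n_parcels=360, ...)`).

Signals are stationary Gaussian draws from a block-structured correlation
matrix: homotopic edges at 0.5, heterotopic at 0.15, intrahemispheric at
0.3 — levels in the range typical of parcellated resting-state data,
with homotopic connectivity strongest. Asymmetry is injected by adding a
signed `delta_he` once to every heterotopic edge incident to a left
network parcel (partner edge excluded), and `delta_intra` analogously to
within-left edges, then repairing the matrix to positive
semi-definiteness by eigenvalue clipping at 1e−6 and rescaling to unit
diagonal; the maximum entry perturbation is recorded in the provenance
and flagged when it exceeds 0.05 (at the default levels it is < 1e−14).
Negative `delta_he` weakens left heterotopic edges and produces a
rightward population `LI_he`; the analytic value is obtained by running
the lateralization pipeline on the z-transform of the generating matrix,
which is also the infinite-scan limit of the empirical index.

Temporal autocorrelation is off by default — the LI depends only on the
spatial correlation structure — but an AR(1) kernel is available for
robustness checks (`simulate_timeseries(..., ar1=φ)`), constructed so the
marginal spatial correlation is unchanged.

The baseline asymmetry is `delta_he = −0.04` in every arm, giving a
population `LI_he` of −0.113 against a within-cell sampling sd of ≈ 0.08
at 180 volumes (one-sample effect size ≈ 1.4 at baseline). The training
arm's `delta_he` is released to 0 at week 7 and reverts to −0.04 at month
6. The week-7 shift of ≈ 0.11 is ≈ 1.4 within-cell sds — calibrated so
the design's qualitative pattern holds robustly (clearly rightward
baselines, a non-significant training-arm week-7 cell) and the group ×
time interaction is detectable with high power at the trial's arm sizes,
as the Monte-Carlo experiments in `hemilat.validation` verify (measured
type-I ≈ 0.04–0.06, power ≈ 0.9 over 200-replicate runs).

Behaviour scores are linear in the subject's realized network `LI_he`
plus Gaussian noise: a memory-like score with negative slope (rightward
lateralization ↔ better memory, the healthy-aging pattern) and an
executive-like score with positive slope, with noise set via
`noise_sd_for_partial_r` so the population correlation is ≈ 0.5.
Demographics are drawn once per subject (age ~ N(65, 7), education
~ N(10.5, 3) clipped to [6, 20], sex Bernoulli(0.5)); mFD ~ N(0.15, 0.04)
clipped below at 0.03 per session. All randomness descends from the
master seed through deterministic per-session spawn keys, so a cohort is
bit-reproducible from (spec, seed) across processes.

What the generator does **not** emulate: BOLD hemodynamics and
autocorrelated physiological noise, between-subject variation in the true
asymmetry (all subjects of a cell share one generating matrix, so
between-subject LI variance is purely sampling noise), site or scanner
effects, and any coupling between demographics and connectivity. Passing
tests therefore demonstrate that the estimators and the inference
machinery behave correctly under the stated model at the design's sample
sizes — not that real VCIND cohorts satisfy that model.

## Statistics

- **Pooled t / Cohen's d.** Student's pooled-variance t with
  df = n₁ + n₂ − 2; d uses the pooled sd with n−1 weights. These are the
  conventions that reproduce the reference trial's printed baseline
  statistics from its rounded summaries; raw-vector and summary entry
  points are algebraically identical. Two constant equal groups define
  t = 0, p = 1 rather than 0/0.
- **χ².** Pearson, *without* Yates continuity correction — with the
  correction the printed 2×2 sex statistic (1.244) is not recovered.
  Cramér's V = √(χ²/(N·min(r−1, c−1))).
- **ANOVA / ANCOVA.** Sums of squares reconstructed from n/mean/sd for
  summary inputs; partial η² = SS_effect/(SS_effect + SS_error). ANCOVA
  is OLS with the group factor and covariates; the HC3 variant reports
  the robust Wald F while partial η² is always the classical one.
- **Partial correlation.** Both variables residualized on the covariates
  (with intercept) by least squares; Pearson r of residuals on
  n − 2 − k df. A variable fully explained by the covariates has partial
  r defined as 0 (its residual is rounding noise).
- **FDR.** Benjamini–Hochberg step-up over an explicitly declared family;
  the family size is never inferred from whatever happens to be
  computed. Mirroring common reporting practice, effects with raw
  p < α that fail correction are emitted with an `uncorrected_only` flag
  rather than dropped.
- **Games–Howell** (Welch df + studentized range) is provided for
  post hocs under variance heterogeneity, via pingouin.

## Mixed model

Training effects are tested on within-subject LI change (post minus
baseline, one row per patient per post-baseline timepoint) with fixed
effects group, time, group × time and the covariates age, sex, education,
mFD, mFC, and a random intercept per participant — "participant as
repeated variable" is read as a random intercept, the most common
interpretation, and the result carries a `df_method` tag. The fit is REML
with the per-subject covariance σ²I + τ²J inverted in closed form and the
criterion profiled over the variance ratio (a robust 1-D optimization).
F tests use Satterthwaite denominator df computed by the delta method
over (τ², σ²) with the variance-parameter covariance from the numerical
REML information matrix, pooling multi-df contrasts through the
eigendecomposition recipe that lmerTest uses; factors are sum-to-zero
coded so the tests are Type-III-style marginal tests. On a synthetic
cohort fixture the implementation reproduces R lmerTest's Type III table
(F, fractional df and p for all three terms) to four decimals, and on
balanced two-timepoint data the interaction F collapses exactly to the
between-group ANOVA on difference scores, which the tests verify.
Attrition is handled naturally (missing sessions are absent rows); a
boundary estimate τ² → 0 is clamped to zero. The session-level covariates
of a change row take their post-session values. Partial η² for mixed-model
terms is approximated as F·df₁/(F·df₁ + df₂).

## Numerical choices and limitations

- Correlation clip 1e−7; LI denominator guard 1e−12; PSD eigenvalue floor
  1e−6; REML variance-ratio search over e^[−12, 12].
- Monte-Carlo problem sizes: operating characteristics use 200–400
  replicate trials (type-I band checked at 400 for a Monte-Carlo error
  ≈ 0.01) and 500 replicates for partial-r recovery; the population-limit
  check uses a single 5000-volume scan.
- The group × time F test is mildly conservative at the design's cell
  sizes (measured type-I ≈ 0.038 across 600 development replicates),
  consistent with Satterthwaite behaviour in small unbalanced designs.
- The reference trial reports its LI magnitudes only graphically, so the
  generator's effect sizes reproduce the qualitative pattern and the
  printed significance bounds, not specific LI values.
- `laterality_index` is scale-invariant but not robust to near-cancelling
  denominators; downstream consumers must respect the `defined` flags.
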