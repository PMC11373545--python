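# Methods

This note documents the models, estimators, numerical choices and
limitations of `protmr`. Notation: j = 1..J indexes genetic instruments;
β̂_Xj ± se_Xj is the instrument's estimated effect on the exposure (a
circulating protein, SD units), β̂_Yj ± se_Yj its effect on the outcome
(log-odds for a binary disease); θ is the causal effect of one SD of the
exposure on the outcome log-odds.

## Structural model behind the synthetic data

The MR generator draws, per instrument,

    γ_j ~ Normal(0, γ_sd²) truncated to |γ_j| ≥ floor
    β̂_Xj ~ Normal(γ_j, se_X²)
    α_j = 0                          with probability 1 − prop_invalid
        ~ Normal(pleio_mean, pleio_sd²) otherwise
    β̂_Yj ~ Normal(θ·γ_j + α_j, se_Y²)

α_j is horizontal pleiotropy: balanced when pleio_mean = 0, directional
otherwise. Because γ and α are drawn independently, the InSIDE condition
holds by construction, so MR-Egger is consistent for θ under directional
pleiotropy in this model. The truncation floor defaults to 0.1·γ_sd — its
only purpose is to rule out degenerate (near-zero) instruments; an absolute
floor can be set instead (`gamma_floor`). Variant metadata (non-palindromic
allele pairs, EAF ~ U(0.05, 0.5), 1 Mb-spaced positions) make the datasets
exercise the harmonization path; simulated instruments carry no LD — LD
pruning and proxy search are tested on hand-built LD matrices instead.

Default scales are chosen to mimic the study setting the package models:
exposure side a pQTL-discovery cohort (n ≈ 5,343, se_X = 0.02, γ_sd = 0.3),
outcome side a large case/control GWAS (n ≈ 184,305, se_Y = 0.02–0.03).
In the full study bundle the instrument-strength floor is 0.13, so
F = (β̂_X/se_X)² spans roughly 40–5,600, matching the strength range the
design assumes (all instruments clear the F > 10 filter).

The mediation generator builds three independent two-sample datasets —
exposure→mediator (θ_EM), mediator→outcome (θ_MO), exposure→outcome with
total effect θ_dir + θ_EM·θ_MO — and records the true proportion mediated
PM = θ_EM·θ_MO / (θ_dir + θ_EM·θ_MO).

The protein-array generator draws log2 intensities Normal(baseline_p,
noise_sd²) with per-protein baselines Normal(10, 1), shifting case samples
of spiked proteins by an assigned log2FC. Defaults mirror the screen the
package models: 640 proteins, 33 cases / 31 controls, 33 spiked proteins at
|log2FC| = 1 and within-group noise 0.5 on the log2 scale. What the
generator does **not** emulate: chip background and inter-chip
normalization artifacts (inputs are assumed vendor-normalized; a per-sample
median-centering utility exists but is off by default), correlated
proteins, heavy-tailed intensity noise, or LD among instruments. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated sampling model, not robustness to those real-data features.

## Differential-expression screen

Tests operate on log2 intensities; log2FC is the difference of group means
(equivalently the log2 ratio of geometric means; a ratio-of-arithmetic-means
variant is available). The DEP rule is p < 0.05 and |log2FC| > 0.263
(2^0.263 ≈ 1.20); BH q-values are computed and reported but deliberately do
not enter the DEP rule, matching the screen's convention. Note the
consequence: with hundreds of null proteins the raw-p rule admits ~3.5% of
them (both thresholds are crossed together once the estimated |log2FC|
exceeds ~2.1 standard errors), so the false fraction among calls can be
large; the q-value column is what controls it.

The moderated test pools each protein's two-group variance (df d = n₁+n₂−2)
and shrinks it toward a prior: s̃² = (d₀s₀² + d s²)/(d₀+d). d₀ solves
trigamma(d₀/2) = Var(log s²) − trigamma(d/2) (method of moments; d₀ = ∞,
i.e. full shrinkage, when the observed spread of log-variances is no larger
than the sampling component), and the prior scale s₀² is estimated on the
log scale so that heavy-tailed variance distributions do not inflate it.
Inference uses t with d + d₀ df. This emulates the empirical-Bayes
moderated t of standard DE tools without importing them; exact replication
is a non-goal.

## Instrument selection and harmonization

Filters are applied in a fixed order — discovery p-value, then F > 10, then
MAF > 0.001 — and each record is labeled with the first criterion it fails,
so status counts partition the input. The default discovery threshold is
0.05/54,469/4,782 ≈ 1.9e-10, the Bonferroni correction for a 54,469-variant
by 4,782-protein pQTL scan; it is configurable. LD pruning is greedy by
descending F (deterministic, standard clumping practice, not graph-optimal)
with r² < 0.2 within 500 kb; a missing r² entry for a required
same-chromosome pair is an error, not a silent pass. Proxy instruments
(r² ≥ 0.8, ties broken by position then id) substitute outcome-missing
variants; the proxy's outcome estimate is used as reported, a documented
limitation since the proxy's orientation relative to the target is not
re-inferred.

Harmonization flips swapped-allele outcome records (β negated, EAF
complemented). Palindromic variants (A/T, C/G) are dropped when either EAF
is missing or lies in (0.42, 0.58) — a common ambiguity window; the design
is otherwise silent on this — and otherwise oriented by whether the two
EAFs sit on the same side of 0.5. Policies `drop` and `keep` are available.

## Estimators

- **Wald ratio** (single instrument): θ̂ = β̂_Y/β̂_X, first-order SE
  se_Y/|β̂_X| (the default in standard practice; a second-order option adds
  the exposure-noise term).
- **IVW**: precision-weighted mean of Wald ratios with w_j = β̂²_Xj/se²_Yj,
  identical to the zero-intercept WLS slope of β̂_Y on β̂_X with weights
  se_Y⁻² (an oracle equivalence asserted in tests against statsmodels).
  Fixed-effect SE (Σw)^(−1/2); the random-effects model inflates it by
  max(1, √(Q/(J−1))) (multiplicative, not additive τ²); `auto` switches to
  random effects when Cochran's Q has p ≤ 0.05. Normal inference.
- **Cochran's Q / I²**: Q = Σw_j(θ̂_j − θ̂)², df J−1 (J−2 around an Egger
  fit), I² = max(0, (Q−df)/Q).
- **MR-Egger**: variants oriented to β̂_X ≥ 0, WLS with intercept, weights
  se_Y⁻², SEs inflated by max(1, √(Q_egger/(J−2))), t(J−2) inference (small-J
  regression convention; IVW keeps normal inference). The intercept ± se is
  the directional-pleiotropy test. A constrained-intercept hook reproduces
  IVW exactly (nested-model identity, tested).
- **Weighted median**: ratios sorted, weights se(θ̂_j)⁻² normalized,
  cumulative midpoint weights p_j = Σ_{k≤j}w_k − w_j/2, estimate by linear
  interpolation at p = 1/2. Consistent when valid instruments carry ≥ half
  the weight.
- **Weighted mode**: argmax of the weighted normal-kernel density of ratios
  over a 512-point grid spanning the ratio range ± 3 bandwidths; bandwidth
  0.9·min(sd, IQR/1.34)·J^(−1/5) times a configurable factor (default 1; the
  appropriate factor for any given application is an open choice). All
  ratios identical is handled by returning that ratio.
- Median and mode SEs come from a seeded parametric bootstrap (default
  1000 draws of β̂*_X, β̂*_Y from their reported SEs, weights recomputed per
  draw); estimates are deterministic given the seed.

P-values are floored at the smallest positive double rather than reported
as 0. Confidence intervals use z = 1.959964; odds ratios are exponentiated
log-odds, never computed on the OR scale.

## Sensitivity suite

Leave-one-out re-runs IVW (auto model) J times plus the all-instrument row.
MR-PRESSO follows the residual-sum-of-squares construction: expected
outcome effects from leave-one-out IVW slopes, observed RSS = Σ w_j(β̂_Yj −
expected_j)² with w = se_Y⁻², a null distribution from parametric
simulation under no pleiotropy (β*_X from the observed effects, β*_Y from
the expectations), empirical p-values with the (1+k)/(n+1) zero-avoiding
correction, per-variant outlier tails Bonferroni-multiplied by J, and an
outlier-corrected IVW. The distortion test (corrected-vs-full slope shift
against random same-size removals) is implemented but optional. Exact
replication of the published tool's internal constants is not claimed; the
construction is mirrored at desk scale. Default n_sim = 1000,
config-exposed (the appropriate value is not prescribed anywhere
authoritative).

## Mediation

Proportion mediated is computed on the log-odds scale: indirect =
β_EM·β_MO, se²_ind = β²_EM·se²_MO + β²_MO·se²_EM, PM = indirect/total with
first-order delta SE treating the three estimates as independent (the legs
come from non-overlapping GWAS — stated as an assumption, not verified from
data). The total effect is the directly estimated exposure→outcome MR, not
direct + indirect reconstruction, so PM is measured against the quantity
the primary analysis reports. Screening requires both leg p-values below
alpha (default 0.05) under univariable IVW; multivariable MR is out of
scope. The published mediation fractions (42.1% and 8.7%) recompute to
~43.4% and ~9.0% from the rounded printed leg estimates — agreement to
printed precision is not possible from rounded inputs, and the package
reports the recomputed values.

## Power

The binary-outcome formula attenuates the causal OR to the observed risk
scale, b = K(OR/(1+K(OR−1)) − 1), sets v = K(1−K) − b² and NCP =
N·R²·b²/(v(1−R²)), and sums both rejection tails, so power equals alpha
exactly at OR = 1. Because the exact variance convention of the
widely used online calculator is not published, the formula is validated
against an individual-level logistic simulation oracle (score test for the
instrument-outcome association; agreement within ±0.05 at n = 20,000,
K = 0.3, OR = 1.3, R² = 0.05 over 2000 replicates, asserted in tests).

## Pipeline and reproducibility

The pipeline applies BH FDR across the proteins actually tested by MR (those
with instruments), not across the full panel — multiplicity is counted
where the causal tests happen. The sensitivity suite runs for
FDR-significant proteins by default (flag to run for all). Every stochastic
component (bootstraps, PRESSO simulations) receives a seed split
deterministically from the run seed via SeedSequence; identical config and
seeds give byte-identical output tables, which is asserted in tests.

Problem sizes in the test suite follow the package's standard study
conditions: the full 640 × 64 panel with 17 instrumented proteins for
end-to-end runs (50 seeded replicates), 2000 replicates for null
calibration of IVW, 100 seeds for MR-PRESSO detection/calibration, and 200
trios for mediation recovery.

## Known limitations

- No multivariable MR, Steiger filtering, radial MR, or
  contamination-mixture estimators; no VCF/BGEN parsing, remote LD lookups,
  or genome-build liftover.
- Proxy orientation is taken as reported (see above).
- The weighted-mode bandwidth factor and MR-PRESSO n_sim are conventions,
  not fitted quantities.
- Under one true discovery among m proteins, the chance that some null
  protein also clears BH at level α is ≈ 1 − (1 − 2α/m)^(m−1) ≈ 1 − e^(−2α)
  (~9.5% at α = 0.05) for any m — "the hit is unique" is therefore a
  ~90%-probability event by construction, a property of BH rather than of
  this implementation.
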