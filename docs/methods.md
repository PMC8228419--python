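# Methods

## Model and estimators

mrwald implements two-sample summary-level Mendelian randomization under
the standard linear structural model. Each instrument *j* is an
additively coded variant with true per-allele effect γ<sub>j</sub> on the
exposure X; the outcome Y depends on X with causal effect θ and may receive
a direct (pleiotropic) effect α<sub>j</sub> from the variant, so the true
per-allele outcome effect is θγ<sub>j</sub> + α<sub>j</sub>. The MR
assumptions are the usual instrumental-variable triple: relevance
(γ<sub>j</sub> ≠ 0), independence from confounders of X–Y, and exclusion
restriction (α<sub>j</sub> = 0).

The per-variant causal estimate is the Wald ratio
θ̂<sub>j</sub> = β̂<sub>Yj</sub>/β̂<sub>Xj</sub>. Its default standard error
is the first-order delta approximation σ<sub>Yj</sub>/|β̂<sub>Xj</sub>|;
a second-order option adds the exposure-noise term
β̂²<sub>Yj</sub>σ²<sub>Xj</sub>/β̂⁴<sub>Xj</sub>. First order is the
default because it makes fixed-effects IVW pooling algebraically identical
to the weighted least-squares slope of outcome betas on exposure betas
through the origin with weights σ<sub>Yj</sub>⁻² (the dominant convention,
and the dual-route identity the test suite verifies against statsmodels
WLS to 1e−10 relative tolerance). An exposure beta of exactly zero is an
error, never an epsilon fudge.

Pooling is fixed-effects inverse-variance weighting; heterogeneity is
Cochran's Q with J−1 degrees of freedom (undefined for a single
instrument). A multiplicative random-effects option — SE inflated by
√(Q/df) when Q/df > 1, point estimate unchanged — is available behind a
flag as a sensitivity analysis; it is deliberately not the default.
Confidence intervals use the 1.96 normal quantile rather than t, and
p-values are two-sided normal, matching summary-level MR practice where
the inputs are themselves asymptotically normal GWAS estimates.

Per-SD rescaling multiplies estimate, SE and CI bounds by the exposure SD;
the z-score and p-value are invariant. The SD is taken on whichever scale
the exposure betas use (for the reference scenario, 0.25 on the log scale);
rescaling before or after pooling is algebraically identical for a shared
scalar, and the pipeline rescales after. Rescaling twice is a state error.
Log-odds results can be exponentiated to odds ratios; exponentiating a
linear-scale estimate is refused.

## Harmonization

Outcome records are aligned to the exposure's effect-allele orientation:
identical orientation copies the beta; swapped labels negate it and
complement the frequency; a strand-complement coding (A/G vs T/C) is first
mapped onto the exposure strand — a standard convenience beyond the
minimal rule set, since such pairs are scientifically compatible.
Palindromic pairs (A/T, C/G) carry no strand information in their labels,
so they are oriented purely by effect-allele frequency, and only when both
frequencies are present and informative: the minor-allele frequency on
both sides must not exceed the ambiguity threshold (default 0.42 —
near 0.5 the two strand readings are statistically indistinguishable).
Ambiguous or frequency-less palindromes are dropped; strand is never
guessed. Every drop and sign flip is logged at WARNING. Duplicated rsids
are an error rather than first-wins, because IVW weights are per-variant.
Harmonization is idempotent, and the suite checks sign consistency
(swapping outcome alleles while negating the beta is a no-op).

## Instrument selection and diagnostics

Selection keeps candidates with p strictly below the threshold (default
5×10⁻⁸). "Uncorrelated" instruments are operationalized as one per locus
label (cytoband or gene-region string) — the smallest-p candidate per
locus, ties broken by smaller SE then rsid — because the package works
from summary statistics only and consults no LD reference panel; this is
a documented stand-in, not an LD r² criterion. Variance explained
(2p(1−p)β²/Var(X)) requires the trait variance as an explicit input, and
the F-statistic follows from r², n and k. The confounder screen flags
instruments with table associations at p < 0.01 against a configurable
trait list whose default covers established risk factors for low BMD and
fracture: body mass index, fat-free soft tissue body mass, height, type 2
diabetes, smoking, alcohol consumption, estrogens, testosterone, cortisol.
The screen reads a local table; no live database is queried.

## Synthetic data generator

The generator simulates *summary statistics directly*: estimated betas are
drawn normal around their true values with analytic standard errors —
se<sub>X</sub> = √(Var(X)/(2p(1−p)n<sub>X</sub>)) for a continuous trait
and se<sub>Y</sub> = 1/√(2p(1−p)n v(1−v)) on the log-odds scale for a
case–control outcome with case fraction v. This matches the two-sample
summary-level scope exactly, makes the SEs correct by construction, and is
orders of magnitude faster than genotype-level simulation. What it does
*not* emulate: LD between instruments, sample overlap between the two
GWASs, selection of instruments on their estimated significance (winner's
curse), allele-frequency mismatch between cohorts, and non-normal
finite-sample behaviour of the underlying GWAS estimators. Passing tests
therefore validate the estimators and plumbing under the stated sampling
model, not robustness to those real-data pathologies.

Per-variant exposure effects are drawn uniform on a configurable range
(uniform, not normal, so instrument-strength bounds are explicit), and
frequencies uniform within [0.05, 0.95]; both can be pinned explicitly.
The single RNG stream is seeded once and sub-draws occur in a fixed order
(frequencies, γ, α, β<sub>X</sub>, β<sub>Y</sub>, allele assignment, swap
selection), so output is bit-reproducible. A configurable fraction of
outcome records is emitted with swapped allele labels (beta negated,
frequency complemented) to exercise harmonization, and a fraction of
variants receives palindromic allele pairs.

### Reference scenario

The default configuration encodes the study conditions of a published
three-instrument analysis of circulating α-tocopherol against heel eBMD
and fracture: exposure GWAS n = 7781 on log α-tocopherol with SD 0.25
(variance 0.0625); instruments rs964184 (C/G — palindromic, frequency
0.14), rs2108622 (T/C, 0.29) and rs11057830 (A/G, 0.15); continuous
outcome n = 426,824; binary outcome 53,184 cases / 373,611 controls. The
per-variant exposure effects are recovered from the instruments' published
exposure p-values (|z| = Φ⁻¹(1 − p/2) times the analytic SE at each
frequency), which implies a total variance explained of ≈1.6%, consistent
with the ≈1.7% reported for the source GWAS. The true causal effects are
set to the effects the scenario emulates: 0.28 standardized-eBMD units per
log-unit (0.07 per SD) and log(0.97)/0.25 per log-unit on the odds scale.

The continuous outcome is simulated with phenotypic variance 1
(standardized eBMD). This is a deliberate calibration: with eBMD in raw
g/cm² units (SD ≈ 0.11) the analytic pooled SE would be several-fold
smaller than the precision the emulated study reports, whereas a
standardized outcome reproduces it (pooled per-SD SE ≈ 0.012); the
pipeline reports the per-SD estimate on the conventional g/cm² scale of
presentation. The original per-variant association table is not
redistributed; everything above is reconstructed from design parameters,
and all scenario-based checks are consistency checks, not replications
from the source data.

## Numerical choices and calibration behaviour

- Report rounding is half-away-from-zero at 2 decimals (presentation
  layer only; machine-readable outputs are full precision and re-runs are
  byte-identical).
- Weight shares in forest tables are exact inverse-variance fractions and
  sum to 100 within 1e−9.
- Simulated p-values are floored at 1e−300 to stay inside (0, 1].
- At moderate instrument strength (mean F ≈ 40–60) the first-order Wald
  ratio inherits a finite-sample bias of order θ/F from exposure-side
  noise (downward after IVW weighting, since weights correlate with the
  estimated exposure betas). The recovery test asserts mean recovery
  within that analytic envelope plus Monte-Carlo error, and separately
  verifies that the bias disappears (within Monte-Carlo error) when
  instruments are strong.
- First-order CIs are calibrated only where outcome-side noise dominates
  the ratio. The true per-variant ratio SD is inflated over the nominal
  σ<sub>Y</sub>/|γ| by roughly √(1 + θ²σ²<sub>X</sub>/σ²<sub>Y</sub>),
  a factor independent of instrument strength. In a balanced two-sample
  design (comparable GWAS sizes) or under the null (θ = 0) this factor is
  ≈1 and empirical 95% coverage is nominal (≈0.95 in the suite's
  1000-replicate experiments). In the asymmetric study-like design
  (exposure n = 7781 against outcome n ≈ 427k, θ = 0.28) the factor is
  ≈1.17 and first-order intervals undercover (≈0.91 measured; ≈0.92 with
  second-order SEs, which remove the SE deficit but not the weighting
  bias). The suite asserts nominal coverage in the balanced and null
  regimes and asserts — and thereby documents — the undercoverage in the
  exposure-noise-dominated regime.
- Cochran's Q under homogeneity is calibrated: the 0.05-level rejection
  rate over 2000 replicates matches nominal within binomial tolerance.

## Problem sizes

The acceptance computation uses 300 replicate studies for the reference
scenario means, 1000 datasets (J = 10) for recovery and coverage, 2000
replicates for Q calibration, and 100 random instrument sets for the
regression-equivalence check; the full test suite and the acceptance
script each run in well under a minute on one CPU.

## Known limitations

- No LD modelling, clumping, or reference panels; "uncorrelated" is
  by locus label only.
- No MR-Egger, weighted-median or other pleiotropy-robust estimators:
  with very few instruments (three, in the reference scenario) those
  methods are not meaningfully estimable, and they are out of scope here.
- The generator's idealizations listed above; in particular, two-sample
  independence is assumed, never checked.
- Binary-outcome SEs use the standard log-odds approximation; rare-disease
  or unbalanced designs with small case counts may be less well
  approximated.
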