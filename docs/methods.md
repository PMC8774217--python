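# Methods

## Scoring the S-GUS

The S-GUS is a 12-item usability questionnaire scored per
patient-device record on 0–50 points. Items 1–9 carry one subscore
each (items 1–3 probe previous inhaler experience, items 4–9
"at a glance" preference and satisfaction), items 10–11 grade the
objectively observed handling/actuation difficulty with strictly
decreasing subscores, and item 12 awards a fixed constant (3.2) when
the patient's self-assessment agrees with the supervising nurse's
judgment, else 0.

The instrument's full per-item subscore table is not publicly
available. The shipped default (`sgus_ic.scoring.default_scoring_config`)
is therefore a declared stand-in chosen to satisfy every published
constraint — item maxima summing to exactly 50, item-12 constant 3.2,
strictly decreasing difficulty grades for items 10–11 (four levels
each) — with simple values elsewhere (2.0 for items 1–3, 3.0 for items
4–9, 10/6.6/3.3/0 and 12.8/8.5/4.3/0 for items 10–11). Any study using
the real instrument should supply its table as a YAML config
(`examples/scoring_config.yaml` shows the schema); `validate_config`
enforces the invariants and returns violations rather than raising, so
configs can be linted. Totals are written with one decimal.

## The indirect-comparison model

The source design writes a contrast-level likelihood (per-patient
device contrasts with patient-specific contrast variances). With one
observation per patient-device pair that formulation is unidentifiable
and ambiguous — a patient main effect cancels in within-patient
contrasts — so we implement the equivalent arm-level model

    Y_sd = μ + δ_d + u_s + ε_sd,  u_s ~ N(0, τ²),  ε_sd ~ N(0, σ²),

with a single shared residual variance. This yields the same
estimands: absolute device means (μ + δ_d) *and* all pairwise AMDs
(δ_i − δ_j), exactly the two quantities the published summary table
reports. Consistency across comparison loops holds identically at the
draw level because effects, not contrasts, are sampled; multi-arm
correlation is induced by the shared u_s.

Priors: N(0, 10⁴) on μ and each δ_d; Uniform(0, 5) on σ and τ (the
variances are therefore bounded by 25 points², ample for a 0–50
instrument with the observed spread). Reference device: Breezhaler,
tested by all 33 patients — the choice affects no AMD and is
overridable.

### Sampler

Gibbs, with every update exact:

* (μ, δ): joint multivariate-normal conditional (6×6 solve); the joint
  block removes the strong μ–δ coupling a one-at-a-time scan would
  mix slowly through.
* u_s: independent normal conditionals.
* σ, τ: with a uniform prior on the SD, the conditional of the
  variance is inverse-gamma((n−1)/2, SS/2) truncated to (0, 25);
  sampled by inverse-CDF of the corresponding truncated gamma on the
  precision (`scipy.special.gammaincinv`), so the Uniform(0, 5)
  support is respected without rejection. n = 0 returns a prior draw
  (this is what makes the empty-dataset prior-recovery check work);
  n = 1 falls back to a fine-grid inverse CDF.

Default schedule: one chain, 100,000 iterations, 50,000 burn-in,
thinning 1, seeded `numpy.random.default_rng`. An optional multi-chain
mode (over-dispersed initial μ, `split_rhat` diagnostic) exists but is
off by default. Ties in pairwise probabilities are split 50/50 and
ranking ties break by device-id order — both measure-zero for
continuous draws, fixed for reproducibility on degenerate inputs.

### Verification

`conjugate_oracle` computes the exact Gaussian posterior of (μ, δ) for
*fixed* σ and τ by generalised least squares (V = σ²I + τ²ZZ'); the
test suite requires the sampler to match it within 3 batch-means
Monte-Carlo standard errors. Coverage is validated end to end: on 100
synthetic cohorts of the study design the 90% CrIs for the 15 AMDs
cover the generating truth at 87.9% (the validation script and the
acceptance test accept 85–95%), using a reduced 10,000/5,000 schedule
per cohort to keep the full check around a minute. Prior recovery on
an empty dataset reproduces Uniform(0, 5) for both SDs
(Kolmogorov–Smirnov).

## Ranking, classification, heterogeneity

Rank 1 = highest μ + δ_d in a draw (higher S-GUS is better). SUCRA_d
is the mean of the cumulative rank distribution over ranks 1..D−1;
identities ΣP(rank r) = 1 per device and per rank and Σ SUCRA = D/2
hold exactly. Classification uses the published 15-point rule with a
strict inequality (mean > 15 → "good to pretty good"). I² is computed
per draw as τ²/(τ²+σ²) and summarized by its posterior mean and 90%
CrI; total variance is the posterior mean of τ²+σ². The single
published I² figure does not state its summary functional; the
posterior mean is used.

## Synthetic cohorts

`default_study_spec` encodes the study conditions: groups of 18 and
15, device subsets {B,S,E,N} / {B,S,T,D}, generating means at the
published posterior point estimates (B 9.0, D 25.1, E 28.5, N 12.2,
S 20.6, T 14.3 points), τ = 4, σ = 3 (implying I² ≈ 0.64, near the
published 67.4%), and demographic margins equal to the published
baseline frequencies. Ages are Normal(16.4, 2.0) truncated to
[11, 17.99] years (the cohort is under 18). Covariates are sampled
independently per patient from group-specific margins — only margins
are published, so no dependence structure is emulated; baseline tests
on synthetic cohorts therefore exercise the machinery, not any real
group imbalance. Truncation of scores to [0, 50] is **off** by default
so that generated data follow the model exactly (the instrument is
bounded but the model is unbounded normal); switch it on for realism
demonstrations. Passing model-validation tests on these cohorts shows
the inference machinery is correct under its own assumptions; it
cannot show that real S-GUS data satisfy them (normality, shared σ,
margin-only demographics).

## Baseline statistics

Fisher's exact test for 2×2 rows uses exact rational arithmetic over
the conditional hypergeometric null. The default p-value is the
**one-sided lower-tail** probability of the Group-1 count: exact
enumeration shows this convention reproduces all four verifiable
published baseline p-values (0.107, 0.295, 0.355, 0.71), while the
common two-sided rule does not; the two-sided variant
(probability-ordering) is exposed alongside. For r×c tables
(region, education) the Freeman–Halton probability-ordering test is
enumerated exactly; the published region p-value (0.199) reproduces
under it, the education one does not, so only the verified value is
asserted in tests. The Wilcoxon rank-sum test enumerates the full
permutation null for combined n ≤ 20 (midranks handle ties) and
otherwise uses the normal approximation with tie and continuity
corrections; the two agree within 0.02 at the boundary.

## Sample size

For each pair of usability classes (good 26, 95% interval 21–32;
pretty good 20, 15–25; insufficient 11, 8–13) the two-sample
normal-approximation formula gives
n/group = ⌈2(z₁₋α/2 + z_power)²σ²_pooled/Δ²⌉ with per-class SD =
interval width / (2·1.96) and pooled SD the root mean square; the
recommended enrolment is the maximum total over comparisons. The
originally reported minimum of 28 cannot be reproduced under any
convention we tested (the original algorithm's SD rule, sidedness and
rounding are unstated); the module documents its own explicit rule
(every piece configurable) rather than claiming to match.

## Problem sizes and numerics

Default analysis runs use the full 100,000-iteration schedule
(seconds on one core at n = 33). Validation sweeps use 10,000/5,000
per cohort × 100 cohorts — enough for coverage estimation to a few
percent. Degenerate inputs are handled explicitly: empty datasets
return prior draws, τ → 0 collapses patient effects to zero, residual
sums of squares are floored at 1e−12 to avoid a degenerate
inverse-gamma when data are exactly collinear.

## Known limitations

* The default subscore table is a stand-in; absolute totals from it
  are not comparable with studies using the real instrument.
* One observation per patient-device: σ and τ are separated only
  through the incomplete-block replication, so their individual
  posteriors are sensitive to the Uniform(0, 5) bound on small
  cohorts.
* No meta-regression on covariates, no node-splitting inconsistency
  assessment, no item-level simulation (the generator emits device
  totals directly).
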