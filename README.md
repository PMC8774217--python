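# sgus-ic

Bayesian indirect comparison of dry-powder-inhaler (DPI) usability in
asthma adolescents, built around the 12-item short-form Global
Usability Score (S-GUS, 0–50 points, higher = more usable).

## The problem

Adolescents with persistent asthma handle different inhalers with very
different ease, and usability — not just the drug — drives adherence.
In the motivating study design, 33 adolescents each test four of six
DPIs (Breezhaler, Diskus, Ellipta, Nexthaler, Spiromax, Turbohaler):
Group 1 (n = 18) tests Breezhaler/Spiromax/Ellipta/Nexthaler, Group 2
(n = 15) tests Breezhaler/Spiromax/Turbohaler/Diskus. No patient tests
all six, so the devices are compared *indirectly* through the evidence
network of shared within-patient comparisons (Breezhaler–Spiromax is
tested by all 33).

## The model

For patient *s* and device *d*,

```
Y_sd = μ + δ_d + u_s + ε_sd,   u_s ~ N(0, τ²),   ε_sd ~ N(0, σ²),
```

with δ_ref ≡ 0 (reference: Breezhaler). The absolute mean difference
(AMD) between devices *i* and *j* is δ_i − δ_j. Priors are vague:
N(0, 10⁴) on μ and each δ_d, Uniform(0, 5) on σ and τ. Sampling is a
Gibbs scheme — exact joint multivariate-normal updates for (μ, δ),
normal conditionals for u_s, and exact truncated inverse-gamma
inverse-CDF updates for σ and τ — run as one chain of 100,000
iterations with 50,000 burn-in; summaries use posterior means and 90%
credible intervals (5th/95th percentiles). Devices are ranked per draw
by μ + δ_d and condensed into SUCRA (surface under the cumulative
ranking curve); heterogeneity is decomposed per draw as
I² = τ²/(τ² + σ²). Devices with posterior mean S-GUS > 15 points are
classed "good to pretty good", otherwise "insufficient".

The patient-level data of the original study are not shareable, so the
package includes a generator for synthetic cohorts with exactly this
design (`sgus_ic.cohort`), plus the baseline statistics (exact Fisher
and Wilcoxon tests) and the power-based sample-size rule.

## Worked example

```
sgus-ic simulate --seed 3 --out cohort/
sgus-ic analyze --scores cohort/scores.csv --demographics cohort/demographics.csv \
    --out report/ --seed 5 --iterations 20000 --burnin 10000
```

or run the scripted analysis end to end:

```
python analysis/01_simulate_cohort.py
python analysis/02_baseline_table.py
python analysis/03_fit_indirect_comparison.py
python analysis/04_model_validation.py
python analysis/05_sample_size.py
```

The fit step prints, for a default synthetic cohort (generating means
at the published point estimates, τ = 4, σ = 3):

```
devices, best to worst:
            mean_sgus  cri_lower  cri_upper  sucra                class
Ellipta         29.11      27.17      31.05   1.00  good to pretty good
Diskus          25.33      23.29      27.35   0.80  good to pretty good
Spiromax        21.49      19.87      23.10   0.60  good to pretty good
Turbohaler      13.51      11.47      15.54   0.35         insufficient
Nexthaler       12.52      10.57      14.46   0.24         insufficient
Breezhaler      10.49       8.85      12.12   0.01         insufficient

total variance 31.38 points^2; I^2 = 63.5% (90% CrI 53.5 to 71.3)
```

i.e. the posterior mean S-GUS per device with its 90% CrI, the SUCRA
rank surface (1 = certainly best), the 15-point usability class, and
the share of variability attributable to between-patient differences.
`report/table2.csv` holds the full cross-table: device estimates on
the diagonal (ordered by SUCRA), AMDs with CrIs in the lower triangle,
and posterior probabilities that the row device beats the column
device in the upper triangle.

`analysis/04_model_validation.py` verifies the sampler against a
closed-form conjugate posterior, measures 90%-CrI coverage of all 15
AMDs across 100 simulated studies (87.9% at the reduced 10k/5k
schedule), and checks that an empty dataset returns the Uniform(0, 5)
SD priors.

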