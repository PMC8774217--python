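#!/usr/bin/env python
"""Generate the synthetic study cohort.

Emulates the study design the downstream analyses assume: 33 asthma
adolescents in two groups (18 testing Breezhaler/Spiromax/Ellipta/
Nexthaler, 15 testing Breezhaler/Spiromax/Turbohaler/Diskus), device
means at the published point estimates, patient-effect SD 4 and
residual SD 3, demographics drawn from the published baseline margins.

Writes results/cohort/{scores,demographics}.csv and provenance.json.
"""

from sgus_ic.cohort import default_study_spec, generate

SEED = 20260924

spec = default_study_spec(seed=SEED)
cohort = generate(spec)
cohort.write("results/cohort")

print(f"cohort: {len(cohort.demographics)} patients, {len(cohort.scores)} scores")
print(cohort.scores.groupby("device_id")["sgus_total"].agg(["count", "mean"]).round(2))
print("written to results/cohort/")
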