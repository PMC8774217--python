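"""Synthetic cohorts with the study's incomplete-block design.

The original patient-level data are not public, so this module
generates cohorts with the same design and the statistical structure
the indirect-comparison model assumes: two groups of patients, each
testing a four-device subset of the six inhalers (both groups share
Breezhaler and Spiromax), with per-device S-GUS totals

    score(s, d) = mu_d + u_s + eps_{s,d},
    u_s ~ Normal(0, tau_true^2),  eps ~ Normal(0, sigma_true^2),

optionally clamped to the instrument's [0, 50] range.  Demographics are
sampled from group-specific margins (sex, prior inhaler experience,
region of origin, education level, age); only margins are emulated, not
any dependence between covariates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEVICES",
    "GroupDesign",
    "DemographicsMargins",
    "SimulationSpec",
    "SyntheticCohort",
    "default_study_spec",
    "generate",
]

#: Canonical names of the six dry powder inhalers under comparison.
DEVICES = ("Breezhaler", "Diskus", "Ellipta", "Nexthaler", "Spiromax", "Turbohaler")

#: Posterior point estimates used as the default generating device means
#: (points on the 0-50 S-GUS scale), one per device in DEVICES order.
DEFAULT_DEVICE_MEANS = {
    "Breezhaler": 9.0,
    "Diskus": 25.1,
    "Ellipta": 28.5,
    "Nexthaler": 12.2,
    "Spiromax": 20.6,
    "Turbohaler": 14.3,
}


@dataclass(frozen=True)
class DemographicsMargins:
    """Per-group marginal probabilities for the baseline covariates."""

    p_male: float
    p_instructed_dpi: float
    p_instructed_mdi: float
    p_instructed_smi: float
    region_probs: dict[str, float]
    education_probs: dict[str, float]
    age_mean: float = 16.4
    age_sd: float = 2.0
    age_min: float = 11.0
    age_max: float = 17.99


@dataclass(frozen=True)
class GroupDesign:
    name: str
    devices: tuple[str, ...]
    n: int
    margins: DemographicsMargins


@dataclass(frozen=True)
class SimulationSpec:
    devices: tuple[str, ...] = DEVICES
    groups: tuple[GroupDesign, ...] = ()
    device_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEVICE_MEANS)
    )
    tau_true: float = 4.0
    sigma_true: float = 3.0
    truncate: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("spec must define at least one group")
        for g in self.groups:
            if g.n < 1:
                raise ValueError(f"group {g.name!r}: size must be >= 1")
            unknown = set(g.devices) - set(self.devices)
            if unknown:
                raise ValueError(
                    f"group {g.name!r}: unknown device id(s) {sorted(unknown)}"
                )
        missing_mu = set(
            d for g in self.groups for d in g.devices
        ) - set(self.device_means)
        if missing_mu:
            raise ValueError(f"no generating mean for device(s) {sorted(missing_mu)}")
        if self.tau_true < 0 or self.sigma_true < 0:
            raise ValueError("tau_true and sigma_true must be >= 0")


@dataclass(frozen=True)
class SyntheticCohort:
    """Scores + demographics tables plus a provenance record.

    ``scores`` has columns ``patient_id, device_id, sgus_total``;
    ``demographics`` has one row per patient with group membership,
    sex, age, prior-inhaler flags, region, and education.
    """

    scores: pd.DataFrame
    demographics: pd.DataFrame
    provenance: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(outdir / "scores.csv", index=False)
        self.demographics.to_csv(outdir / "demographics.csv", index=False)
        (outdir / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True) + "\n"
        )


def default_study_spec(seed: int = 0) -> SimulationSpec:
    """The study's design: 18 + 15 patients, Table-1 demographic margins.

    Group 1 (n=18) tests Breezhaler, Spiromax, Ellipta, Nexthaler;
    Group 2 (n=15) tests Breezhaler, Spiromax, Turbohaler, Diskus.
    Marginal probabilities reproduce the observed baseline frequencies
    (e.g. 7/18 and 10/15 male; 8/18 and 9/15 previously instructed to
    dry powder inhalers).
    """
    g1 = GroupDesign(
        name="Group 1",
        devices=("Breezhaler", "Spiromax", "Ellipta", "Nexthaler"),
        n=18,
        margins=DemographicsMargins(
            p_male=7 / 18,
            p_instructed_dpi=8 / 18,
            p_instructed_mdi=5 / 18,
            p_instructed_smi=1 / 18,
            region_probs={"North": 15 / 18, "Center": 0.0, "South and Islands": 3 / 18},
            education_probs={"Lower secondary": 15 / 18, "Upper secondary": 3 / 18},
        ),
    )
    g2 = GroupDesign(
        name="Group 2",
        devices=("Breezhaler", "Spiromax", "Turbohaler", "Diskus"),
        n=15,
        margins=DemographicsMargins(
            p_male=10 / 15,
            p_instructed_dpi=9 / 15,
            p_instructed_mdi=6 / 15,
            p_instructed_smi=1 / 15,
            region_probs={"North": 10 / 15, "Center": 3 / 15, "South and Islands": 2 / 15},
            education_probs={"Lower secondary": 11 / 15, "Upper secondary": 4 / 15},
        ),
    )
    return SimulationSpec(groups=(g1, g2), seed=seed)


def _sample_categorical(rng: np.random.Generator, probs: dict[str, float], n: int):
    labels = list(probs)
    p = np.asarray([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=n, p=p)


def _sample_ages(rng: np.random.Generator, m: DemographicsMargins, n: int):
    a = (m.age_min - m.age_mean) / m.age_sd
    b = (m.age_max - m.age_mean) / m.age_sd
    u = rng.uniform(size=n)
    return stats.truncnorm.ppf(u, a, b, loc=m.age_mean, scale=m.age_sd)


def generate(spec: SimulationSpec) -> SyntheticCohort:
    """Draw a cohort from ``spec``; fully reproducible given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    score_rows = []
    demo_rows = []
    pid = 0
    for g in spec.groups:
        for _ in range(g.n):
            pid += 1
            patient = f"P{pid:03d}"
            u_s = rng.normal(0.0, spec.tau_true) if spec.tau_true > 0 else 0.0
            for d in g.devices:
                eps = rng.normal(0.0, spec.sigma_true) if spec.sigma_true > 0 else 0.0
                y = spec.device_means[d] + u_s + eps
                if spec.truncate:
                    y = float(np.clip(y, 0.0, 50.0))
                score_rows.append((patient, d, y))
            m = g.margins
            demo_rows.append(
                {
                    "patient_id": patient,
                    "group": g.name,
                    "sex": "male" if rng.uniform() < m.p_male else "female",
                    "age": float(_sample_ages(rng, m, 1)[0]),
                    "instructed_dpi": int(rng.uniform() < m.p_instructed_dpi),
                    "instructed_mdi": int(rng.uniform() < m.p_instructed_mdi),
                    "instructed_smi": int(rng.uniform() < m.p_instructed_smi),
                    "region": str(_sample_categorical(rng, m.region_probs, 1)[0]),
                    "education": str(_sample_categorical(rng, m.education_probs, 1)[0]),
                }
            )

    scores = pd.DataFrame(score_rows, columns=["patient_id", "device_id", "sgus_total"])
    demographics = pd.DataFrame(demo_rows)
    provenance = {
        "seed": spec.seed,
        "tau_true": spec.tau_true,
        "sigma_true": spec.sigma_true,
        "truncate": spec.truncate,
        "device_means": dict(spec.device_means),
        "groups": [
            {"name": g.name, "n": g.n, "devices": list(g.devices)} for g in spec.groups
        ],
    }
    return SyntheticCohort(scores=scores, demographics=demographics, provenance=provenance)
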