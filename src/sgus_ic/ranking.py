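"""Device ranking (SUCRA), usability classification, and heterogeneity.

Rank probabilities are empirical: in each posterior draw the devices
are ordered by their absolute mean usability mu + delta_d, descending,
so rank 1 is the most usable device in that draw.  SUCRA (surface
under the cumulative ranking curve) condenses the rank distribution of
device d into

    SUCRA_d = (1 / (D - 1)) * sum_{r=1}^{D-1} F_d(r),

where F_d(r) = P(rank_d <= r); 1 means certainly best, 0 certainly
worst, 0.5 uninformative.  Heterogeneity is decomposed per draw into
the between-patient variance tau^2 and residual variance sigma^2, with
I^2 = tau^2 / (tau^2 + sigma^2) the proportion of total variability
attributable to between-patient differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sgus_ic.model import PosteriorDraws, PosteriorSummary

__all__ = [
    "RankingSummary",
    "HeterogeneitySummary",
    "rank_probabilities",
    "cumulative_ranking",
    "sucra",
    "ranking_summary",
    "classify_usability",
    "heterogeneity",
]

GOOD_LABEL = "good to pretty good"
INSUFFICIENT_LABEL = "insufficient"

#: S-GUS threshold (points) separating acceptable from insufficient usability.
USABILITY_THRESHOLD = 15.0


@dataclass(frozen=True)
class RankingSummary:
    device_ids: tuple[str, ...]
    rank_probs: pd.DataFrame      # devices x ranks, entries P(device has rank r)
    cumulative: pd.DataFrame      # devices x ranks, F_d(r) = P(rank <= r)
    sucra: pd.Series              # per device, in [0, 1]

    @property
    def order(self) -> list[str]:
        """Devices from best (highest SUCRA) to worst."""
        return list(self.sucra.sort_values(ascending=False).index)


@dataclass(frozen=True)
class HeterogeneitySummary:
    tau2_mean: float
    sigma2_mean: float
    total_variance: float
    i2_mean: float
    i2_lower: float
    i2_upper: float
    level: float

    def as_dict(self) -> dict:
        return {
            "tau2_mean": self.tau2_mean,
            "sigma2_mean": self.sigma2_mean,
            "total_variance": self.total_variance,
            "i2_mean": self.i2_mean,
            "i2_lower": self.i2_lower,
            "i2_upper": self.i2_upper,
            "level": self.level,
        }


def _ranks_per_draw(draws: PosteriorDraws) -> np.ndarray:
    """Rank (1 = most usable) of every device in every draw.

    Ties broken deterministically by device-id order (measure-zero for
    continuous draws; fixed order keeps reruns identical).
    """
    values = draws.absolute
    # argsort on (-value, device index): stable sort breaks ties by id order
    order = np.argsort(-values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    n, d = order.shape
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(1, d + 1)
    return ranks


def rank_probabilities(draws: PosteriorDraws) -> pd.DataFrame:
    """P(device d has rank r) for r = 1..D; rank 1 = highest usability."""
    if draws.n_draws == 0:
        raise ValueError("no draws")
    d = len(draws.device_ids)
    if d < 2:
        raise ValueError("ranking needs at least 2 devices")
    ranks = _ranks_per_draw(draws)
    probs = np.zeros((d, d))
    for k in range(d):
        probs[k] = np.bincount(ranks[:, k], minlength=d + 1)[1:] / draws.n_draws
    return pd.DataFrame(
        probs,
        index=pd.Index(draws.device_ids, name="device_id"),
        columns=pd.Index(range(1, d + 1), name="rank"),
    )


def cumulative_ranking(rank_probs: pd.DataFrame) -> pd.DataFrame:
    """F_d(r) = P(rank of d <= r); the curves behind the SUCRA surface."""
    return rank_probs.cumsum(axis=1)


def sucra(rank_probs: pd.DataFrame) -> pd.Series:
    """SUCRA_d = mean of the cumulative ranking curve over ranks 1..D-1."""
    d = rank_probs.shape[1]
    if d < 2:
        raise ValueError("SUCRA needs at least 2 devices")
    cum = cumulative_ranking(rank_probs)
    out = cum.iloc[:, : d - 1].sum(axis=1) / (d - 1)
    out.name = "sucra"
    return out


def ranking_summary(draws: PosteriorDraws) -> RankingSummary:
    probs = rank_probabilities(draws)
    return RankingSummary(
        device_ids=draws.device_ids,
        rank_probs=probs,
        cumulative=cumulative_ranking(probs),
        sucra=sucra(probs),
    )


def classify_usability(
    summary: PosteriorSummary, threshold: float = USABILITY_THRESHOLD
) -> pd.Series:
    """Label each device by its posterior mean S-GUS.

    Strictly above ``threshold`` (default 15 points) is "good to pretty
    good"; at or below is "insufficient".
    """
    table = summary.device_table.set_index("device_id")
    labels = np.where(
        table["mean_sgus"] > threshold, GOOD_LABEL, INSUFFICIENT_LABEL
    )
    return pd.Series(labels, index=table.index, name="usability_class")


def heterogeneity(draws: PosteriorDraws, level: float = 0.90) -> HeterogeneitySummary:
    """Variance decomposition and I^2 from the SD draws.

    I^2 is computed per iteration as tau^2 / (tau^2 + sigma^2) and
    summarized by its posterior mean and quantile CrI; total variance
    is the posterior mean of tau^2 + sigma^2.  Draws where both SDs are
    zero contribute I^2 = 0 (no variability to apportion).
    """
    if draws.n_draws == 0:
        raise ValueError("no draws")
    tau2 = draws.tau**2
    sigma2 = draws.sigma**2
    total = tau2 + sigma2
    with np.errstate(invalid="ignore", divide="ignore"):
        i2 = np.where(total > 0, tau2 / np.where(total > 0, total, 1.0), 0.0)
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    return HeterogeneitySummary(
        tau2_mean=float(tau2.mean()),
        sigma2_mean=float(sigma2.mean()),
        total_variance=float(total.mean()),
        i2_mean=float(i2.mean()),
        i2_lower=float(np.quantile(i2, lo_q)),
        i2_upper=float(np.quantile(i2, hi_q)),
        level=level,
    )
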