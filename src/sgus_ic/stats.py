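"""Baseline-table statistics and the power-based sample-size rule.

Group comparisons for the baseline table use exact tests throughout:
Fisher's exact test by hypergeometric enumeration for categorical
variables (exact rational arithmetic internally) and the Wilcoxon
rank-sum test for age, with the exact permutation null enumerated for
small samples.

The default Fisher p-value is the one-sided lower-tail probability
P(X <= a) of the Group-1 count under the conditional hypergeometric
null.  That convention reproduces all four verifiable published
baseline p-values for this study design; the common two-sided rule
(sum of outcomes no more probable than observed) is also provided.

Sample size follows the classical two-sample normal-approximation
formula: for each pair of usability classes with mean difference
``delta`` and pooled SD ``sd``,

    n per group = ceil( 2 * (z_{1-alpha/2} + z_{power})^2 * sd^2 / delta^2 ),

with per-class SDs derived from the reported 95% intervals
(half-width / 1.96 by default; the divisor is configurable because the
original derivation is not fully specified).  The final recommended
enrolment is the maximum total over the pairwise comparisons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FourfoldTable",
    "UsabilityClass",
    "PowerSpec",
    "SampleSizeResult",
    "fisher_exact_one_sided",
    "fisher_exact_two_sided",
    "fisher_exact_rxc",
    "wilcoxon_rank_sum",
    "sample_size",
    "baseline_table",
]


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 counts: (a, b) = Group 1 yes/no, (c, d) = Group 2 yes/no."""

    a: int
    b: int
    c: int
    d: int

    def validate(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both group sizes must be positive")
        if self.a + self.c == 0 or self.b + self.d == 0:
            raise ValueError("both outcome margins must be positive")


def _hypergeom_pmf_exact(table: FourfoldTable) -> tuple[int, int, int, list[Fraction]]:
    """Exact hypergeometric pmf over the support of the Group-1 count.

    Conditions on all margins: X = Group-1 yes-count, N total, K total
    yes, n Group-1 size.  Returns (k_min, k_max, a, pmf list).
    """
    table.validate()
    n1 = table.a + table.b
    k_yes = table.a + table.c
    n_tot = n1 + table.c + table.d
    k_min = max(0, n1 - (n_tot - k_yes))
    k_max = min(n1, k_yes)
    denom = math.comb(n_tot, n1)
    pmf = [
        Fraction(math.comb(k_yes, k) * math.comb(n_tot - k_yes, n1 - k), denom)
        for k in range(k_min, k_max + 1)
    ]
    return k_min, k_max, table.a, pmf


def fisher_exact_one_sided(table: FourfoldTable) -> float:
    """Lower-tail exact p-value P(X <= a) on the Group-1 count."""
    k_min, _k_max, a, pmf = _hypergeom_pmf_exact(table)
    p = sum(pmf[: a - k_min + 1], Fraction(0))
    return float(p)


def fisher_exact_two_sided(table: FourfoldTable) -> float:
    """Two-sided exact p: sum of outcomes no more probable than observed."""
    k_min, _k_max, a, pmf = _hypergeom_pmf_exact(table)
    p_obs = pmf[a - k_min]
    p = sum((q for q in pmf if q <= p_obs), Fraction(0))
    return float(min(p, Fraction(1)))


def _enumerate_rxc(row_margins: list[int], col_margins: list[int]):
    """Yield all nonnegative integer tables with the given margins."""

    def rec(rows_left: list[int], cols_left: list[int]):
        if len(rows_left) == 1:
            if all(c >= 0 for c in cols_left):
                yield [list(cols_left)]
            return
        r = rows_left[0]
        ncols = len(cols_left)

        def fill(col: int, remaining: int, row_acc: list[int]):
            if col == ncols - 1:
                if 0 <= remaining <= cols_left[col]:
                    yield row_acc + [remaining]
                return
            for v in range(0, min(remaining, cols_left[col]) + 1):
                yield from fill(col + 1, remaining - v, row_acc + [v])

        for row in fill(0, r, []):
            new_cols = [c - v for c, v in zip(cols_left, row)]
            for rest in rec(rows_left[1:], new_cols):
                yield [row] + rest

    yield from rec(row_margins, col_margins)


def _rxc_prob(cells: list[list[int]], row_margins, col_margins, n_tot) -> Fraction:
    num = 1
    for m in row_margins:
        num *= math.factorial(m)
    for m in col_margins:
        num *= math.factorial(m)
    den = math.factorial(n_tot)
    for row in cells:
        for v in row:
            den *= math.factorial(v)
    return Fraction(num, den)


def fisher_exact_rxc(counts: Sequence[Sequence[int]]) -> float:
    """Freeman-Halton exact test for an r x c contingency table.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table
    (probability-ordering rule).  Exact rational arithmetic; intended
    for the small tables of a baseline summary.
    """
    cells = [[int(v) for v in row] for row in counts]
    row_margins = [sum(r) for r in cells]
    col_margins = [sum(c) for c in zip(*cells)]
    n_tot = sum(row_margins)
    if n_tot == 0:
        raise ValueError("empty table")
    p_obs = _rxc_prob(cells, row_margins, col_margins, n_tot)
    p = Fraction(0)
    for t in _enumerate_rxc(row_margins, col_margins):
        q = _rxc_prob(t, row_margins, col_margins, n_tot)
        if q <= p_obs:
            p += q
    return float(min(p, Fraction(1)))


#: combined sample size up to which the rank-sum null is enumerated exactly
_EXACT_ENUMERATION_LIMIT = 20


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact permutation null by full enumeration of rank assignments for
    combined n <= 20 (ties handled through midranks, which the
    enumeration permutes like any other value); normal approximation
    with the usual tie correction and a 0.5 continuity correction
    otherwise.  ``method`` forces one branch ("exact" / "approx").
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    n = combined.size
    nx = x.size
    ranks = sps.rankdata(combined)
    w_obs = float(ranks[:nx].sum())

    use_exact = method == "exact" or (method == "auto" and n <= _EXACT_ENUMERATION_LIMIT)
    if use_exact:
        if n > 24:
            raise ValueError("exact enumeration limited to combined n <= 24")
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), nx)),
            dtype=np.intp,
        ).reshape(-1, nx)
        sums = ranks[idx].sum(axis=1)
        total = sums.size
        eps = 1e-9
        p_le = np.count_nonzero(sums <= w_obs + eps) / total
        p_ge = np.count_nonzero(sums >= w_obs - eps) / total
        return float(min(1.0, 2.0 * min(p_le, p_ge)))

    mean_w = nx * (n + 1) / 2.0
    _uniq, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var_w = nx * (n - nx) / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return 1.0
    z = max(abs(w_obs - mean_w) - 0.5, 0.0) / math.sqrt(var_w)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


@dataclass(frozen=True)
class UsabilityClass:
    """A usability class with its mean S-GUS and 95% interval (points)."""

    name: str
    mean: float
    lower: float
    upper: float

    def sd(self, divisor: float) -> float:
        if not self.lower <= self.mean <= self.upper:
            raise ValueError(f"class {self.name!r}: interval must bracket the mean")
        return (self.upper - self.lower) / divisor


_Z975 = 1.959964  # Phi^-1(0.975)


def _default_classes() -> tuple[UsabilityClass, ...]:
    return (
        UsabilityClass("good", 26.0, 21.0, 32.0),
        UsabilityClass("pretty good", 20.0, 15.0, 25.0),
        UsabilityClass("insufficient", 11.0, 8.0, 13.0),
    )


@dataclass(frozen=True)
class PowerSpec:
    alpha: float = 0.05
    power: float = 0.80
    classes: tuple[UsabilityClass, ...] = field(default_factory=_default_classes)
    #: SD = (upper - lower) / sd_divisor; default treats the interval as
    #: mean +/- 1.96 SD.
    sd_divisor: float = 2 * _Z975

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must be in (0, 1)")
        if len(self.classes) < 2:
            raise ValueError("need at least two classes to compare")


@dataclass(frozen=True)
class SampleSizeResult:
    comparisons: pd.DataFrame  # pair, delta, sd_pooled, n_per_group, n_total
    final_n: int


def _n_per_group(alpha: float, power: float, sd_pooled: float, delta: float) -> int:
    if delta == 0:
        raise ValueError("no detectable difference (delta = 0)")
    z_a = sps.norm.ppf(1 - alpha / 2)
    z_b = sps.norm.ppf(power)
    return max(1, math.ceil(2 * (z_a + z_b) ** 2 * sd_pooled**2 / delta**2))


def sample_size(spec: PowerSpec) -> SampleSizeResult:
    """Per-comparison and final sample sizes for the usability classes.

    Every unordered pair of classes is compared with the two-sample
    normal-approximation formula; the final recommended enrolment is
    the maximum total (both groups) over the comparisons.
    """
    spec.validate()
    rows = []
    for c1, c2 in itertools.combinations(spec.classes, 2):
        delta = abs(c1.mean - c2.mean)
        sd_pooled = math.sqrt((c1.sd(spec.sd_divisor) ** 2 + c2.sd(spec.sd_divisor) ** 2) / 2)
        n_grp = _n_per_group(spec.alpha, spec.power, sd_pooled, delta)
        rows.append(
            {
                "comparison": f"{c1.name} vs {c2.name}",
                "delta": delta,
                "sd_pooled": sd_pooled,
                "n_per_group": n_grp,
                "n_total": 2 * n_grp,
            }
        )
    table = pd.DataFrame(rows)
    return SampleSizeResult(comparisons=table, final_n=int(table["n_total"].max()))


def _binary_row(
    name: str, demographics: pd.DataFrame, col: str, yes
) -> dict:
    g1 = demographics[demographics["group"] == "Group 1"]
    g2 = demographics[demographics["group"] == "Group 2"]
    a = int((g1[col] == yes).sum())
    c = int((g2[col] == yes).sum())
    tbl = FourfoldTable(a, len(g1) - a, c, len(g2) - c)
    try:
        p = fisher_exact_one_sided(tbl)
        method = "fisher one-sided"
    except ValueError:
        p, method = float("nan"), "undefined (zero margin)"
    return {
        "variable": name,
        "total": f"{a + c} ({100 * (a + c) / len(demographics):.1f}%)",
        "group1": f"{a} ({100 * a / len(g1):.1f}%)",
        "group2": f"{c} ({100 * c / len(g2):.1f}%)",
        "p_value": p,
        "method": method,
    }


def _categorical_row(name: str, demographics: pd.DataFrame, col: str) -> dict:
    g1 = demographics[demographics["group"] == "Group 1"]
    g2 = demographics[demographics["group"] == "Group 2"]
    levels = sorted(demographics[col].unique())
    counts = [
        [int((g[col] == lev).sum()) for lev in levels] for g in (g1, g2)
    ]
    return {
        "variable": name,
        "total": " / ".join(
            f"{lev}: {int((demographics[col] == lev).sum())}" for lev in levels
        ),
        "group1": " / ".join(f"{lev}: {c}" for lev, c in zip(levels, counts[0])),
        "group2": " / ".join(f"{lev}: {c}" for lev, c in zip(levels, counts[1])),
        "p_value": fisher_exact_rxc(counts),
        "method": "fisher exact (Freeman-Halton)",
    }


def baseline_table(demographics: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics by group with per-variable exact tests.

    Expects the demographics schema written by the cohort generator
    (columns ``group, sex, age, instructed_dpi/mdi/smi, region,
    education``); returns one row per variable with counts and the
    group-comparison p-value.
    """
    g1 = demographics[demographics["group"] == "Group 1"]
    g2 = demographics[demographics["group"] == "Group 2"]
    rows = [
        _binary_row("Instructed to DPIs", demographics, "instructed_dpi", 1),
        _binary_row("Instructed to MDIs", demographics, "instructed_mdi", 1),
        _binary_row("Instructed to SMIs", demographics, "instructed_smi", 1),
        {
            "variable": "Mean age (SD)",
            "total": f"{demographics['age'].mean():.1f} ({demographics['age'].std():.2f})",
            "group1": f"{g1['age'].mean():.1f} ({g1['age'].std():.2f})",
            "group2": f"{g2['age'].mean():.1f} ({g2['age'].std():.2f})",
            "p_value": wilcoxon_rank_sum(g1["age"], g2["age"]),
            "method": "wilcoxon rank-sum",
        },
        _binary_row("Male", demographics, "sex", "male"),
        _categorical_row("Country", demographics, "region"),
        _categorical_row("Education", demographics, "education"),
    ]
    return pd.DataFrame(rows)
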