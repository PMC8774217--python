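"""Hierarchical random-effects indirect comparison of device usability.

Patients score several inhalers each, so every within-patient pair of
devices is a direct comparison and the whole cohort forms an evidence
network.  The model is the arm-level formulation of the standard
contrast-based hierarchical random-effects model:

    score(s, d) = mu + delta_d + u_s + eps_{s,d}
    u_s ~ Normal(0, tau^2),   eps ~ Normal(0, sigma^2)

with ``delta_ref = 0`` for a chosen reference device.  ``mu`` is the
reference device's mean S-GUS, ``delta_d`` the usability effect of
device d versus the reference, ``u_s`` a patient random effect
capturing between-patient heterogeneity, and ``sigma`` the residual
scale.  Any absolute mean difference (AMD) between devices i and j is
``delta_i - delta_j``, so one fit yields every pairwise comparison and
consistency (AMD(i,k) = AMD(i,j) + AMD(j,k)) holds exactly at the draw
level.  The shared patient effect also induces the correct correlation
between comparisons sharing a patient, with no ad hoc adjustment.

Priors are vague: Normal(0, 1e4) on mu and each delta_d, Uniform(0, 5)
on both standard deviations.  Posterior sampling is Gibbs: the location
block (mu, delta) is updated jointly from its exact multivariate-normal
conditional, patient effects from their univariate normal conditionals,
and each standard deviation from its exact truncated inverse-gamma
conditional via the inverse-CDF (so the Uniform(0, 5) support is
respected without rejection steps).

:func:`conjugate_oracle` computes, for fixed ``sigma`` and ``tau``, the
exact Gaussian posterior of (mu, delta) by generalised least squares;
it exists to verify the sampler and is not used by :func:`fit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "EvidenceNetwork",
    "ModelSpec",
    "PosteriorDraws",
    "PosteriorSummary",
    "build_network",
    "fit",
    "conjugate_oracle",
    "summarize",
    "split_rhat",
]

_TAU_FLOOR = 1e-8  # avoids division by zero when the SD draw underflows


@dataclass(frozen=True)
class EvidenceNetwork:
    """Devices as nodes; edge weight = number of patients scoring both."""

    graph: nx.Graph

    @property
    def devices(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    def weight(self, i: str, j: str) -> int:
        if self.graph.has_edge(i, j):
            return int(self.graph.edges[i, j]["weight"])
        return 0

    def is_connected(self) -> bool:
        positive = nx.Graph(
            (u, v) for u, v, w in self.graph.edges(data="weight") if w > 0
        )
        positive.add_nodes_from(self.graph.nodes)
        return nx.is_connected(positive) if len(positive) else True


def build_network(scores: pd.DataFrame) -> EvidenceNetwork:
    """Evidence network of a cohort's ``patient_id, device_id`` score table."""
    if scores.empty:
        raise ValueError("cohort is empty")
    g = nx.Graph()
    devices = sorted(scores["device_id"].unique())
    g.add_nodes_from(devices)
    by_patient = scores.groupby("patient_id")["device_id"].apply(set)
    for i_pos, i in enumerate(devices):
        for j in devices[i_pos + 1 :]:
            w = int(sum(1 for devs in by_patient if i in devs and j in devs))
            if w:
                g.add_edge(i, j, weight=w)
    return EvidenceNetwork(graph=g)


@dataclass(frozen=True)
class ModelSpec:
    """Priors, MCMC schedule and options for :func:`fit`.

    ``sigma_fixed`` / ``tau_fixed`` pin a standard deviation to a known
    value instead of sampling it (used for oracle-equivalence checks).
    """

    reference_device: str = "Breezhaler"
    effect_prior_var: float = 1e4
    sd_upper: float = 5.0
    iterations: int = 100_000
    burn_in: int = 50_000
    thinning: int = 1
    chains: int = 1
    seed: int = 0
    cri_level: float = 0.90
    sigma_fixed: float | None = None
    tau_fixed: float | None = None

    def validate(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError(
                f"burn_in ({self.burn_in}) must be < iterations ({self.iterations})"
            )
        if not 0.0 < self.cri_level < 1.0:
            raise ValueError("cri_level must be in (0, 1)")
        if self.effect_prior_var <= 0 or self.sd_upper <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if self.thinning < 1 or self.chains < 1:
            raise ValueError("thinning and chains must be >= 1")


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MCMC draws (post burn-in, thinned; chains concatenated)."""

    device_ids: tuple[str, ...]
    patient_ids: tuple[str, ...]
    reference_device: str
    mu: np.ndarray          # (n_draws,)
    delta: np.ndarray       # (n_draws, D); reference column identically 0
    u: np.ndarray           # (n_draws, S)
    sigma: np.ndarray       # (n_draws,)
    tau: np.ndarray         # (n_draws,)
    chains: int = 1

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    @property
    def absolute(self) -> np.ndarray:
        """Per-draw absolute device means mu + delta_d, shape (n_draws, D)."""
        return self.mu[:, None] + self.delta


def _sample_sd(
    rng: np.random.Generator, n: int, sum_sq: float, upper: float
) -> float:
    """Draw from p(s) ~ s^-n * exp(-sum_sq / (2 s^2)) on (0, upper).

    With a Uniform(0, upper) prior on the SD the conditional for the
    variance is inverse-gamma((n-1)/2, sum_sq/2) truncated to
    (0, upper^2); sampled exactly by inverse-CDF of the corresponding
    truncated gamma on the precision.  n == 0 recovers the prior.
    """
    if n == 0:
        return float(rng.uniform(0.0, upper))
    shape = (n - 1) / 2.0
    rate = max(sum_sq, 1e-12) / 2.0
    if shape <= 0:
        # n == 1: density s^-1 * exp(-rate/s^2) on (0, upper); fine-grid inverse CDF
        grid = np.linspace(upper / 4096.0, upper, 4096)
        logf = -np.log(grid) - rate / grid**2
        f = np.exp(logf - logf.max())
        cdf = np.cumsum(f)
        cdf /= cdf[-1]
        return float(np.interp(rng.uniform(), cdf, grid))
    # precision g = 1/s^2 ~ Gamma(shape, rate) truncated to g > 1/upper^2
    lo = special.gammainc(shape, rate / upper**2)
    uu = rng.uniform(lo, 1.0)
    g = special.gammaincinv(shape, uu) / rate
    return float(1.0 / np.sqrt(g))


def _prior_only_draws(spec: ModelSpec, n_keep: int, rng: np.random.Generator):
    mu = rng.normal(0.0, np.sqrt(spec.effect_prior_var), size=n_keep)
    sigma = rng.uniform(0.0, spec.sd_upper, size=n_keep)
    tau = rng.uniform(0.0, spec.sd_upper, size=n_keep)
    return mu, sigma, tau


def fit(scores: pd.DataFrame, spec: ModelSpec) -> PosteriorDraws:
    """Sample the posterior of the indirect-comparison model by Gibbs.

    ``scores`` needs columns ``patient_id, device_id, sgus_total``.  The
    evidence network must be connected (every device reachable from the
    reference through shared patients), otherwise relative effects are
    unidentified and a ``ValueError`` names the unreachable devices.

    An empty table is allowed and returns draws from the priors (useful
    as a prior-recovery diagnostic).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if scores.empty:
        n_keep = (spec.iterations - spec.burn_in) // spec.thinning * spec.chains
        mu, sigma, tau = _prior_only_draws(spec, n_keep, rng)
        if spec.sigma_fixed is not None:
            sigma = np.full(n_keep, float(spec.sigma_fixed))
        if spec.tau_fixed is not None:
            tau = np.full(n_keep, float(spec.tau_fixed))
        return PosteriorDraws(
            device_ids=(spec.reference_device,),
            patient_ids=(),
            reference_device=spec.reference_device,
            mu=mu,
            delta=np.zeros((n_keep, 1)),
            u=np.zeros((n_keep, 0)),
            sigma=sigma,
            tau=tau,
            chains=spec.chains,
        )

    net = build_network(scores)
    devices = list(net.devices)
    if spec.reference_device not in devices:
        raise ValueError(
            f"reference device {spec.reference_device!r} not present in cohort"
        )
    positive = nx.Graph(
        (a, b) for a, b, w in net.graph.edges(data="weight") if w > 0
    )
    positive.add_nodes_from(devices)
    reachable = nx.node_connected_component(positive, spec.reference_device)
    unreachable = sorted(set(devices) - reachable)
    if unreachable:
        raise ValueError(
            "evidence network is disconnected; unreachable from "
            f"{spec.reference_device!r}: {unreachable}"
        )

    patients = sorted(scores["patient_id"].unique())
    dev_index = {d: k for k, d in enumerate(devices)}
    pat_index = {p: k for k, p in enumerate(patients)}
    y = scores["sgus_total"].to_numpy(dtype=float)
    d_idx = scores["device_id"].map(dev_index).to_numpy()
    p_idx = scores["patient_id"].map(pat_index).to_numpy()
    n_obs = y.size
    n_dev = len(devices)
    n_pat = len(patients)
    ref = dev_index[spec.reference_device]

    # design bookkeeping for the joint (mu, delta) block:
    # columns = [intercept] + [indicator(d) for d != ref]
    free = [k for k in range(n_dev) if k != ref]
    n_per_dev = np.bincount(d_idx, minlength=n_dev).astype(float)
    p_beta = 1 + len(free)
    xtx = np.zeros((p_beta, p_beta))
    xtx[0, 0] = n_obs
    for c, k in enumerate(free, start=1):
        xtx[0, c] = xtx[c, 0] = n_per_dev[k]
        xtx[c, c] = n_per_dev[k]
    m_per_pat = np.bincount(p_idx, minlength=n_pat).astype(float)

    n_keep_per_chain = (spec.iterations - spec.burn_in) // spec.thinning
    n_keep = n_keep_per_chain * spec.chains
    mu_out = np.empty(n_keep)
    delta_out = np.zeros((n_keep, n_dev))
    u_out = np.empty((n_keep, n_pat))
    sigma_out = np.empty(n_keep)
    tau_out = np.empty(n_keep)

    eye = np.eye(p_beta)
    for chain in range(spec.chains):
        # state initialisation; chains are over-dispersed via the rng stream
        mu = float(np.mean(y)) + (rng.normal(0.0, 2.0) if spec.chains > 1 else 0.0)
        delta = np.zeros(n_dev)
        u = np.zeros(n_pat)
        sigma = (
            float(spec.sigma_fixed)
            if spec.sigma_fixed is not None
            else spec.sd_upper / 2.0
        )
        tau = float(spec.tau_fixed) if spec.tau_fixed is not None else spec.sd_upper / 2.0

        kept = 0
        for it in range(spec.iterations):
            inv_s2 = 1.0 / max(sigma, _TAU_FLOOR) ** 2

            # --- (mu, delta) joint conditional: exact multivariate normal
            r = y - u[p_idx]
            dev_sums = np.bincount(d_idx, weights=r, minlength=n_dev)
            xtr = np.empty(p_beta)
            xtr[0] = dev_sums.sum()
            xtr[1:] = dev_sums[free]
            prec = xtx * inv_s2 + eye / spec.effect_prior_var
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, xtr * inv_s2)
            z = rng.standard_normal(p_beta)
            beta = mean + np.linalg.solve(chol.T, z)
            mu = float(beta[0])
            delta[:] = 0.0
            delta[free] = beta[1:]

            # --- patient effects: independent normal conditionals
            if tau <= _TAU_FLOOR:
                u[:] = 0.0
            else:
                r2 = y - mu - delta[d_idx]
                pat_sums = np.bincount(p_idx, weights=r2, minlength=n_pat)
                prec_u = m_per_pat * inv_s2 + 1.0 / tau**2
                u = pat_sums * inv_s2 / prec_u + rng.standard_normal(n_pat) / np.sqrt(
                    prec_u
                )

            # --- residual and heterogeneity SDs: truncated inverse-gamma
            resid = y - mu - delta[d_idx] - u[p_idx]
            if spec.sigma_fixed is None:
                sigma = _sample_sd(rng, n_obs, float(resid @ resid), spec.sd_upper)
            if spec.tau_fixed is None:
                tau = _sample_sd(rng, n_pat, float(u @ u), spec.sd_upper)

            if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0:
                row = chain * n_keep_per_chain + kept
                mu_out[row] = mu
                delta_out[row] = delta
                u_out[row] = u
                sigma_out[row] = sigma
                tau_out[row] = tau
                kept += 1

    return PosteriorDraws(
        device_ids=tuple(devices),
        patient_ids=tuple(patients),
        reference_device=spec.reference_device,
        mu=mu_out,
        delta=delta_out,
        u=u_out,
        sigma=sigma_out,
        tau=tau_out,
        chains=spec.chains,
    )


def conjugate_oracle(
    scores: pd.DataFrame,
    sigma: float,
    tau: float,
    prior_var: float | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Exact Gaussian posterior of (mu, delta) for fixed sigma and tau.

    Integrating the patient effects out of the arm-level model leaves
    y ~ Normal(X beta, V) with V = sigma^2 I + tau^2 Z Z', Z the
    patient-indicator matrix.  With flat (or Normal(0, prior_var))
    priors the posterior of beta = (mu, delta_{d != ref}) is Gaussian
    with covariance (X' V^-1 X [+ I/prior_var])^-1; this is the
    generalised-least-squares solution.  Verification oracle only.

    Returns ``(names, mean, cov)`` where names[0] is ``"mu"`` and the
    rest are ``"delta:<device>"`` for each non-reference device in
    sorted order; the reference is the alphabetically first device.
    """
    if scores.empty:
        raise ValueError("cohort is empty")
    devices = sorted(scores["device_id"].unique())
    patients = sorted(scores["patient_id"].unique())
    ref = devices[0]
    dev_index = {d: k for k, d in enumerate(devices)}
    pat_index = {p: k for k, p in enumerate(patients)}
    y = scores["sgus_total"].to_numpy(dtype=float)
    n = y.size
    # beta columns: [intercept, delta_d for d != ref]; ref is index 0 (sorted)
    x = np.zeros((n, len(devices)))
    x[:, 0] = 1.0
    z = np.zeros((n, len(patients)))
    for row, (d, p) in enumerate(zip(scores["device_id"], scores["patient_id"])):
        k = dev_index[d]
        if k != 0:
            x[row, k] = 1.0
        z[row, pat_index[p]] = 1.0
    v = sigma**2 * np.eye(n) + tau**2 * (z @ z.T)
    vinv = np.linalg.inv(v)
    a = x.T @ vinv @ x
    if prior_var is not None:
        a = a + np.eye(a.shape[0]) / prior_var
    if np.linalg.matrix_rank(a) < a.shape[0]:
        raise ValueError("design matrix is rank deficient")
    cov = np.linalg.inv(a)
    mean = cov @ (x.T @ vinv @ y)
    names = ["mu"] + [f"delta:{d}" for d in devices if d != ref]
    return names, mean, cov


@dataclass(frozen=True)
class PosteriorSummary:
    """Table-2-shaped posterior summary.

    ``device_table`` has one row per device (mean S-GUS and CrI);
    ``amd_mean[i, j]``, ``amd_lower``, ``amd_upper`` give the AMD of
    device i versus j with its CrI; ``post_p[i, j]`` is the posterior
    probability that device i is more usable than device j.
    """

    device_ids: tuple[str, ...]
    device_table: pd.DataFrame
    amd_mean: np.ndarray
    amd_lower: np.ndarray
    amd_upper: np.ndarray
    post_p: np.ndarray
    level: float

    def amd(self, i: str, j: str) -> float:
        a, b = self.device_ids.index(i), self.device_ids.index(j)
        return float(self.amd_mean[a, b])

    def prob_better(self, i: str, j: str) -> float:
        a, b = self.device_ids.index(i), self.device_ids.index(j)
        return float(self.post_p[a, b])


def summarize(draws: PosteriorDraws, level: float | None = None) -> PosteriorSummary:
    """Posterior means, quantile CrIs and pairwise probabilities.

    CrIs are empirical quantiles: at the default 90% level the 5th and
    95th percentiles of the retained draws.  ``post_p[i, j]`` is the
    fraction of draws with delta_i > delta_j; exact ties (measure-zero
    for continuous draws) are split 50/50 so that
    post_p(i, j) + post_p(j, i) = 1 always holds.
    """
    if draws.n_draws == 0:
        raise ValueError("no draws to summarize")
    level = 0.90 if level is None else float(level)
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0

    absolute = draws.absolute
    device_table = pd.DataFrame(
        {
            "device_id": draws.device_ids,
            "mean_sgus": absolute.mean(axis=0),
            "cri_lower": np.quantile(absolute, lo_q, axis=0),
            "cri_upper": np.quantile(absolute, hi_q, axis=0),
        }
    )

    d = len(draws.device_ids)
    amd_mean = np.zeros((d, d))
    amd_lower = np.zeros((d, d))
    amd_upper = np.zeros((d, d))
    post_p = np.full((d, d), 0.5)
    for i in range(d):
        for j in range(d):
            if i == j:
                continue
            diff = draws.delta[:, i] - draws.delta[:, j]
            amd_mean[i, j] = diff.mean()
            amd_lower[i, j] = np.quantile(diff, lo_q)
            amd_upper[i, j] = np.quantile(diff, hi_q)
            post_p[i, j] = np.mean(diff > 0) + 0.5 * np.mean(diff == 0)

    return PosteriorSummary(
        device_ids=draws.device_ids,
        device_table=device_table,
        amd_mean=amd_mean,
        amd_lower=amd_lower,
        amd_upper=amd_upper,
        post_p=post_p,
        level=level,
    )


def split_rhat(chain_values: np.ndarray, n_chains: int) -> float:
    """Split-R-hat convergence diagnostic for one scalar parameter.

    ``chain_values`` holds the concatenated draws of ``n_chains``
    equal-length chains; each chain is split in half, giving 2*n_chains
    segments, and the classic between/within variance ratio is returned.
    """
    per = chain_values.size // n_chains
    segs = []
    for c in range(n_chains):
        block = chain_values[c * per : (c + 1) * per]
        half = per // 2
        segs.append(block[:half])
        segs.append(block[half : 2 * half])
    segs_arr = np.asarray(segs, dtype=float)
    m, n = segs_arr.shape
    means = segs_arr.mean(axis=1)
    w = segs_arr.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w)) if w > 0 else 1.0
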