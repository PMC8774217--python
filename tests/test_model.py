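"""Indirect-comparison model: network, sampler correctness, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sgus_ic.model import (
    ModelSpec,
    build_network,
    conjugate_oracle,
    fit,
    split_rhat,
    summarize,
)
from tests.conftest import make_draws


def _scores(rows):
    return pd.DataFrame(rows, columns=["patient_id", "device_id", "sgus_total"])


def _two_device_cohort(n=8, shift=5.0, tau=1.5, sigma=1.0, seed=7):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n):
        u = rng.normal(0, tau) if tau > 0 else 0.0
        rows.append((f"P{s:02d}", "A", 10.0 + u + rng.normal(0, sigma)))
        rows.append((f"P{s:02d}", "B", 10.0 + shift + u + rng.normal(0, sigma)))
    return _scores(rows)


class TestEvidenceNetwork:
    def test_default_design_edge_weights(self, default_cohort):
        net = build_network(default_cohort.scores)
        assert net.weight("Breezhaler", "Spiromax") == 33
        for i, j in itertools.combinations(("Breezhaler", "Spiromax", "Ellipta", "Nexthaler"), 2):
            if {i, j} != {"Breezhaler", "Spiromax"}:
                assert net.weight(i, j) == 18
        for i, j in itertools.combinations(("Breezhaler", "Spiromax", "Turbohaler", "Diskus"), 2):
            if {i, j} != {"Breezhaler", "Spiromax"}:
                assert net.weight(i, j) == 15
        assert net.weight("Ellipta", "Turbohaler") == 0
        assert net.is_connected()

    def test_empty_cohort_is_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_network(_scores([]))


class TestFitContracts:
    def test_disconnected_network_names_unreachable_devices(self):
        scores = _scores(
            [("P1", "A", 10.0), ("P1", "B", 12.0), ("P2", "C", 20.0), ("P2", "D", 22.0)]
        )
        with pytest.raises(ValueError, match=r"\['C', 'D'\]"):
            fit(scores, ModelSpec(reference_device="A", iterations=10, burn_in=5))

    def test_burnin_must_be_below_iterations(self):
        with pytest.raises(ValueError, match="burn_in"):
            fit(_two_device_cohort(), ModelSpec(iterations=100, burn_in=100))

    def test_missing_reference_device_is_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            fit(_two_device_cohort(), ModelSpec(reference_device="Zonda",
                                                iterations=10, burn_in=5))

    def test_same_seed_reproduces_draws(self):
        spec = ModelSpec(reference_device="A", iterations=400, burn_in=200, seed=5)
        a = fit(_two_device_cohort(), spec)
        b = fit(_two_device_cohort(), spec)
        np.testing.assert_array_equal(a.delta, b.delta)
        np.testing.assert_array_equal(a.sigma, b.sigma)


class TestFitInference:
    def test_identical_scores_give_null_amds(self):
        rows = [
            (f"P{s}", d, 30.0) for s in range(10) for d in ("A", "B", "C")
        ]
        spec = ModelSpec(reference_device="A", iterations=4000, burn_in=2000, seed=1)
        summary = summarize(fit(_scores(rows), spec))
        for i, j in itertools.combinations(range(3), 2):
            assert abs(summary.amd_mean[i, j]) < 0.15

    def test_constant_shift_is_recovered(self):
        rows = []
        for s in range(12):
            base = 20.0 + s * 0.5
            rows.append((f"P{s:02d}", "A", base))
            rows.append((f"P{s:02d}", "B", base + 5.0))
        spec = ModelSpec(reference_device="A", iterations=6000, burn_in=3000, seed=3)
        summary = summarize(fit(_scores(rows), spec))
        assert summary.amd("B", "A") == pytest.approx(5.0, abs=0.2)

    def test_sampler_matches_conjugate_oracle_with_fixed_sds(self):
        scores = _two_device_cohort()
        names, mean, cov = conjugate_oracle(scores, sigma=1.0, tau=1.5, prior_var=1e4)
        spec = ModelSpec(
            reference_device="A", iterations=25000, burn_in=5000, seed=2,
            sigma_fixed=1.0, tau_fixed=1.5,
        )
        draws = fit(scores, spec)
        db = draws.delta[:, draws.device_ids.index("B")]
        k = names.index("delta:B")
        # batch-means Monte-Carlo SE accounts for autocorrelation
        nb = 50
        batches = db[: db.size // nb * nb].reshape(nb, -1).mean(axis=1)
        mcse = batches.std(ddof=1) / np.sqrt(nb)
        assert abs(db.mean() - mean[k]) < 3 * mcse
        assert db.std() == pytest.approx(np.sqrt(cov[k, k]), rel=0.05)

    def test_consistency_holds_at_the_draw_level(self, default_cohort):
        spec = ModelSpec(iterations=2000, burn_in=1000, seed=4)
        draws = fit(default_cohort.scores, spec)
        d = draws.delta
        ids = draws.device_ids
        i, j, k = ids.index("Ellipta"), ids.index("Spiromax"), ids.index("Diskus")
        np.testing.assert_allclose(
            d[:, i] - d[:, k], (d[:, i] - d[:, j]) + (d[:, j] - d[:, k]), atol=1e-10
        )

    def test_multichain_mode_converges(self):
        scores = _two_device_cohort(n=10, seed=11)
        spec = ModelSpec(reference_device="A", iterations=3000, burn_in=1000,
                         seed=6, chains=3)
        draws = fit(scores, spec)
        assert draws.n_draws == 3 * 2000
        db = draws.delta[:, draws.device_ids.index("B")]
        assert split_rhat(db, 3) < 1.05


class TestConjugateOracle:
    def test_single_device_reduces_to_sample_mean(self):
        rng = np.random.default_rng(0)
        y = rng.normal(12.0, 1.0, size=16)
        scores = _scores([(f"P{i}", "A", v) for i, v in enumerate(y)])
        names, mean, cov = conjugate_oracle(scores, sigma=1.0, tau=0.0)
        assert names == ["mu"]
        assert mean[0] == pytest.approx(y.mean())
        assert cov[0, 0] == pytest.approx(1.0 / 16)

    def test_two_crossed_devices_give_difference_of_means(self):
        rng = np.random.default_rng(1)
        ya = rng.normal(10, 1, size=9)
        yb = rng.normal(14, 1, size=9)
        rows = [(f"P{i}", "A", v) for i, v in enumerate(ya)]
        rows += [(f"P{i}", "B", v) for i, v in enumerate(yb)]
        _names, mean, _cov = conjugate_oracle(_scores(rows), sigma=1.0, tau=0.0)
        assert mean[1] == pytest.approx(yb.mean() - ya.mean())

    def test_rank_deficient_design_is_rejected(self):
        # device C never observed with anyone: column of zeros after pivot
        scores = _scores([("P1", "A", 1.0), ("P1", "A", 2.0)])
        with pytest.raises(ValueError):
            conjugate_oracle(scores, sigma=0.0, tau=0.0)


class TestSummarize:
    def test_constant_draws_collapse_mean_and_cri(self):
        draws = make_draws(np.tile([0.0, 3.44], (50, 1)), ("A", "B"), mu=np.zeros(50))
        summary = summarize(draws)
        row = summary.device_table.set_index("device_id").loc["B"]
        assert row["mean_sgus"] == pytest.approx(3.44)
        assert row["cri_lower"] == pytest.approx(3.44)
        assert row["cri_upper"] == pytest.approx(3.44)

    def test_post_p_matches_draw_frequency(self):
        n = 1000
        delta = np.zeros((n, 2))
        delta[:970, 1] = -1.0  # device A beats B in 97.0% of draws
        delta[970:, 1] = 1.0
        summary = summarize(make_draws(delta, ("A", "B")))
        assert summary.prob_better("A", "B") == pytest.approx(0.970)

    def test_post_p_antisymmetry_even_with_ties(self):
        rng = np.random.default_rng(8)
        delta = np.column_stack([np.zeros(200), rng.normal(size=200)])
        delta[:17, 1] = 0.0  # exact ties split 50/50
        summary = summarize(make_draws(delta, ("A", "B")))
        assert summary.prob_better("A", "B") + summary.prob_better("B", "A") == pytest.approx(1.0)

    def test_amd_antisymmetry_and_mean_consistency(self):
        rng = np.random.default_rng(9)
        delta = np.column_stack(
            [np.zeros(500), rng.normal(2, 1, 500), rng.normal(-1, 1, 500)]
        )
        summary = summarize(make_draws(delta, ("A", "B", "C")))
        np.testing.assert_allclose(summary.amd_mean, -summary.amd_mean.T, atol=1e-12)
        tbl = summary.device_table.set_index("device_id")
        assert summary.amd("B", "C") == pytest.approx(
            tbl.loc["B", "mean_sgus"] - tbl.loc["C", "mean_sgus"], abs=1e-9
        )

    def test_level_must_be_in_unit_interval(self):
        draws = make_draws(np.zeros((10, 2)), ("A", "B"))
        with pytest.raises(ValueError, match="level"):
            summarize(draws, level=1.0)
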