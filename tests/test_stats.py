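"""Rank statistics: Spearman, Kruskal-Wallis + Dunn, Friedman, sample size."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from psofa.stats import (
    friedman_dunn,
    kruskal_wallis_dunn,
    spearman,
    survival_sample_size,
)


def _brute_force_spearman(x, y):
    """Rank oracle: Pearson on mid-ranks, written independently."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den


class TestSpearman:
    def test_worked_example(self):
        x, y = (1, 2, 3, 4, 5), (2, 1, 4, 3, 5)
        res = spearman(x, y)
        assert res.r == pytest.approx(_brute_force_spearman(x, y))
        assert res.r == pytest.approx(0.8)
        assert res.method == "exact permutation"

    def test_perfect_monotone(self):
        up = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        down = spearman([1, 2, 3, 4], [5, 4, 3, 1])
        assert up.r == pytest.approx(1.0)
        assert down.r == pytest.approx(-1.0)
        # exactly 2 of 4! permutations reach |r| = 1
        assert up.p_value == pytest.approx(2 / 24)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 2, 3], [5, 5, 5])

    def test_matches_scipy_r_and_p(self):
        rng = np.random.default_rng(42)
        for n in (12, 30, 80):
            x = rng.normal(size=n)
            y = x + rng.normal(size=n)
            res = spearman(x, y)
            ref_r, ref_p = sps.spearmanr(x, y)
            assert res.r == pytest.approx(ref_r)
            assert res.p_value == pytest.approx(ref_p, rel=1e-6)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 10, size=15)
        y = rng.uniform(1, 10, size=15)
        base = spearman(x, y).r
        assert spearman(np.log(x), y).r == pytest.approx(base)
        assert spearman(x, np.exp(y / 5)).r == pytest.approx(base)
        assert spearman(x**3, y).r == pytest.approx(base)

    def test_regression_band_brackets_fit(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 10, 40)
        y = 2 * x + rng.normal(size=40)
        res = spearman(x, y)
        assert res.slope == pytest.approx(2.0, abs=0.2)
        assert (res.band["lower"] <= res.band["fit"]).all()
        assert (res.band["fit"] <= res.band["upper"]).all()


class TestKruskalWallisDunn:
    def test_identical_groups_degenerate(self):
        res = kruskal_wallis_dunn([[1, 1, 1], [1, 1, 1]])
        assert res.degenerate
        assert res.statistic == 0.0
        assert (res.pairwise["p_adjusted"] > 0.05).all()

    def test_two_groups_equal_mann_whitney_z_squared(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 15)
        res = kruskal_wallis_dunn([a, b])
        u = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
        n1, n2 = len(a), len(b)
        z = (u - n1 * n2 / 2) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert res.statistic == pytest.approx(z**2, rel=1e-9)

    def test_separated_groups_all_dunn_significant(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(mu, 0.5, 12) for mu in (0, 5, 10)]
        res = kruskal_wallis_dunn(groups, labels=["low", "mid", "high"])
        assert res.p_value < 1e-4
        assert (res.pairwise["p_adjusted"] < 0.05).all()

    def test_adjustments_ordering(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(mu, 1.0, 8) for mu in (0, 0.5, 1.5)]
        raw = kruskal_wallis_dunn(groups, adjust="none").pairwise
        bon = kruskal_wallis_dunn(groups, adjust="bonferroni").pairwise
        holm = kruskal_wallis_dunn(groups, adjust="holm").pairwise
        assert (bon["p_adjusted"] >= raw["p_raw"] - 1e-12).all()
        assert (holm["p_adjusted"] <= bon["p_adjusted"] + 1e-12).all()

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_dunn([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis_dunn([[1, 2], [1]])


class TestFriedmanDunn:
    def test_identical_blocks_degenerate(self):
        res = friedman_dunn(np.ones((5, 4)))
        assert res.degenerate and res.statistic == 0.0

    def test_strong_time_trend_detected(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 0.2, size=(10, 1))
        trend = base + np.array([0.0, 2.0, 4.0, 6.0])
        res = friedman_dunn(trend, treatment_labels=["16h", "18h", "20h", "24h"])
        assert res.p_value < 1e-3
        late = res.pairwise[res.pairwise["treatment"] == "24h"]
        assert (late["p_raw"] < 0.05).all()

    def test_contrasts_are_against_baseline_column(self):
        res = friedman_dunn(np.random.default_rng(2).normal(size=(6, 3)),
                            treatment_labels=["a", "b", "c"], baseline=1)
        assert set(res.pairwise["baseline"]) == {"b"}
        assert set(res.pairwise["treatment"]) == {"a", "c"}


class TestSampleSize:
    def test_schoenfeld_event_count(self):
        # closed form: (1.95996 + 1.28155)^2 / (0.25*0.75*ln(0.2)^2) = 21.6
        res = survival_sample_size(hazard_ratio=0.2, power=0.9, alpha=0.05,
                                   allocation_fraction=0.25)
        z = sps.norm.ppf(0.975) + sps.norm.ppf(0.9)
        expect = z**2 / (0.25 * 0.75 * math.log(0.2) ** 2)
        assert res.assumptions["required_events_exact"] == pytest.approx(expect)
        assert res.required_events == 22

    def test_hazard_ratio_one_rejected(self):
        with pytest.raises(ValueError):
            survival_sample_size(hazard_ratio=1.0)

    def test_divergence_near_unity(self):
        close = survival_sample_size(hazard_ratio=0.95).required_events
        far = survival_sample_size(hazard_ratio=0.2).required_events
        assert close > 100 * far / 22  # explodes as HR -> 1

    def test_symmetric_allocation_minimizes_events(self):
        events = {
            p: survival_sample_size(0.2, allocation_fraction=p).assumptions[
                "required_events_exact"
            ]
            for p in (0.1, 0.25, 0.5, 0.75, 0.9)
        }
        assert min(events, key=events.get) == 0.5

    def test_assumptions_echoed(self):
        res = survival_sample_size(0.2, event_prob_experimental=0.2,
                                   event_prob_control=0.05)
        assert res.assumptions["hazard_ratio"] == 0.2
        assert res.n_control + res.n_experimental >= res.required_events
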