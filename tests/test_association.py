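import numpy as np
import pandas as pd
import pytest

from cazyprofiler.association import (
    benjamini_hochberg,
    correlate_families,
    group_compare,
    group_compare_many,
    prevalence_filter,
    significant_families,
    summed_marker_correlation,
)
from cazyprofiler.synthetic import SimulationConfig, simulate_profile


def bh_oracle(pvals):
    """Brute-force step-up BH: min over j>=i of m*p_(j)/j, monotonized."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


class TestBenjaminiHochberg:
    def test_hand_example(self):
        got = benjamini_hochberg([0.01, 0.02, 0.03])
        assert got == pytest.approx([0.03, 0.03, 0.03])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            assert benjamini_hochberg(p) == pytest.approx(bh_oracle(p), abs=1e-12)


class TestPrevalenceFilter:
    def make_rates(self, present_counts, n=100):
        data = {f: [1.0] * k + [0.0] * (n - k) for f, k in present_counts.items()}
        return pd.DataFrame(data, index=[f"s{i}" for i in range(n)])

    def test_below_half_dropped(self):
        rates = self.make_rates({"GH1": 49, "GH2": 50, "GH3": 51})
        kept = prevalence_filter(rates, min_prev=0.5)
        assert list(kept.columns) == ["GH2", "GH3"]

    def test_zero_threshold_is_identity(self):
        rates = self.make_rates({"GH1": 1})
        assert list(prevalence_filter(rates, min_prev=0.0).columns) == ["GH1"]


class TestCorrelateFamilies:
    def test_perfect_correlation(self):
        idx = [f"s{i}" for i in range(10)]
        cov = pd.Series(np.arange(10.0), index=idx)
        rates = pd.DataFrame({"GH1": np.arange(10.0)}, index=idx)
        (rec,) = correlate_families(rates, cov, rank_transform=False)
        assert rec.r == pytest.approx(1.0)
        assert rec.p_value < 1e-10

    def test_rank_transform_equals_spearman(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(30)]
        cov = pd.Series(rng.normal(size=30), index=idx)
        rates = pd.DataFrame({"GH1": rng.gamma(2, 1, 30)}, index=idx)
        (rec,) = correlate_families(rates, cov, rank_transform=True)
        from scipy.stats import spearmanr, rankdata

        # ranks are taken within the family axis only, covariate left raw
        expected = np.corrcoef(cov, rankdata(rates["GH1"]))[0, 1]
        assert rec.r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_family_flagged_and_excluded_from_bh(self):
        idx = [f"s{i}" for i in range(10)]
        cov = pd.Series(np.arange(10.0), index=idx)
        rates = pd.DataFrame({"GH1": np.arange(10.0), "GH2": np.ones(10)},
                             index=idx)
        recs = {r.family: r for r in correlate_families(rates, cov)}
        assert recs["GH2"].degenerate
        # BH with m=1 leaves the defined family's p unchanged
        assert recs["GH1"].p_adjusted == pytest.approx(recs["GH1"].p_value)

    def test_planted_bmi_families_recovered(self):
        prof, truth = simulate_profile(SimulationConfig(seed=21))
        bmi = prof.metadata["bmi"]
        rates = prevalence_filter(prof.rates, covariate=bmi)
        recs = correlate_families(rates, bmi)
        sig = {f for f in significant_families(recs)
               if next(r for r in recs if r.family == f).r > 0}
        planted = truth.planted_bmi_families
        assert len(sig & planted) / len(planted) >= 0.8


class TestSummedMarkerCorrelation:
    def test_window_one_equals_plain_pearson(self):
        rng = np.random.default_rng(4)
        idx = [f"s{i}" for i in range(40)]
        cov = pd.Series(rng.normal(25, 4, 40), index=idx)
        rates = pd.DataFrame({"GH1": rng.gamma(2, 1, 40),
                              "GH2": rng.gamma(2, 1, 40)}, index=idx)
        win = summed_marker_correlation(rates, ["GH1", "GH2"], cov,
                                        window=1, step=1)
        sums = rates[["GH1", "GH2"]].sum(axis=1)
        expected = np.corrcoef(cov, sums)[0, 1] ** 2
        assert win.r_squared == pytest.approx(expected, abs=1e-12)

    def test_linear_relationship_r2_one_any_window(self):
        idx = [f"s{i}" for i in range(30)]
        cov = pd.Series(np.linspace(18, 40, 30), index=idx)
        rates = pd.DataFrame({"GH1": 2 * cov.values + 1}, index=idx)
        for window in (1, 3, 7):
            win = summed_marker_correlation(rates, ["GH1"], cov, window=window)
            assert win.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_window_exceeding_n_errors(self):
        idx = ["a", "b"]
        cov = pd.Series([1.0, 2.0], index=idx)
        rates = pd.DataFrame({"GH1": [1.0, 2.0]}, index=idx)
        with pytest.raises(ValueError, match="window"):
            summed_marker_correlation(rates, ["GH1"], cov, window=5)

    def test_windowing_raises_r2_under_noise(self):
        """Averaging windows suppresses sampling noise, so the windowed
        r^2 beats the per-sample r^2 in the majority of seeds."""
        better = 0
        n_seeds = 20
        for seed in range(1, n_seeds + 1):
            prof, truth = simulate_profile(SimulationConfig(seed=seed))
            bmi = prof.metadata["bmi"]
            fams = sorted(truth.planted_bmi_families)
            w = summed_marker_correlation(prof.rates, fams, bmi)
            u = summed_marker_correlation(prof.rates, fams, bmi, window=1)
            better += w.r_squared > u.r_squared
        assert better > n_seeds / 2


class TestGroupCompare:
    def idx(self, n):
        return [f"s{i}" for i in range(n)]

    def test_identical_groups_f_zero(self):
        v = pd.Series([1, 2, 3, 1, 2, 3], index=self.idx(6), dtype=float)
        g = pd.Series(["a"] * 3 + ["b"] * 3, index=self.idx(6))
        cmp = group_compare(v, g)
        assert cmp.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_f(self):
        # groups (1,2,3), (2,3,4), (3,4,5): between MS 3, within MS 1
        v = pd.Series([1, 2, 3, 2, 3, 4, 3, 4, 5], index=self.idx(9), dtype=float)
        g = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=self.idx(9))
        cmp = group_compare(v, g)
        assert cmp.f_statistic == pytest.approx(3.0, abs=1e-12)
        assert cmp.tukey is not None and len(cmp.tukey) == 3

    def test_degenerate_zero_within_variance_flagged(self):
        v = pd.Series([1, 1, 1, 2, 2, 2], index=self.idx(6), dtype=float)
        g = pd.Series(["a"] * 3 + ["b"] * 3, index=self.idx(6))
        assert group_compare(v, g).degenerate

    def test_small_group_errors(self):
        v = pd.Series([1.0, 2.0, 3.0], index=self.idx(3))
        g = pd.Series(["a", "a", "b"], index=self.idx(3))
        with pytest.raises(ValueError, match="fewer than 2"):
            group_compare(v, g)

    def test_bh_across_response_variables(self):
        rng = np.random.default_rng(9)
        idx = self.idx(30)
        table = pd.DataFrame({f"v{i}": rng.normal(size=30) for i in range(4)},
                             index=idx)
        table["v0"] += np.repeat([0.0, 3.0, 6.0], 10)  # one real effect
        g = pd.Series(np.repeat(["a", "b", "c"], 10), index=idx)
        out = group_compare_many(table, g)
        assert out.loc["v0", "significant"]
        assert out["p_adjusted"].min() >= out["p"].min()


class TestNullCalibration:
    def test_no_planted_effect_controls_fdr(self):
        """Under a null cohort the fraction of families called significant
        stays at or below the nominal 5% plus binomial slack."""
        total_called, total_tested = 0, 0
        for seed in range(1, 11):
            prof, _ = simulate_profile(
                SimulationConfig(seed=seed, n_bmi_families=0, bmi_slope=0.0))
            bmi = prof.metadata["bmi"]
            rates = prevalence_filter(prof.rates, covariate=bmi)
            recs = correlate_families(rates, bmi)
            total_called += len(significant_families(recs))
            total_tested += sum(not r.degenerate for r in recs)
        frac = total_called / total_tested
        tol = 5 * np.sqrt(0.05 * 0.95 / total_tested)
        assert frac <= 0.05 + tol
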