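import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cazyprofiler.cazotypes import (
    bca_ordination,
    calinski_harabasz,
    cazotype_preference_table,
    cluster_and_select_k,
    detect_markers,
    pam,
    sample_distance,
)
from cazyprofiler.synthetic import SimulationConfig, simulate_profile


def rel(df):
    return df.div(df.sum(axis=1), axis=0)


class TestSampleDistance:
    def test_identical_profiles_distance_zero(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]] * 2, index=["a", "b"],
                         columns=["GH1", "GH2", "GH3"])
        d = sample_distance(m)
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_support_distance_one(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"],
                         columns=["GH1", "GH2"])
        d = sample_distance(m)
        assert d.loc["a", "b"] == pytest.approx(1.0, abs=1e-3)

    def test_symmetry_zero_diagonal_and_triangle_inequality(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.gamma(0.5, 1.0, (30, 12)),
                         index=[f"s{i}" for i in range(30)])
        d = sample_distance(m).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        for _ in range(100):
            i, j, k = rng.integers(0, 30, 3)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_all_zero_profile_errors(self):
        m = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["a", "b"])
        with pytest.raises(ValueError):
            sample_distance(m)


class TestPam:
    def two_clouds(self, n_per=10, gap=100.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.concatenate([rng.normal(0, 1, (n_per, 2)),
                              rng.normal(gap, 1, (n_per, 2))])
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return d

    def test_two_separated_clouds_recovered_exactly(self):
        d = self.two_clouds()
        labels, med = pam(d, 2)
        assert (labels[:10] == labels[0]).all()
        assert (labels[10:] == labels[10]).all()
        assert labels[0] != labels[10]

    def test_duplicated_samples_share_labels(self):
        d = self.two_clouds()
        dup = np.block([[d, d], [d, d]])
        labels, _ = pam(dup, 2)
        assert (labels[:20] == labels[20:]).all()

    def test_deterministic(self):
        d = self.two_clouds(seed=3)
        a = pam(d, 3)
        b = pam(d, 3)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()


class TestCalinskiHarabasz:
    def test_well_separated_beats_random_partition(self):
        rng = np.random.default_rng(2)
        pts = np.concatenate([rng.normal(0, 1, (15, 2)),
                              rng.normal(50, 1, (15, 2))])
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        true = np.repeat([0, 1], 15)
        scrambled = rng.permutation(true)
        assert calinski_harabasz(d, true) > calinski_harabasz(d, scrambled)

    def test_matches_sklearn_on_euclidean_data(self):
        from sklearn.metrics import calinski_harabasz_score

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(40, 3))
        labels = rng.integers(0, 3, 40)
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        assert calinski_harabasz(d, labels) == pytest.approx(
            calinski_harabasz_score(pts, labels), rel=1e-9)


class TestClusterAndSelectK:
    def test_planted_three_cazotypes_recovered(self):
        prof, truth = simulate_profile(SimulationConfig(seed=17))
        model = cluster_and_select_k(sample_distance(prof))
        assert model.k == 3
        ari = adjusted_rand_score(truth.cazotype_of_sample.to_numpy(),
                                  model.labels.to_numpy())
        assert ari >= 0.9

    def test_k_selection_collapses_gracefully_at_low_separation(self):
        """Below the distinct-cluster regime the chosen k never exceeds
        the planted k."""
        prof, truth = simulate_profile(SimulationConfig(
            seed=17, cluster_separation=1.3,
            dirichlet_concentration_within=100.0, infant_fraction=0.0))
        model = cluster_and_select_k(sample_distance(prof))
        assert model.k <= 3

    def test_invalid_k_range(self):
        prof, _ = simulate_profile(SimulationConfig(n_samples=5, seed=1))
        d = sample_distance(prof)
        with pytest.raises(ValueError):
            cluster_and_select_k(d, range(2, 10))

    def test_label_permutation_invariance_of_ari(self):
        prof, truth = simulate_profile(SimulationConfig(seed=17))
        model = cluster_and_select_k(sample_distance(prof))
        perm = model.labels.map({1: 2, 2: 3, 3: 1})
        t = truth.cazotype_of_sample.to_numpy()
        assert adjusted_rand_score(t, model.labels.to_numpy()) == pytest.approx(
            adjusted_rand_score(t, perm.to_numpy()))


class TestBcaOrdination:
    def test_two_classes_have_single_informative_axis(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(20, 6)),
                         index=[f"s{i}" for i in range(20)])
        m.iloc[10:] += 5.0
        labels = pd.Series([1] * 10 + [2] * 10, index=m.index)
        coords, cents = bca_ordination(m, labels)
        assert cents["bca2"].abs().max() == pytest.approx(0.0, abs=1e-9)

    def test_identical_class_means_collapse_centroids(self):
        m = pd.DataFrame([[1.0, 2.0]] * 8, index=[f"s{i}" for i in range(8)])
        labels = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=m.index)
        _, cents = bca_ordination(m, labels)
        assert np.allclose(cents.to_numpy(), 0.0, atol=1e-12)

    def test_projection_matches_eigendecomposition_oracle(self):
        """Axis-1 centroid ordering agrees with a brute-force
        eigendecomposition of the between-class covariance."""
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(30, 4)),
                         index=[f"s{i}" for i in range(30)])
        labels = pd.Series(np.repeat([1, 2, 3], 10), index=m.index)
        shift = {1: 0.0, 2: 2.0, 3: 5.0}
        for lvl, s in shift.items():
            m.loc[labels == lvl] += s
        coords, cents = bca_ordination(m, labels)

        x = m.to_numpy()
        means = np.vstack([x[(labels == l).to_numpy()].mean(0) for l in (1, 2, 3)])
        w = np.array([1 / 3] * 3)
        grand = w @ means
        cm = means - grand
        bcov = (cm * w[:, None]).T @ cm
        evals, evecs = np.linalg.eigh(bcov)
        axis = evecs[:, np.argmax(evals)]
        oracle = cm @ axis
        got = cents["bca1"].to_numpy()
        if np.sign(oracle[-1]) != np.sign(got[-1]):
            oracle = -oracle
        assert np.argsort(oracle).tolist() == np.argsort(got).tolist()
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_single_member_class_warns(self):
        m = pd.DataFrame([[0.0], [1.0], [2.0]], index=["a", "b", "c"])
        labels = pd.Series([1, 1, 2], index=m.index)
        with pytest.warns(UserWarning, match="single member"):
            bca_ordination(m, labels)


class TestDetectMarkers:
    def planted(self, seed=19):
        prof, truth = simulate_profile(SimulationConfig(seed=seed))
        return prof, truth

    def test_strong_difference_called(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(150)]
        rates = pd.DataFrame({
            "GH1": np.r_[rng.normal(10, 0.5, 50), rng.normal(2, 0.5, 100)],
            "GH2": rng.normal(5, 0.5, 150),
        }, index=idx)
        labels = pd.Series([1] * 50 + [2] * 100, index=idx)
        markers = {(m.family, m.cazotype): m for m in detect_markers(rates, labels)}
        assert markers[("GH1", 1)].is_marker
        assert not markers[("GH2", 1)].is_marker

    def test_ratio_gate_blocks_small_fold_changes(self):
        rng = np.random.default_rng(2)
        idx = [f"s{i}" for i in range(200)]
        # highly significant but only 1.2-fold
        rates = pd.DataFrame({
            "GH1": np.r_[rng.normal(12, 0.1, 100), rng.normal(10, 0.1, 100)],
        }, index=idx)
        labels = pd.Series([1] * 100 + [2] * 100, index=idx)
        (rec,) = [m for m in detect_markers(rates, labels)
                  if m.cazotype == 1]
        assert rec.p_adjusted < 1e-10 and 1.1 < rec.ratio < 1.3
        assert not rec.is_marker

    def test_planted_signatures_recovered(self):
        prof, truth = self.planted()
        model = cluster_and_select_k(sample_distance(prof))
        markers = detect_markers(prof.rates, model.labels)
        called = {(m.family, m.cazotype) for m in markers if m.is_marker}
        mapping = {c: truth.cazotype_of_sample[model.labels == c].mode()[0]
                   for c in model.labels.unique()}
        called_true = {(f, mapping[c]) for f, c in called}
        planted = {(f, c) for c, fams in truth.signature_families.items()
                   for f in fams}
        sens = len(called_true & planted) / len(planted)
        fdp = len(called_true - planted) / max(len(called_true), 1)
        assert sens >= 0.8
        assert fdp <= 0.1

    def test_small_group_errors(self):
        rates = pd.DataFrame({"GH1": [1.0, 2.0, 3.0, 4.0]},
                             index=["a", "b", "c", "d"])
        labels = pd.Series([1, 1, 1, 2], index=rates.index)
        with pytest.raises(ValueError, match="fewer than 3"):
            detect_markers(rates, labels)


class TestPreferenceTable:
    def test_single_geography_single_type(self):
        labels = pd.Series([1, 1, 1], index=["a", "b", "c"])
        geo = pd.Series(["X", "X", "X"], index=labels.index)
        tab = cazotype_preference_table(labels, geo)
        assert tab.loc["X", 1] == pytest.approx(100.0)

    def test_rows_sum_to_hundred(self):
        rng = np.random.default_rng(11)
        idx = [f"s{i}" for i in range(60)]
        labels = pd.Series(rng.integers(1, 4, 60), index=idx)
        geo = pd.Series(rng.choice(["X", "Y", "Z"], 60), index=idx)
        tab = cazotype_preference_table(labels, geo)
        assert np.allclose(tab.sum(axis=1), 100.0, atol=1e-9)

    def test_planted_geography_bias_recovered(self):
        prof, truth = simulate_profile(SimulationConfig(seed=23))
        tab = cazotype_preference_table(truth.cazotype_of_sample,
                                        prof.metadata["geography"])
        for c in (1, 2, 3):
            assert tab.loc[f"geo{c}"].idxmax() == c
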