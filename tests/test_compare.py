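"""Group comparisons, F_ST normalisation, partitioning and OLS models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from invadiv.compare import (NATIVE_RANGE_CORRECTIONS, compare_structure,
                             compare_invasive_vs_noninvasive,
                             fit_ibd_ibe_model, ibd_regression, mann_whitney,
                             mantel_permutations, normalize_fst_by_distance,
                             pair_vectors, partition_by_region, study_table)
from invadiv.dataio import LabeledDistanceMatrix, ValidationError

from conftest import meta_row


class TestMannWhitney:
    def test_complete_separation_gives_maximal_u(self):
        res = mann_whitney([10, 11, 12], [1, 2, 3, 4])
        assert res.U == 12 == res.n_first * res.n_second
        assert res.U + res.U_second == res.n_first * res.n_second

    def test_identical_multisets_give_central_u(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.U == 4.5  # n1*n2/2 with midranks
        assert res.p_value > 0.9

    def test_exact_method_used_for_small_untied_samples(self):
        res = mann_whitney([1.5, 3.7], [2.2, 9.9, 0.4])
        assert res.method == "exact"
        ref = stats.mannwhitneyu([1.5, 3.7], [2.2, 9.9, 0.4],
                                 alternative="two-sided", method="exact")
        assert res.p_value == ref.pvalue

    def test_tie_corrected_z_matches_p(self):
        x = [1, 1, 2, 3, 5, 5, 5]
        y = [2, 2, 3, 4, 4, 6]
        res = mann_whitney(x, y)
        assert res.method == "asymptotic"
        # z and the two-sided asymptotic p must tell the same story
        assert 2 * stats.norm.sf(abs(res.z)) == pytest.approx(res.p_value,
                                                              abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 20), min_size=1, max_size=8),
           st.lists(st.integers(0, 20), min_size=1, max_size=8))
    def test_u_statistics_of_both_orientations_sum_to_n1n2(self, x, y):
        a = mann_whitney(x, y)
        b = mann_whitney(y, x)
        assert a.U + b.U == pytest.approx(len(x) * len(y))
        assert a.U_second == pytest.approx(b.U)

    def test_null_calibration_on_identical_distributions(self):
        rng = np.random.default_rng(5)
        false_pos = 0
        for _ in range(50):
            x = rng.normal(size=12)
            y = rng.normal(size=15)
            false_pos += mann_whitney(x, y).p_value < 0.05
        assert false_pos <= 5  # p > 0.05 in >= 90% of null draws


class TestStudyComparisons:
    def test_range_corrections_only_touch_the_two_listed_sites(self):
        raw = study_table(apply_range_corrections=False)
        fixed = study_table()
        changed = raw.distribution != fixed.distribution
        touched = set(zip(fixed[changed].species, fixed[changed].population))
        assert touched == set(NATIVE_RANGE_CORRECTIONS)

    def test_segregating_sites_comparison_on_study_data(self):
        res = compare_invasive_vs_noninvasive(study_table(), "S")
        assert res.n_first == 27 and res.n_second == 16
        assert res.U == 214.0

    def test_group_with_no_native_rows_rejected(self):
        df = study_table()
        df = df[df.status == "invasive"]
        with pytest.raises(ValidationError):
            compare_invasive_vs_noninvasive(df, "Hd")


class TestNormalization:
    def _matrices(self, fst_vals, km):
        labels = [f"p{i}" for i in range(len(km))]
        f = LabeledDistanceMatrix(labels=labels, values=fst_vals, kind="fst")
        g = LabeledDistanceMatrix(labels=labels, values=km, kind="geographic")
        from invadiv.geo import log10_transform
        return f, log10_transform(g)

    def test_unit_mean_distance_is_identity(self):
        km = np.array([[0, 10.0], [10.0, 0]])     # log10 = 1 -> m = 1
        f, g = self._matrices(np.array([[0, 0.3], [0.3, 0]]), km)
        norm, m = normalize_fst_by_distance(f, g)
        assert m == pytest.approx(1.0)
        assert norm[("p0", "p1")] == pytest.approx(0.3)

    def test_hundred_km_halves_point_three(self):
        km = np.full((3, 3), 100.0)
        np.fill_diagonal(km, 0.0)
        fst = np.full((3, 3), 0.3)
        np.fill_diagonal(fst, 0.0)
        f, g = self._matrices(fst, km)
        norm, m = normalize_fst_by_distance(f, g)
        assert m == pytest.approx(2.0)
        assert all(v == pytest.approx(0.15) for v in norm.values())

    def test_random_fixture_matches_two_step_hand_computation(self, rng):
        k = 4
        km = rng.uniform(10, 5000, size=(k, k))
        km = (km + km.T) / 2
        np.fill_diagonal(km, 0.0)
        fst = rng.uniform(0, 1, size=(k, k))
        fst = (fst + fst.T) / 2
        np.fill_diagonal(fst, 0.0)
        f, g = self._matrices(fst, km)
        norm, m = normalize_fst_by_distance(f, g)
        iu = np.triu_indices(k, 1)
        hand_m = np.mean(np.log10(km[iu]))
        assert m == pytest.approx(hand_m)
        for (a, b), v in norm.items():
            assert v == pytest.approx(f.get(a, b) / hand_m)

    def test_mismatched_labels_rejected(self):
        f = LabeledDistanceMatrix(labels=["a", "b"],
                                  values=[[0, 0.1], [0.1, 0]], kind="fst")
        g = LabeledDistanceMatrix(labels=["a", "c"],
                                  values=[[0, 2.0], [2.0, 0]],
                                  kind="geographic_log10")
        with pytest.raises(ValidationError):
            normalize_fst_by_distance(f, g)

    def test_structure_comparison_invariant_to_population_relabeling(self):
        norm_a = {("x", "y"): 0.1, ("x", "z"): 0.5}
        norm_b = {("q", "r"): 0.3}
        res1 = compare_structure({"s1": norm_a, "s2": norm_b},
                                 {"s1": "invasive", "s2": "non_invasive"})
        renamed = {("deme1", "deme2"): 0.1, ("deme1", "deme3"): 0.5}
        res2 = compare_structure({"s1": renamed, "s2": norm_b},
                                 {"s1": "invasive", "s2": "non_invasive"})
        assert res1.U == res2.U and res1.p_value == res2.p_value


class TestPartition:
    def test_transatlantic_species_split_into_two_subsets(self):
        meta = [meta_row(population=f"na{i}", species="sp1",
                         region="North America") for i in range(4)]
        meta += [meta_row(population=f"eu{i}", species="sp1", region="Europe")
                 for i in range(4)]
        parts = partition_by_region(meta)
        assert set(parts) == {("sp1", "North America"), ("sp1", "Europe")}
        assert all(p["regressable"] for p in parts.values())

    def test_single_region_species_stays_whole(self):
        meta = [meta_row(population=f"p{i}", species="sp1", region="Baltic")
                for i in range(3)]
        parts = partition_by_region(meta)
        assert list(parts) == [("sp1", "Baltic")]

    def test_stepping_stone_species_not_split(self):
        meta = [meta_row(population=f"p{i}", species="wide",
                         region=r) for i, r in enumerate(
                    ["Europe", "Europe", "Iceland", "North America"])]
        parts = partition_by_region(meta, keep_whole={"wide"})
        assert list(parts) == [("wide", "all")]
        assert len(parts[("wide", "all")]["populations"]) == 4

    def test_small_subsets_flagged_non_regressable(self):
        meta = [meta_row(population=f"p{i}", species="sp1", region="r")
                for i in range(3)]
        parts = partition_by_region(meta)
        assert parts[("sp1", "r")]["regressable"] is False

    def test_unknown_region_label_rejected(self):
        meta = [meta_row(species="sp1", region="Atlantis")]
        with pytest.raises(ValidationError, match="Atlantis"):
            partition_by_region(meta, known_regions={"sp1": ["Europe"]})


class TestRegression:
    def test_noise_free_coefficients_recovered_exactly(self, rng):
        d = rng.uniform(0, 0.1, size=12)
        g = rng.uniform(1, 3, size=12)
        y = 0.2 + 11.77 * d + 0.484 * g
        res = fit_ibd_ibe_model(y, d, g)
        est = res.terms.estimate
        assert est["intercept"] == pytest.approx(0.2, abs=1e-9)
        assert est["evolutionary_distance"] == pytest.approx(11.77, abs=1e-9)
        assert est["geographic_distance"] == pytest.approx(0.484, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_t_equals_estimate_over_se(self, rng):
        d = rng.uniform(0, 0.1, size=10)
        g = rng.uniform(1, 3, size=10)
        y = 0.1 + 2 * d + rng.normal(scale=0.05, size=10)
        res = fit_ibd_ibe_model(y, d, g)
        for term in res.terms.index:
            row = res.terms.loc[term]
            assert abs(row.t) == pytest.approx(abs(row.estimate / row.se),
                                               abs=1e-9)

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(11)
        hits = {"evolutionary_distance": 0, "geographic_distance": 0}
        n_reps = 50
        for _ in range(n_reps):
            d = rng.uniform(0, 0.1, size=15)
            g = rng.uniform(1, 3, size=15)
            y = rng.normal(size=15)
            res = fit_ibd_ibe_model(y, d, g)
            for term in hits:
                hits[term] += res.terms.loc[term, "p"] < 0.05
        for term, count in hits.items():
            assert count <= 0.10 * n_reps

    def test_results_invariant_to_pair_order(self, rng):
        d = rng.uniform(0, 0.1, size=8)
        g = rng.uniform(1, 3, size=8)
        y = 0.1 + d + 0.2 * g + rng.normal(scale=0.01, size=8)
        res1 = fit_ibd_ibe_model(y, d, g)
        perm = rng.permutation(8)
        res2 = fit_ibd_ibe_model(y[perm], d[perm], g[perm])
        pd.testing.assert_frame_equal(res1.terms, res2.terms)

    def test_collinear_design_rejected(self):
        d = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        with pytest.raises(ValidationError, match="collinear"):
            fit_ibd_ibe_model(np.ones(5), d, 2 * d + 1)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError, match="at least 4"):
            fit_ibd_ibe_model([1, 2, 3], [1, 2, 3], [3, 2, 1])

    def test_geography_only_regression_matches_full_on_orthogonal_data(self, rng):
        g = rng.uniform(1, 3, size=20)
        y = 0.05 + 0.3 * g + rng.normal(scale=0.02, size=20)
        res = ibd_regression(y, g)
        assert res.terms.loc["geographic_distance", "estimate"] == \
               pytest.approx(0.3, abs=0.05)
        assert res.n_pairs == 20


def test_mantel_permutation_p_in_unit_interval(rng):
    k = 6
    base = rng.uniform(0, 1, size=(k, k))
    A = (base + base.T) / 2
    np.fill_diagonal(A, 0)
    noise = rng.uniform(0, 1, size=(k, k))
    B = A + 0.1 * (noise + noise.T) / 2
    np.fill_diagonal(B, 0)
    labels = [f"p{i}" for i in range(k)]
    f = LabeledDistanceMatrix(labels=labels, values=A, kind="fst")
    g = LabeledDistanceMatrix(labels=labels, values=B, kind="geographic_log10")
    p = mantel_permutations(f, g, n_perm=199, seed=1)
    assert 0 < p <= 1
    assert p < 0.2  # strongly correlated matrices


def test_pair_vectors_align_upper_triangles(rng):
    k = 4
    vals = rng.random((k, k))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0)
    labels = [f"p{i}" for i in range(k)]
    m = LabeledDistanceMatrix(labels=labels, values=vals, kind="fst")
    (v,) = pair_vectors(m)
    assert v.shape == (6,)
    assert v[0] == vals[0, 1]
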