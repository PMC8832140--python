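import numpy as np
import pytest

import normbench as nb
from normbench.errors import (
    DegenerateCenteringError,
    DegeneratePercentileError,
    NoReferenceError,
    RankError,
)

from conftest import make_matrix, make_groups

SCALING = ["TC", "UQ", "Med", "TMM", "DESeq", "PoissonSeq"]


def gmean(v):
    return np.exp(np.mean(np.log(v)))


class TestTotalCount:
    def test_factors_are_depth_over_mean(self):
        cm = make_matrix([[60, 180], [40, 120]])
        r = nb.norm_total_count(cm)
        assert r.scale_factors == pytest.approx([0.5, 1.5])
        # effective library sizes all equal the mean depth
        assert r.effective_lib_sizes == pytest.approx([200.0, 200.0])

    def test_equal_depths_are_identity(self):
        cm = make_matrix([[10, 20], [30, 20]])
        r = nb.norm_total_count(cm)
        assert r.scale_factors == pytest.approx([1.0, 1.0])
        assert np.array_equal(r.normalized, cm.counts)

    def test_single_sample(self):
        r = nb.norm_total_count(make_matrix([[5], [7]]))
        assert r.scale_factors == pytest.approx([1.0])


class TestPercentile:
    def test_upper_quartile_order_statistic(self):
        # brute-force linear-interpolation oracle on sorted (1,2,3,4):
        # rank position 1 + 0.75*(4-1) = 3.25 -> 3 + 0.25*(4-3) = 3.25
        cm = make_matrix([[1, 1], [2, 2], [3, 3], [4, 4]])
        sorted_counts = np.sort(cm.counts[:, 0])
        h = 1 + 0.75 * (len(sorted_counts) - 1)
        lo = sorted_counts[int(np.floor(h)) - 1]
        hi = sorted_counts[int(np.ceil(h)) - 1]
        oracle = lo + (h - np.floor(h)) * (hi - lo)
        assert oracle == 3.25
        r = nb.norm_percentile(cm, q=0.75)
        # two identical samples: factors 1, so p_i / gmean = 1 regardless
        assert r.scale_factors == pytest.approx([1.0, 1.0])

    @pytest.mark.parametrize("q", [0.5, 0.75, 0.9])
    def test_doubling_a_sample_doubles_its_factor(self, q, rng):
        base = rng.integers(1, 200, size=(60, 3)).astype(float)
        cm = make_matrix(base)
        doubled = base.copy()
        doubled[:, 2] *= 2
        r1 = nb.norm_percentile(cm, q=q)
        r2 = nb.norm_percentile(make_matrix(doubled), q=q)
        ratio = r2.scale_factors / r1.scale_factors
        # up to the geometric-mean renormalization, sample 2 doubles
        assert ratio[2] / gmean(ratio) == pytest.approx(2 / 2 ** (1 / 3))

    def test_zero_percentile_rejected(self):
        cm = make_matrix([[0, 5], [0, 5], [0, 5], [1, 5]])
        with pytest.raises(DegeneratePercentileError):
            nb.norm_percentile(cm, q=0.5)

    def test_registry_aliases_share_the_percentile_path(self, small_study):
        uq = nb.normalize(small_study.test, "UQ")
        med = nb.normalize(small_study.test, "Med")
        assert np.allclose(
            uq.scale_factors,
            nb.norm_percentile(small_study.test, q=0.75).scale_factors)
        assert np.allclose(
            med.scale_factors,
            nb.norm_percentile(small_study.test, q=0.5).scale_factors)


def tmm_oracle(x_i, x_r, d_i, d_r, trim_m=0.30, trim_a=0.05):
    """Literal transcription of the trim-and-weight formula on explicit
    sorted lists (independent of the implementation's vectorized path)."""
    entries = []
    for g in range(len(x_i)):
        if x_i[g] > 0 and x_r[g] > 0:
            pi, pr = x_i[g] / d_i, x_r[g] / d_r
            m = np.log2(pi / pr)
            a = 0.5 * np.log2(pi * pr)
            w = 1.0 / ((1 - pi) / x_i[g] + (1 - pr) / x_r[g])
            entries.append((m, a, w))
    n = len(entries)
    by_m = sorted(range(n), key=lambda i: entries[i][0])
    by_a = sorted(range(n), key=lambda i: entries[i][1])
    lo_m = int(np.floor(n * trim_m)) + 1
    lo_a = int(np.floor(n * trim_a)) + 1
    keep_m = set(by_m[lo_m - 1: n + 1 - lo_m])
    keep_a = set(by_a[lo_a - 1: n + 1 - lo_a])
    keep = keep_m & keep_a
    num = sum(entries[i][2] * entries[i][0] for i in keep)
    den = sum(entries[i][2] for i in keep)
    return 2.0 ** (num / den)


class TestTMM:
    def test_identical_to_reference_gives_unit_factor(self, rng):
        base = rng.integers(1, 300, size=(40, 1)).astype(float)
        cm = make_matrix(np.hstack([base, base]))
        r = nb.norm_tmm(cm, ref_sample="s0")
        # f_i = 1 for both, so s_i = d_i / mean(d) with equal depths = 1
        assert r.scale_factors == pytest.approx([1.0, 1.0])

    def test_pure_depth_shift_absorbed_by_library_size(self, rng):
        base = rng.integers(1, 300, size=(40, 1)).astype(float)
        cm = make_matrix(np.hstack([base, base * 2]))
        r = nb.norm_tmm(cm, ref_sample="s0")
        # all M_g = 0 after depth scaling: s proportional to depth
        assert r.scale_factors / gmean(r.scale_factors) == pytest.approx(
            [2 / 3 / gmean([2 / 3, 4 / 3]), 4 / 3 / gmean([2 / 3, 4 / 3])])

    def test_shifted_toy_matches_brute_force_oracle(self, rng):
        # 60 markers so the doubly-trimmed set stays above the fallback size
        base = rng.integers(20, 400, size=60).astype(float)
        x2 = base.copy()
        x2[[3, 11, 40]] *= 10  # a few markers 10-fold up in sample 2
        cm = make_matrix(np.column_stack([base, x2]))
        d = cm.library_sizes
        f2 = tmm_oracle(x2, base, d[1], d[0])
        f = np.array([1.0, f2])
        f /= gmean(f)
        expected = f * d / d.mean()
        r = nb.norm_tmm(cm, ref_sample="s0")
        assert r.scale_factors == pytest.approx(expected, rel=1e-12)

    def test_small_overlap_uses_untrimmed_weighted_mean(self, rng):
        # 20 markers leave < 10 after double trimming: the documented
        # fallback is the untrimmed precision-weighted mean
        base = rng.integers(20, 400, size=20).astype(float)
        x2 = base.copy()
        x2[[3, 11]] *= 10
        cm = make_matrix(np.column_stack([base, x2]))
        d = cm.library_sizes
        with pytest.warns(RuntimeWarning, match="trimming"):
            r = nb.norm_tmm(cm, ref_sample="s0")
        f2 = tmm_oracle(x2, base, d[1], d[0], trim_m=0.0, trim_a=0.0)
        f = np.array([1.0, f2])
        f /= gmean(f)
        assert r.scale_factors == pytest.approx(f * d / d.mean(), rel=1e-12)

    def test_sparse_overlap_falls_back_with_warning(self):
        x = np.zeros((12, 2))
        x[:6, 0] = [5, 8, 9, 11, 40, 100]
        x[4:, 1] = [7, 9, 30, 50, 60, 70, 80, 90]
        with pytest.warns(RuntimeWarning, match="trimming"):
            nb.norm_tmm(make_matrix(x), ref_sample="s0")


class TestDESeq:
    def test_proportional_columns_give_proportional_factors(self):
        c1 = np.array([10.0, 40, 7, 90, 3])
        cm = make_matrix(np.column_stack([c1, 3 * c1]))
        r = nb.norm_deseq(cm)
        assert r.scale_factors == pytest.approx(
            [1 / np.sqrt(3), np.sqrt(3)], rel=1e-12)

    def test_toy_matrix_matches_median_of_ratios_oracle(self, rng):
        x = rng.integers(1, 100, size=(5, 3)).astype(float)
        cm = make_matrix(x)
        # brute-force oracle: per-marker geometric-mean reference, per-sample
        # median ratio, geometric-mean anchoring
        ref = np.array([gmean(x[g]) for g in range(5)])
        f = np.array([np.median([x[g, i] / ref[g] for g in range(5)])
                      for i in range(3)])
        expected = f / gmean(f)
        assert nb.norm_deseq(cm).scale_factors == pytest.approx(
            expected, rel=1e-12)

    def test_no_all_positive_marker_raises(self):
        cm = make_matrix([[0, 5], [5, 0], [1, 0]])
        with pytest.raises(NoReferenceError):
            nb.norm_deseq(cm)


class TestPoissonSeq:
    def test_null_poisson_recovers_depth_proportions(self, rng):
        mu = rng.lognormal(3, 1, 400)
        lam = np.array([0.6, 1.0, 1.8])
        x = rng.poisson(mu[:, None] * lam[None, :]).astype(float)
        x[x.sum(axis=1) == 0, 0] = 1
        r = nb.norm_poissonseq(make_matrix(x))
        prop = r.scale_factors / r.scale_factors.sum()
        d = lam / lam.sum()
        assert prop == pytest.approx(d, rel=0.05)

    def test_identical_samples_give_unit_factors(self):
        base = np.arange(1.0, 31.0)[:, None]
        cm = make_matrix(np.hstack([base, base]))
        r = nb.norm_poissonseq(cm)
        assert r.scale_factors == pytest.approx([1.0, 1.0])

    def test_outlier_marker_does_not_drag_the_factors(self, rng):
        mu = rng.lognormal(3, 1, 300)
        x = rng.poisson(np.tile(mu[:, None], (1, 4))).astype(float)
        x[x.sum(axis=1) == 0, 0] = 1
        clean = x.copy()
        x[0, 3] += 2e5  # massive outlier in one sample
        r_out = nb.norm_poissonseq(make_matrix(x))
        tc_out = nb.norm_total_count(make_matrix(x))
        truth = np.ones(4)
        # the GOF window excludes the outlier marker; TC is dragged instead
        assert np.max(np.abs(r_out.scale_factors - truth)) < 0.05
        assert np.max(np.abs(tc_out.scale_factors - truth)) > 0.5
        del clean


class TestQuantile:
    def test_permuted_columns_map_to_common_profile(self, rng):
        col = rng.integers(0, 50, size=30).astype(float)
        col[0] = 1  # keep libraries positive
        perm = rng.permutation(col)
        r = nb.norm_quantile(make_matrix(np.column_stack([col, perm])))
        assert sorted(r.normalized[:, 0]) == pytest.approx(
            sorted(r.normalized[:, 1]))

    def test_rank_wise_means(self):
        cm = make_matrix([[1, 4], [2, 5], [3, 6]])
        r = nb.norm_quantile(cm)
        assert np.allclose(r.normalized[:, 0], [2.5, 3.5, 4.5])
        assert np.allclose(r.normalized[:, 1], [2.5, 3.5, 4.5])

    def test_ties_get_mean_of_their_rank_averages(self):
        cm = make_matrix([[1, 10], [1, 20], [4, 30]])
        r = nb.norm_quantile(cm)
        # column 0 sorted targets: (5.5, 10.5, 17); ties at ranks 1-2
        assert np.allclose(r.normalized[:, 0], [8.0, 8.0, 17.0])

    def test_single_sample_unchanged(self):
        cm = make_matrix([[3], [1], [2]])
        assert np.array_equal(nb.norm_quantile(cm).normalized, cm.counts)

    def test_column_multisets_identical_without_ties(self, rng):
        # ties aside, every column takes on exactly the common profile
        cols = [rng.choice(np.arange(1, 500), size=40, replace=False)
                for _ in range(5)]
        r = nb.norm_quantile(make_matrix(np.column_stack(cols).astype(float)))
        ref = np.sort(r.normalized[:, 0])
        for j in range(1, r.normalized.shape[1]):
            assert np.allclose(np.sort(r.normalized[:, j]), ref)


class TestRUV:
    def _batch_data(self, rng, strength=0.4):
        G, n = 400, 20
        mu = rng.lognormal(4, 1.0, G)
        group = np.array([0] * 10 + [1] * 10, float)
        b = rng.normal(0, 1, n)
        b -= b.mean()
        gc = group - group.mean()
        b -= (b @ gc) / (gc @ gc) * gc  # orthogonal to group
        b /= b.std()
        load = rng.normal(1.0, 0.2, G)
        x = rng.poisson(mu[:, None] * np.exp(strength * load[:, None]
                                             * b[None, :])).astype(float)
        x[x.sum(axis=1) == 0, 0] = 1
        cm = make_matrix(x)
        return cm, make_groups(cm), b

    def test_ruvg_recovers_planted_batch(self, rng):
        cm, ga, b = self._batch_data(rng)
        r = nb.norm_ruv(cm, ga, variant="g", k=1, controls=cm.marker_ids)
        corr = np.corrcoef(r.covariates[:, 0], b)[0, 1]
        assert abs(corr) > 0.95

    @pytest.mark.parametrize("variant", ["r", "s"])
    def test_other_variants_recover_batch_too(self, variant, rng):
        cm, ga, b = self._batch_data(rng)
        r = nb.norm_ruv(cm, ga, variant=variant, k=1,
                        controls=None if variant == "r" else cm.marker_ids)
        corr = np.corrcoef(r.covariates[:, 0], b)[0, 1]
        assert abs(corr) > 0.9

    def test_k_zero_rejected(self, small_study):
        with pytest.raises(RankError):
            nb.norm_ruv(small_study.test, small_study.groups, k=0)

    def test_k_at_least_n_rejected(self, small_study):
        with pytest.raises(RankError):
            nb.norm_ruv(small_study.test, small_study.groups, k=12)

    def test_ruvs_singleton_groups_degenerate(self):
        cm = make_matrix([[1, 2, 3, 4], [4, 3, 2, 1], [2, 2, 2, 2]])
        # constant control rows within groups -> centring removes everything
        const = make_matrix(np.tile([[5.0, 5, 7, 7]], (4, 1)))
        ga = nb.GroupAssignment(const.sample_ids, ("A", "A", "B", "B"))
        with pytest.raises(DegenerateCenteringError):
            nb.norm_ruv(const, ga, variant="s", k=1,
                        controls=const.marker_ids)
        del cm


class TestSVA:
    def test_pure_noise_estimates_k_zero_across_seeds(self):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(s)
            x = r.poisson(100, size=(200, 20)).astype(float)
            cm = make_matrix(x)
            res = nb.norm_sva(cm, make_groups(cm), seed=s)
            hits += res.covariates.shape[1] == 0
        assert hits >= 9

    def test_planted_factor_detected_and_recovered(self, rng):
        G, n = 300, 20
        mu = rng.lognormal(4, 0.5, G)
        b = rng.normal(0, 1, n)
        # centre within groups: the group-means fit removes that component,
        # so only the centred part of the truth is recoverable
        b[:10] -= b[:10].mean()
        b[10:] -= b[10:].mean()
        load = rng.normal(1.0, 0.3, G)
        x = rng.poisson(mu[:, None] * np.exp(0.8 * load[:, None]
                                             * b[None, :])).astype(float)
        x[x.sum(axis=1) == 0, 0] = 1
        cm = make_matrix(x)
        res = nb.norm_sva(cm, make_groups(cm), seed=1)
        assert res.covariates.shape[1] >= 1
        corr = np.corrcoef(res.covariates[:, 0], b)[0, 1]
        assert abs(corr) > 0.9

    def test_forced_k_gives_that_many_columns(self, small_study):
        res = nb.norm_sva(small_study.test, small_study.groups, k=2)
        assert res.covariates.shape == (12, 2)


class TestRegistryAndProperties:
    def test_builtin_census(self):
        reg = nb.builtin_methods()
        assert set(reg) == {"TC", "UQ", "Med", "TMM", "DESeq", "PoissonSeq",
                            "QN", "SVA", "RUVg", "RUVr", "RUVs"}

    def test_plugin_registration_round_trip(self, small_study):
        nb.register_method(
            "double", lambda c, g=None, **kw: nb.norm_total_count(c))
        try:
            r = nb.normalize(small_study.test, "double")
            assert r.method == "double"
            assert "double" not in nb.builtin_methods()
        finally:
            from normbench.normalization import _REGISTRY
            _REGISTRY.pop("double", None)

    @pytest.mark.parametrize("method", SCALING)
    def test_pure_depth_shift_maps_to_proportional_factors(self, method, rng):
        base = rng.integers(1, 60, size=80).astype(float)
        lam = np.array([1, 2, 5], dtype=float)
        cm = make_matrix(base[:, None] * lam[None, :])
        r = nb.normalize(cm, method, groups=make_groups(cm, split=1)
                         if False else None)
        s = r.scale_factors / gmean(r.scale_factors)
        expected = lam / gmean(lam)
        assert s == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("method", SCALING)
    def test_marker_reorder_invariance_and_sample_equivariance(
            self, method, rng):
        x = rng.integers(1, 200, size=(50, 4)).astype(float)
        cm = make_matrix(x)
        r = nb.normalize(cm, method)
        m_perm = rng.permutation(50)
        cm_m = nb.CountMatrix(tuple(cm.marker_ids[i] for i in m_perm),
                              cm.sample_ids, x[m_perm])
        assert nb.normalize(cm_m, method).scale_factors == pytest.approx(
            r.scale_factors, rel=1e-12)
        s_perm = np.array([2, 0, 3, 1])
        cm_s = nb.CountMatrix(cm.marker_ids,
                              tuple(cm.sample_ids[j] for j in s_perm),
                              x[:, s_perm])
        assert nb.normalize(cm_s, method).scale_factors == pytest.approx(
            r.scale_factors[s_perm], rel=1e-12)

    @pytest.mark.parametrize("method", ["UQ", "Med", "TMM", "DESeq"])
    def test_factors_have_unit_geometric_mean_before_depth(self, method,
                                                           small_study):
        r = nb.normalize(small_study.test, method)
        s = r.scale_factors
        if method in ("TMM",):
            d = small_study.test.library_sizes
            f = s * d.mean() / d
            assert gmean(f) == pytest.approx(1.0, rel=1e-10)
        else:
            assert gmean(s) == pytest.approx(1.0, rel=1e-10)
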