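"""Close-kin decomposition, kernel fitting, null ensemble and density test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from gravikin import closekin_kernel as ck


def _pair(cat, d, k=0):
    return ck.KinPair(f"a{k}", f"b{k}", cat, d)


class TestDecomposition:
    def test_third_degree_divisors(self):
        assert ck.decompose_pair(_pair("THIRD", 100.0)) == pytest.approx(
            [50.0, 100 / 3, 25.0, 20.0])

    def test_parent_offspring_single_divisor(self):
        assert ck.decompose_pair(_pair("PO", 60.0)) == [30.0]

    def test_zero_distance_rejected(self):
        with pytest.raises(ck.KernelError):
            _pair("FS", 0.0)

    def test_unknown_category(self):
        with pytest.raises(ck.KernelError, match="unknown"):
            ck.decompose_pair(_pair("FOURTH", 10.0))

    def test_pooled_size_identity_for_study_counts(self):
        pairs = ([_pair("FS", 50, k) for k in range(19)]
                 + [_pair("SECOND", 60, 100 + k) for k in range(18)]
                 + [_pair("THIRD", 70, 200 + k) for k in range(39)])
        sample = ck.pool_candidates(pairs)
        assert len(sample.values) == 19 * 2 + 18 * 4 + 39 * 4 == 266

    def test_single_po_pair(self):
        sample = ck.pool_candidates([_pair("PO", 80.0)])
        assert sample.values.tolist() == [40.0]

    def test_provenance_bijective(self):
        pairs = [_pair("FS", 30, 0), _pair("THIRD", 90, 1)]
        sample = ck.pool_candidates(pairs)
        recomputed = [p.d / m for p, m in sample.provenance]
        assert recomputed == sample.values.tolist()
        assert len(set((id(p), m) for p, m in sample.provenance)) == len(sample.values)

    @given(st.lists(st.tuples(
        st.sampled_from(["PO", "FS", "SECOND", "THIRD"]),
        st.floats(1.0, 1e4)), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pooled_size_identity_property(self, pair_specs):
        pairs = [_pair(c, d, k) for k, (c, d) in enumerate(pair_specs)]
        counts = {c: sum(1 for p in pairs if p.category == c)
                  for c in ck.DEFAULT_DECOMPOSITION}
        sample = ck.pool_candidates(pairs)
        expect = (2 * counts["FS"] + counts["PO"]
                  + 4 * counts["SECOND"] + 4 * counts["THIRD"])
        assert len(sample.values) == expect


class TestFitting:
    def test_exponential_closed_form(self):
        fit = ck.fit_kernel(np.array([10.0, 20, 30] * 4), "exponential")
        assert fit.params["rate"] == pytest.approx(0.05)

    def test_exponential_loglik_aic_hand_computed(self):
        values = np.array([10.0, 20.0, 30.0] * 4)
        fit = ck.fit_kernel(values, "exponential")
        lam = 12 / values.sum()
        ll = 12 * math.log(lam) - lam * values.sum()
        assert fit.loglik == pytest.approx(ll)
        assert fit.aic == pytest.approx(2 - 2 * ll)
        assert fit.bic == pytest.approx(math.log(12) - 2 * ll)

    def test_weibull_shape_one_matches_exponential(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(40.0, size=200)
        e = ck.fit_kernel(x, "exponential")
        w_ll = stats.weibull_min(1.0, scale=1 / e.params["rate"]).logpdf(x).sum()
        assert w_ll == pytest.approx(e.loglik)

    def test_closed_form_matches_numeric_optimizer(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x = rng.exponential(rng.uniform(5, 200), size=rng.integers(20, 500))
            closed = len(x) / x.sum()
            numeric = ck.exponential_rate_numeric(x)
            assert abs(numeric - closed) / closed < 1e-8

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ck.KernelError):
            ck.fit_kernel(np.array([1.0, -2.0] + [3.0] * 10), "exponential")

    def test_scale_equivariance(self):
        rng = np.random.default_rng(10)
        x = rng.exponential(30.0, size=300)
        c = 7.5
        e1, e2 = ck.fit_kernel(x, "exponential"), ck.fit_kernel(c * x, "exponential")
        assert 1 / e2.params["rate"] == pytest.approx(c / e1.params["rate"])
        l1, l2 = ck.fit_kernel(x, "lognormal"), ck.fit_kernel(c * x, "lognormal")
        assert math.exp(l2.params["meanlog"]) == pytest.approx(
            c * math.exp(l1.params["meanlog"]))
        assert l2.params["sdlog"] == pytest.approx(l1.params["sdlog"])
        w1, w2 = ck.fit_kernel(x, "weibull"), ck.fit_kernel(c * x, "weibull")
        assert w2.params["scale"] == pytest.approx(c * w1.params["scale"], rel=1e-4)


class TestBootstrap:
    def test_large_sample_coverage(self):
        rng = np.random.default_rng(11)
        x = rng.exponential(1 / 0.022, size=10000)
        fit = ck.bootstrap_fit(x, "exponential", n_boot=200, seed=12)
        med = fit.boot["rate"][0]
        assert 0.020 <= med <= 0.025
        assert fit.boot["rate"][1] <= med <= fit.boot["rate"][2]

    def test_reproducible_under_seed(self):
        x = np.random.default_rng(13).exponential(50.0, size=100)
        a = ck.bootstrap_fit(x, "lognormal", n_boot=50, seed=99)
        b = ck.bootstrap_fit(x, "lognormal", n_boot=50, seed=99)
        assert a.boot == b.boot

    def test_zero_boot_rejected(self):
        with pytest.raises(ck.KernelError):
            ck.bootstrap_fit(np.ones(20), "exponential", n_boot=0)


class TestSelection:
    def test_tie_stable_by_family_name(self):
        x = np.random.default_rng(14).exponential(20, 50)
        f = ck.fit_kernel(x, "exponential")
        g = ck.fit_kernel(x, "exponential")
        ranked = ck.select_best_fit([g, f])
        assert [r.family for r in ranked] == ["exponential", "exponential"]

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(15)
        f = ck.fit_kernel(rng.exponential(20, 50), "exponential")
        g = ck.fit_kernel(rng.exponential(20, 60), "lognormal")
        with pytest.raises(ck.KernelError):
            ck.select_best_fit([f, g])

    def test_qq_data_monotone(self):
        x = np.random.default_rng(16).exponential(20, 100)
        fit = ck.fit_kernel(x, "exponential")
        qq = ck.qq_data(fit, x)
        assert qq.shape == (100, 2)
        assert (np.diff(qq[:, 0]) >= 0).all() and (np.diff(qq[:, 1]) >= 0).all()


class TestQuantilesAndSummary:
    def test_exponential_quantiles_printed_values(self):
        fit = ck.KernelFit("exponential", {"rate": 0.022}, 0, 0, 0, 0, 100)
        assert round(ck.kernel_quantile(fit, 0.95)) == 136
        assert round(ck.kernel_quantile(fit, 0.5)) == 32

    def test_quantile_edges(self):
        fit = ck.KernelFit("exponential", {"rate": 0.02}, 0, 0, 0, 0, 10)
        assert ck.kernel_quantile(fit, 0.0) == 0.0
        with pytest.raises(ck.KernelError):
            ck.kernel_quantile(fit, 1.0)

    def test_exponential_mean_equals_sd(self):
        fit = ck.KernelFit("exponential", {"rate": 0.02}, 0, 0, 0, 0, 10)
        s = ck.kernel_summary(fit)
        assert s["mean"] == pytest.approx(50.0)
        assert s["sd"] == pytest.approx(50.0)

    def test_weibull_shape_one_mean_is_scale(self):
        fit = ck.KernelFit("weibull", {"shape": 1.0, "scale": 37.0}, 0, 0, 0, 0, 10)
        assert ck.kernel_summary(fit)["mean"] == pytest.approx(37.0)

    def test_lognormal_mean_formula(self):
        fit = ck.KernelFit("lognormal", {"meanlog": 3.322, "sdlog": 1.162}, 0, 0, 0, 0, 10)
        expect = math.exp(3.322 + 1.162 ** 2 / 2)
        assert ck.kernel_summary(fit)["mean"] == pytest.approx(expect)
        assert expect == pytest.approx(54.5, abs=0.5)


class TestLocationKernel:
    def test_normalization_round_trip_2d(self):
        fit = ck.KernelFit("exponential", {"rate": 0.03}, 0, 0, 0, 0, 10)
        k_l = ck.distance_to_location_kernel(fit, 2)
        total, _ = integrate.quad(lambda r: 2 * np.pi * r * k_l(r), 1e-9, 2000,
                                  limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_algebraic_identity(self):
        lam = 0.022
        fit = ck.KernelFit("exponential", {"rate": lam}, 0, 0, 0, 0, 10)
        k_l = ck.distance_to_location_kernel(fit, 2)
        assert k_l(100.0) * 2 * np.pi * 100 == pytest.approx(lam * np.exp(-100 * lam))

    def test_3d_round_trip(self):
        fit = ck.KernelFit("weibull", {"shape": 1.3, "scale": 60.0}, 0, 0, 0, 0, 10)
        k_l = ck.distance_to_location_kernel(fit, 3)
        r = np.linspace(1, 500, 50)
        k_d = k_l(r) * 4 * np.pi * r ** 2
        assert np.allclose(k_d, stats.weibull_min(1.3, scale=60).pdf(r), atol=1e-6)

    def test_nonpositive_r_rejected(self):
        fit = ck.KernelFit("exponential", {"rate": 0.02}, 0, 0, 0, 0, 10)
        with pytest.raises(ck.KernelError):
            ck.distance_to_location_kernel(fit, 2)(0.0)


class TestNullEnsemble:
    def test_replicate_sizes_match_counts(self):
        rng = np.random.default_rng(17)
        pool = rng.uniform(10, 400, size=1000)
        ens = ck.build_null_ensemble(pool, {"FS": 19, "SECOND": 18, "THIRD": 39},
                                     n_rep=5, seed=18)
        for s in ens.samples:
            assert len(s.values) == 266

    def test_constant_pool(self):
        ens = ck.build_null_ensemble(np.array([100.0]), {"THIRD": 3}, n_rep=2, seed=1)
        for s in ens.samples:
            assert set(np.round(s.values, 6)) <= {50.0, round(100 / 3, 6), 25.0, 20.0}

    def test_seed_reproducibility(self):
        pool = np.random.default_rng(19).uniform(5, 300, 200)
        a = ck.build_null_ensemble(pool, {"FS": 4, "THIRD": 3}, n_rep=3, seed=7)
        b = ck.build_null_ensemble(pool, {"FS": 4, "THIRD": 3}, n_rep=3, seed=7)
        for sa, sb in zip(a.samples, b.samples):
            assert np.array_equal(sa.values, sb.values)

    def test_empty_pool_rejected(self):
        with pytest.raises(ck.KernelError):
            ck.build_null_ensemble(np.array([]), {"FS": 1})

    def test_null_differs_from_shifted_kin(self):
        # close-kin candidates at half the pool median separate clearly
        rng = np.random.default_rng(20)
        pool = rng.exponential(200.0, size=400) + 20
        ens = ck.build_null_ensemble(pool, {"FS": 10, "SECOND": 10, "THIRD": 10},
                                     n_rep=1, seed=21)
        kin_pairs = [_pair(c, d, k) for k, (c, d) in enumerate(
            [(c, float(rng.exponential(np.median(pool) / 2) + 5))
             for c in ["FS", "SECOND", "THIRD"] * 10])]
        kin_sample = ck.pool_candidates(kin_pairs)
        _, p = ck.density_equality_test(kin_sample.values, ens.samples[0].values,
                                        n_perm=499, seed=22)
        assert p < 0.01


class TestDensityEqualityTest:
    def test_identical_samples(self):
        x = np.linspace(1, 10, 20)
        stat, p = ck.density_equality_test(x, x.copy(), n_perm=199, seed=0)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_disjoint_samples_minimum_p(self):
        a = np.linspace(0, 1, 30)
        b = np.linspace(100, 101, 30)
        _, p = ck.density_equality_test(a, b, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_degenerate_input(self):
        with pytest.raises(ck.KernelError, match="zero variance"):
            ck.density_equality_test(np.ones(10), np.ones(10))

    def test_seed_reproducible(self):
        rng = np.random.default_rng(23)
        a, b = rng.exponential(40, 30), rng.exponential(45, 25)
        r1 = ck.density_equality_test(a, b, n_perm=299, seed=5)
        r2 = ck.density_equality_test(a, b, n_perm=299, seed=5)
        assert r1 == r2
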