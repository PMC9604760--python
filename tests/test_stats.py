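import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcl6quant._stineman import stineman_interp
from bcl6quant.errors import ContractError, DegenerateInputError
from bcl6quant.quantification import IntensityDistribution
from bcl6quant.stats import (
    GroupDistribution,
    correlate_hscore,
    distribution_percentiles,
    fit_gaussian,
    mann_whitney,
    mean_distribution,
    pointwise_mann_whitney,
    smooth_curve,
)
from bcl6quant.synthetic import IntensitySpec, sample_group_distributions


def norm_dist(counts):
    counts = np.asarray(counts, dtype=float)
    return IntensityDistribution(
        counts=counts / counts.sum(), normalized=True, n_pixels=int(counts.sum())
    )


def curve_from(mean, sem=None):
    mean = np.asarray(mean, float)
    sem = np.zeros_like(mean) if sem is None else np.asarray(sem, float)
    return GroupDistribution(levels=np.arange(mean.size, dtype=float),
                             mean=mean, sem=sem, n_sections=2)


class TestMeanDistribution:
    def test_identical_sections_have_zero_sem(self):
        c = np.zeros(256)
        c[40] = 3
        dists = [norm_dist(c)] * 4
        g = mean_distribution(dists)
        np.testing.assert_allclose(g.mean, dists[0].counts)
        assert (g.sem == 0).all()
        assert g.n_sections == 4

    def test_two_point_masses_average_to_half(self):
        a = np.zeros(256); a[10] = 1
        b = np.zeros(256); b[20] = 1
        g = mean_distribution([norm_dist(a), norm_dist(b)])
        assert g.mean[10] == g.mean[20] == 0.5

    def test_matches_loop_oracle_and_is_order_invariant(self, rng):
        mats = rng.dirichlet(np.ones(256), size=5)
        dists = [IntensityDistribution(m, normalized=True) for m in mats]
        g = mean_distribution(dists)
        for lvl in range(0, 256, 17):
            vals = [m[lvl] for m in mats]
            assert g.mean[lvl] == pytest.approx(np.mean(vals))
            assert g.sem[lvl] == pytest.approx(np.std(vals, ddof=1) / np.sqrt(5))
        g2 = mean_distribution(dists[::-1])
        np.testing.assert_allclose(g.mean, g2.mean)
        np.testing.assert_allclose(g.sem, g2.sem)

    def test_raw_distributions_rejected(self):
        raw = IntensityDistribution(np.ones(256), normalized=False, n_pixels=256)
        with pytest.raises(ContractError):
            mean_distribution([raw])


class TestSmoothing:
    def test_linear_data_reproduced_exactly(self):
        x = np.arange(20.0)
        y = 3.0 * x + 2.0
        xi = np.linspace(0, 19, 191)
        np.testing.assert_allclose(stineman_interp(xi, x, y), 3.0 * xi + 2.0, atol=1e-12)

    def test_interpolant_passes_through_data_points(self, rng):
        x = np.arange(30.0)
        y = rng.random(30)
        np.testing.assert_allclose(stineman_interp(x, x, y), y, atol=0)

    def test_monotone_under_scheme_conditions(self):
        # Stineman's guarantee: monotone ordinates with monotone chord
        # slopes give a monotone interpolant
        x = np.arange(25.0)
        for y in (x**2, np.exp(x / 5.0), np.sqrt(x + 1)):
            yi = stineman_interp(np.linspace(0, 24, 2401), x, y)
            assert (np.diff(yi) >= -1e-12).all()

    def test_no_new_extrema_on_unimodal_curve(self):
        x = np.arange(256.0)
        y = np.exp(-((x - 90) ** 2) / (2 * 25**2))
        yi = stineman_interp(np.linspace(0, 255, 2551), x, y)
        d = np.diff(yi)
        sign_changes = np.sum((d[:-1] > 1e-14) & (d[1:] < -1e-14)) + np.sum(
            (d[:-1] < -1e-14) & (d[1:] > 1e-14)
        )
        assert sign_changes <= 1  # only the data's own peak

    def test_smooth_curve_contains_original_points(self):
        mean = np.zeros(256)
        mean[50:150] = np.hamming(100)
        curve = curve_from(mean / mean.sum())
        out = smooth_curve(curve, grid_factor=4)
        assert out.levels.size == 255 * 4 + 1
        np.testing.assert_allclose(out.mean[::4], curve.mean, atol=1e-12)
        assert (out.mean >= 0).all() and (out.sem >= 0).all()

    def test_too_few_points_rejected(self):
        tiny = GroupDistribution(levels=np.arange(2.0), mean=np.ones(2),
                                 sem=np.zeros(2), n_sections=1)
        with pytest.raises(ContractError):
            smooth_curve(tiny)


class TestPercentiles:
    def test_point_mass_returns_its_level(self):
        mean = np.zeros(256)
        mean[42] = 1.0
        pct = distribution_percentiles(curve_from(mean))
        assert pct.p10 == pct.p25 == pct.p50 == pct.p75 == pct.p90 == 42.0

    def test_uniform_symmetry(self):
        mean = np.zeros(256)
        mean[: 101] = 1.0
        pct = distribution_percentiles(curve_from(mean))
        assert pct.p50 == pytest.approx(50.0, abs=0.5)

    def test_matches_cdf_inversion_oracle(self, rng):
        mean = rng.random(256)
        mean[rng.random(256) > 0.6] = 0.0
        pct = distribution_percentiles(curve_from(mean))
        # brute-force: walk the CDF over mass-carrying levels
        support = [i for i in range(256) if mean[i] > 0]
        cum = np.cumsum([mean[i] for i in support]) / mean.sum()
        for prob, value in pct.as_dict().items():
            q = float(prob[1:]) / 100.0
            i = next(k for k in range(len(support)) if cum[k] >= q)
            if i == 0:
                expected = support[0]
            else:
                expected = support[i - 1] + (q - cum[i - 1]) / (cum[i] - cum[i - 1]) * (
                    support[i] - support[i - 1]
                )
            assert value == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_percentile_monotonicity(self, seed):
        mean = np.random.default_rng(seed).random(256) ** 3
        pct = distribution_percentiles(curve_from(mean))
        vals = [pct.p10, pct.p25, pct.p50, pct.p75, pct.p90]
        assert all(a <= b for a, b in itertools.pairwise(vals))

    def test_zero_mass_rejected(self):
        with pytest.raises(DegenerateInputError):
            distribution_percentiles(curve_from(np.zeros(256)))


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_separated_samples_exact_p(self):
        # all 3 values of a below all of b: U = 0 and exact two-sided
        # p = 2 / C(6,3) = 0.1 (verified by enumerating label permutations)
        u, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(2.0 / 20.0)

    def test_enumeration_oracle_small_samples(self, rng):
        from itertools import combinations

        a = rng.normal(size=4)
        b = rng.normal(size=3) + 0.5
        u_obs, p = mann_whitney(a, b)
        pooled = np.concatenate([a, b])
        n = a.size
        us = []
        for idx in combinations(range(pooled.size), n):
            sel = pooled[list(idx)]
            rest = np.delete(pooled, list(idx))
            us.append(sum((x > y) + 0.5 * (x == y) for x in sel for y in rest))
        us = np.asarray(us)
        mid = n * b.size / 2.0
        expected = np.mean(np.abs(us - mid) >= abs(u_obs - mid) - 1e-12)
        assert p == pytest.approx(expected)

    def test_swap_symmetry(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=9)
        assert mann_whitney(a, b)[1] == pytest.approx(mann_whitney(b, a)[1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(size=8)
        b = r.normal(size=10)
        _, p_raw = mann_whitney(a, b)
        _, p_exp = mann_whitney(np.exp(a), np.exp(b))
        _, p_cub = mann_whitney(a**3, b**3)
        assert p_raw == pytest.approx(p_exp)
        assert p_raw == pytest.approx(p_cub)

    def test_empty_sample_rejected(self):
        with pytest.raises(ContractError):
            mann_whitney([], [1.0])


class TestPointwise:
    def test_identical_groups_flag_nothing(self, rng):
        mats = rng.dirichlet(np.ones(256), size=3)
        dists = [IntensityDistribution(m, normalized=True) for m in mats]
        test = pointwise_mann_whitney(dists, dists)
        assert not test.significant.any()
        assert (test.p_values == 1.0).all()

    def test_shifted_group_flags_upper_range(self, rng):
        # emulates the skewed heterogeneous patient groups: a +40 shift
        # of the lognormal median shows up mostly above the lower
        # group's median intensity
        a = sample_group_distributions(IntensitySpec("lognormal", 35, 0.65), 5,
                                       between_section_sd=12, rng=rng)
        b = sample_group_distributions(IntensitySpec("lognormal", 75, 0.65), 5,
                                       between_section_sd=12, rng=rng)
        test = pointwise_mann_whitney(a, b)
        sig = np.flatnonzero(test.significant)
        assert sig.size > 0
        p50_a = distribution_percentiles(mean_distribution(a)).p50
        assert (sig > p50_a).mean() >= 0.7

    def test_too_few_sections_rejected(self, rng):
        one = [norm_dist(rng.random(256) + 0.01)]
        two = one * 2
        with pytest.raises(ContractError):
            pointwise_mann_whitney(one, two)

    def test_bh_correction_never_increases_significance(self, rng):
        a = sample_group_distributions(IntensitySpec("gaussian", 120, 25), 4, rng=rng)
        b = sample_group_distributions(IntensitySpec("gaussian", 140, 25), 4, rng=rng)
        raw = pointwise_mann_whitney(a, b)
        bh = pointwise_mann_whitney(a, b, correction="bh")
        assert bh.significant.sum() <= raw.significant.sum()
        assert (bh.p_values >= raw.p_values - 1e-12).all()


class TestGaussianFit:
    def test_noiseless_recovery_to_machine_precision(self):
        x = np.arange(256.0)
        y = 2.0 * np.exp(-((x - 60) ** 2) / (2 * 15**2))
        fit = fit_gaussian(curve_from(y))
        assert fit.converged
        assert fit.amplitude == pytest.approx(2.0, rel=1e-6)
        assert fit.mu == pytest.approx(60.0, rel=1e-6)
        assert fit.sigma == pytest.approx(15.0, rel=1e-6)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-12)

    def test_mu_within_one_level_under_noise(self, rng):
        x = np.arange(256.0)
        y0 = 2.0 * np.exp(-((x - 60) ** 2) / (2 * 15**2))
        for _ in range(10):
            y = y0 + rng.normal(0, 0.02, 256)  # 1% of amplitude
            fit = fit_gaussian(curve_from(np.maximum(y, 0)))
            assert abs(fit.mu - 60.0) < 1.0

    def test_symmetric_curve_centre(self):
        x = np.arange(256.0)
        y = np.exp(-np.abs(x - 100) / 20.0)  # symmetric, non-Gaussian
        fit = fit_gaussian(curve_from(y))
        assert fit.mu == pytest.approx(100.0, abs=0.1)

    def test_too_few_positive_points_rejected(self):
        mean = np.zeros(256)
        mean[10:13] = 1.0
        with pytest.raises(ContractError):
            fit_gaussian(curve_from(mean))


class TestRegression:
    def test_collinear_points(self):
        pairs = [(2 * x + 1, x) for x in (1.0, 2.0, 3.0, 4.0)]
        res = correlate_hscore(pairs)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.n == 4

    def test_matches_closed_form_least_squares(self, rng):
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(size=30)
        res = correlate_hscore(list(zip(y, x)))
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        assert res.slope == pytest.approx(sxy / sxx)
        assert res.intercept == pytest.approx(y.mean() - res.slope * x.mean())
        assert res.r == pytest.approx(sxy / np.sqrt(sxx * ((y - y.mean()) ** 2).sum()))

    def test_permuted_pairs_rarely_significant(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.normal(size=50)
            y = r.permutation(r.normal(size=50))
            res = correlate_hscore(list(zip(y, x)))
            hits += res.p_value < 0.05
        assert hits <= 10  # ~5% expected under the null

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            correlate_hscore([(1.0, 5.0), (1.0, 6.0), (1.0, 7.0)])
        with pytest.raises(ContractError):
            correlate_hscore([(1.0, 2.0)])
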