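import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from conftest import TABLE1_ALL, TABLE1_ERPOS
from mixpop.mixture import (
    BinnedFrequency,
    FitError,
    GaussianComponent,
    bin_values,
    component_auc,
    fit_mixture,
    gaussian_sum,
    ks_normality,
    probit_coordinates,
    select_model,
)
from mixpop.simulate import SyntheticConfig, sample_mixture

SQRT2PI = math.sqrt(2 * math.pi)


def table1_components():
    return [
        GaussianComponent(a, m, s)
        for a, m, s in zip(
            TABLE1_ALL["amplitudes"], TABLE1_ALL["means"], TABLE1_ALL["sds"]
        )
    ]


class TestBinning:
    def test_half_open_edge_semantics(self):
        freq = bin_values([5.0, 5.05, 5.19, 5.2], bin_width=0.2)
        edges = dict(zip(np.round(freq.left_edges, 10), freq.counts))
        assert edges[5.0] == 3
        assert edges[5.2] == 1

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=2,
            max_size=200,
        )
    )
    def test_counts_conserve_sample_size(self, values):
        freq = bin_values(values, bin_width=0.2)
        assert freq.counts.sum() == len(values)

    def test_interior_empty_bins_retained(self):
        freq = bin_values([0.05, 1.05], bin_width=0.2)
        assert freq.n_bins == 6
        assert freq.counts[1] == 0

    def test_modal_bin_mass_of_standard_normal(self):
        # integral of the standard normal pdf over [0, 0.2) is 0.0793
        values = np.random.default_rng(0).normal(size=10_000)
        freq = bin_values(values, bin_width=0.2)
        assert freq.counts.max() / 10_000 == pytest.approx(0.0793, abs=0.01)

    def test_rejects_empty_and_bad_width(self):
        with pytest.raises(ValueError):
            bin_values([], bin_width=0.2)
        with pytest.raises(ValueError):
            bin_values([1.0, 2.0], bin_width=0.0)


class TestGaussianSum:
    def test_peak_equals_amplitude(self):
        c = [GaussianComponent(1.0, 0.0, 1.0)]
        assert gaussian_sum(0.0, c) == pytest.approx(1.0)

    def test_one_sd_from_peak(self):
        c = [GaussianComponent(1.0, 0.0, 1.0)]
        assert gaussian_sum(1.0, c) == pytest.approx(math.exp(-0.5))

    def test_trimodal_evaluation_at_low_mean(self):
        # hand computation: 104 + 54*exp(-0.5*((6.25-7.89)/1.12)^2)
        #                       + 68*exp(-0.5*((6.25-10.58)/0.86)^2) = 122.484
        assert gaussian_sum(6.25, table1_components()) == pytest.approx(
            122.4844, abs=1e-3
        )


class TestComponentAuc:
    def test_unit_component(self):
        assert component_auc(GaussianComponent(1.0, 0.0, 1.0)) == pytest.approx(
            SQRT2PI, abs=1e-4
        )

    def test_low_component_area(self):
        assert component_auc(GaussianComponent(104, 6.25, 0.39)) == pytest.approx(
            101.669, abs=1e-3
        )

    def test_normalized_weights_reproduce_subpopulation_percentages(self):
        aucs = np.array([component_auc(c) for c in table1_components()])
        weights = 100 * aucs / aucs.sum()
        np.testing.assert_allclose(weights, [25.43, 37.91, 36.66], atol=0.01)

    def test_er_positive_row_percentages(self):
        aucs = np.array(
            [a * s * SQRT2PI for a, s in zip(TABLE1_ERPOS["amplitudes"], TABLE1_ERPOS["sds"])]
        )
        weights = 100 * aucs / aucs.sum()
        assert round(weights[1]) == 44
        assert round(weights[2]) == 46


class TestFitMixture:
    def test_noiseless_two_component_recovery(self):
        truth = [GaussianComponent(80.0, 5.0, 0.5), GaussianComponent(50.0, 8.0, 1.0)]
        edges = np.arange(2.0, 12.0, 0.2)
        freq = BinnedFrequency(0.2, edges, gaussian_sum(edges + 0.1, truth))
        fit = fit_mixture(freq, 2, n_starts=3, seed=0)
        assert fit.converged
        for got, want in zip(fit.components, truth):
            assert got.amplitude == pytest.approx(want.amplitude, abs=1e-6)
            assert got.mean == pytest.approx(want.mean, abs=1e-6)
            assert got.sd == pytest.approx(want.sd, abs=1e-6)

    def test_trimodal_recovery_and_fit_quality(self, trimodal_sample):
        """Single-seed recovery at 3 sigma of the estimator's sampling SD.

        Over repeated draws the binned-LS high-mean estimate scatters with
        SD ~ 0.12 around 10.58 (the components overlap); the tight +/-0.1
        claim is asserted on the median in
        ``test_median_mean_recovery_over_seeds``.
        """
        values, _ = trimodal_sample
        freq = bin_values(values, 0.2)
        fit = fit_mixture(freq, 3, n_starts=3, seed=11)
        assert fit.converged
        assert fit.components == sorted(fit.components, key=lambda c: c.mean)
        assert fit.means[-1] == pytest.approx(10.58, abs=0.35)
        assert fit.means[0] == pytest.approx(6.25, abs=0.12)
        assert fit.pearson_r_obs_pred >= 0.96
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_component_fit_is_markedly_worse(self, trimodal_sample):
        values, _ = trimodal_sample
        freq = bin_values(values, 0.2)
        r3 = fit_mixture(freq, 3, seed=11).pearson_r_obs_pred
        r1 = fit_mixture(freq, 1, seed=11).pearson_r_obs_pred
        assert r1 < r3 - 0.05

    def test_area_conservation_for_separated_fit(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(5, 0.5, 1200), rng.normal(10, 0.8, 800)])
        freq = bin_values(values, 0.2)
        fit = fit_mixture(freq, 2, seed=5)
        riemann = fit.predicted_counts.sum() * freq.bin_width
        assert riemann == pytest.approx(fit.aucs.sum(), rel=0.02)

    def test_median_mean_recovery_over_seeds(self):
        """Median recovery error over 20 cohort-sized draws.

        The outer components recover within 0.1 log2 units in the median.
        The intermediate component (SD 1.12, overlapped on both flanks)
        carries a small upward bias in the binned least-squares estimator
        (median error ~0.12), so it is held to a wider bound.
        """
        errors = {0: [], 1: [], 2: []}
        for seed in range(20):
            values, _ = sample_mixture(SyntheticConfig(seed=seed))
            fit = fit_mixture(bin_values(values, 0.2), 3, seed=seed)
            for k, true_mean in enumerate(TABLE1_ALL["means"]):
                errors[k].append(abs(fit.means[k] - true_mean))
        assert np.median(errors[0]) <= 0.1
        assert np.median(errors[2]) <= 0.1
        assert np.median(errors[1]) <= 0.2

    def test_too_few_bins_rejected(self):
        freq = BinnedFrequency(0.2, np.arange(0, 1.2, 0.2), np.ones(6))
        with pytest.raises(FitError, match="bins"):
            fit_mixture(freq, 2)


class TestSelectModel:
    def test_trimodal_data_selects_three(self, trimodal_sample):
        values, _ = trimodal_sample
        fit = select_model(bin_values(values, 0.2), seed=11)
        assert fit.n_components == 3
        assert set(fit.candidates) == {1, 2, 3}

    def test_single_gaussian_selects_one(self):
        values = np.random.default_rng(1).normal(8.0, 1.0, 1980)
        assert select_model(bin_values(values, 0.2), seed=1).n_components == 1

    def test_two_separated_components_selects_two(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(5, 0.5, 1000), rng.normal(10, 0.5, 980)])
        assert select_model(bin_values(values, 0.2), seed=2).n_components == 2


class TestNormality:
    def test_normal_sample_not_rejected(self):
        values = np.random.default_rng(3).normal(size=1980)
        assert ks_normality(values).p_value > 0.05

    def test_trimodal_sample_strongly_rejected(self, trimodal_sample):
        values, _ = trimodal_sample
        res = ks_normality(values)
        assert res.p_value < 0.0001
        assert 0 <= res.ks_distance <= 1

    def test_exact_quantile_sample_has_minimal_distance(self):
        # values at the (i-0.5)/n plotting positions minimise D; with the
        # location and scale re-estimated from the sample the supremum sits
        # just above the 1/(2n) plotting-position floor
        n = 1000
        values = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        d = ks_normality(values).ks_distance
        assert 1 / (2 * n) <= d <= 1.2 / (2 * n)

    def test_small_sample_uses_deterministic_bootstrap(self):
        values = np.random.default_rng(4).normal(size=20)
        a = ks_normality(values, seed=1)
        b = ks_normality(values, seed=1)
        assert a.p_value == b.p_value
        assert 0 < a.p_value <= 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])


class TestProbit:
    def test_normal_sample_is_linear(self):
        values = np.random.default_rng(6).normal(5, 2, 1000)
        x, q = probit_coordinates(values)
        assert np.corrcoef(x, q)[0, 1] > 0.995

    def test_trimodal_less_linear_than_matched_normal(self, trimodal_sample):
        values, _ = trimodal_sample
        x, q = probit_coordinates(values)
        r_tri = np.corrcoef(x, q)[0, 1]
        control = np.random.default_rng(7).normal(
            values.mean(), values.std(), len(values)
        )
        xc, qc = probit_coordinates(control)
        assert r_tri < np.corrcoef(xc, qc)[0, 1]

    def test_two_point_closed_form(self):
        _, q = probit_coordinates([3.0, 1.0])
        np.testing.assert_allclose(q, [-0.6745, 0.6745], atol=1e-4)


class TestOracleEquivalence:
    def test_binned_fit_agrees_with_em_on_raw_values(self):
        """Least squares on bins vs maximum-likelihood EM on raw values."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(8)
        values = np.concatenate([rng.normal(6, 0.5, 2000), rng.normal(10, 0.8, 3000)])
        fit = fit_mixture(bin_values(values, 0.2), 2, seed=8)
        em = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(
            values.reshape(-1, 1)
        )
        order = np.argsort(em.means_.ravel())
        em_means = em.means_.ravel()[order]
        em_weights = em.weights_[order]
        np.testing.assert_allclose(fit.means, em_means, atol=0.1)
        np.testing.assert_allclose(fit.weights, em_weights, atol=0.05)
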