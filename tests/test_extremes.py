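"""Extreme-value laws of the earliest binding events."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import gammainc
from scipy.stats import kstest

from chemosense.extremes import (
    ErrorLaw,
    error_moments,
    gumbel_scaling,
    hypoexponential_cdf,
    hypoexponential_pdf,
    kth_arrival_density,
    kth_arrival_mode,
    lambda1_asymptotic,
    lambda_k,
    nu_log_factor,
    optimal_k,
    sample_hypoexponential,
    sample_kth_arrival,
    survival_prefactor_h,
    survival_short_time,
)
from chemosense.homogenized import HomogenizedParams, total_flux_rho


@pytest.fixture(scope="module")
def tradeoff_params():
    """The K-averaging study conditions."""
    return HomogenizedParams(R=4.4, D=1.0, kappa=3.36)


@pytest.fixture(scope="module")
def scaling(tradeoff_params):
    return gumbel_scaling(100_000, tradeoff_params, "numeric")


class TestSurvival:
    def test_approaches_one_at_short_times(self, ref_params):
        assert survival_short_time(1e-4, ref_params) == pytest.approx(1.0, abs=1e-100)

    def test_decreasing_on_validity_window(self, ref_params):
        t = np.geomspace(0.05, 0.3, 25)
        S = survival_short_time(t, ref_params)
        assert np.all(np.diff(S) <= 0)
        assert S[-1] < S[0] <= 1.0
        assert S[-1] < 1.0

    def test_tracks_flux_quadrature_within_asymptotic_error(self, ref_params):
        """1 - S(t) matches the integral of the capture-time density with
        the O(D t/(R-1)^2) relative error intrinsic to the asymptote."""
        R, D = ref_params.R, ref_params.D
        for t in np.geomspace(0.05, 0.2, 5):
            integral, _ = quad(lambda u: total_flux_rho(u, ref_params), 0.0, t,
                               limit=300, epsabs=0.0, epsrel=1e-10)
            # 1 - S evaluated in its product form: the subtraction from 1
            # underflows below t ~ 0.1 where 1 - S < 1e-16
            approx = survival_prefactor_h(t, ref_params) * np.exp(
                -((R - 1.0) ** 2) / (4.0 * D * t))
            bound = 9.0 * D * t / (R - 1.0) ** 2
            assert abs(approx / integral - 1.0) < bound

    def test_warns_outside_validity(self, ref_params):
        with pytest.warns(RuntimeWarning):
            survival_short_time(1e4, ref_params)


class TestGumbelScaling:
    def test_more_particles_bind_sooner(self, tradeoff_params):
        b = [gumbel_scaling(M, tradeoff_params).bM for M in (10_000, 1_000_000)]
        assert b[1] < b[0]

    def test_scales_positive(self, scaling):
        assert scaling.bM > 0 and scaling.aM > 0 and scaling.nu > 0

    def test_numeric_approaches_asymptotic(self, ref_params):
        """Relative gap between the root-solved and leading-order centering
        shrinks monotonically as M grows."""
        gaps, lgaps = [], []
        for M in (10**5, 10**8, 10**12):
            num = gumbel_scaling(M, ref_params, "numeric")
            asym = gumbel_scaling(M, ref_params, "asymptotic")
            gaps.append(abs(num.bM - asym.bM) / num.bM)
            l_num = lambda_k(1, num)
            lgaps.append(abs(l_num - lambda1_asymptotic(M, ref_params, "nu")) / l_num)
        assert gaps[0] > gaps[1] > gaps[2]
        assert lgaps[0] > lgaps[1] > lgaps[2]

    def test_crude_logM_form_converges_from_below(self, ref_params):
        ratios = [
            lambda_k(1, gumbel_scaling(M, ref_params)) /
            lambda1_asymptotic(M, ref_params, "logM")
            for M in (10**5, 10**8, 10**12)
        ]
        assert ratios[0] > ratios[1] > ratios[2] > 1.0

    def test_small_M_rejected(self, ref_params):
        with pytest.raises(ValueError):
            gumbel_scaling(50, ref_params)

    def test_derivative_consistency(self, scaling, tradeoff_params):
        """a_M = -1/(M S'(b_M)) with S' from the analytic product rule."""
        eps = 1e-6 * scaling.bM
        h = survival_prefactor_h
        c = (tradeoff_params.R - 1) ** 2 / (4 * tradeoff_params.D)
        S = lambda b: 1.0 - h(b, tradeoff_params) * np.exp(-c / b)
        Sp = (S(scaling.bM + eps) - S(scaling.bM - eps)) / (2 * eps)
        assert scaling.aM == pytest.approx(-1.0 / (scaling.M * Sp), rel=1e-5)

    def test_json_roundtrip(self, scaling, tmp_path):
        path = tmp_path / "scaling.json"
        scaling.to_json(path)
        import json

        back = json.loads(path.read_text())
        assert back["bM"] == pytest.approx(scaling.bM)


class TestKthArrivalLaw:
    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_normalized(self, k):
        val, _ = quad(lambda x: kth_arrival_density(x, k), -40, 40, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_first_arrival_is_gumbel(self):
        x = np.linspace(-5, 3, 50)
        assert np.allclose(kth_arrival_density(x, 1), np.exp(x - np.exp(x)))
        mean, _ = quad(lambda u: u * kth_arrival_density(u, 1), -40, 40, limit=200)
        assert mean == pytest.approx(-np.euler_gamma, abs=1e-9)

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_mode(self, k, scaling):
        assert kth_arrival_mode(k) == pytest.approx(np.log(k))
        assert kth_arrival_mode(k, scaling) == pytest.approx(
            scaling.bM + scaling.aM * np.log(k))

    def test_sampling_matches_density(self, rng):
        k = 3
        x = sample_kth_arrival(k, 4000, rng)
        cdf = lambda v: gammainc(k, np.exp(v))  # X = log Gamma(k)
        assert kstest(x, cdf).pvalue > 0.01

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            kth_arrival_density(0.0, 0)


class TestLambdaRates:
    def test_strictly_increasing_in_rank(self, scaling):
        lam = lambda_k(np.arange(1, 30), scaling)
        assert np.all(np.diff(lam) > 0)

    def test_first_event_is_most_accurate(self, scaling):
        """Exponential single-event laws: the k=1 rate gives both the
        smallest mean and the smallest variance."""
        lam = np.asarray(lambda_k(np.arange(1, 10), scaling))
        assert np.argmin(lam) == 0
        assert np.argmin(lam**2) == 0

    def test_nu_matches_centering(self, ref_params):
        M = 10**7
        nu = nu_log_factor(M, ref_params)
        asym = gumbel_scaling(M, ref_params, "asymptotic")
        assert asym.bM == pytest.approx(
            (ref_params.R - 1) ** 2 / (6 * ref_params.D * nu))


class TestHypoexponential:
    def test_single_rate_reduces_to_exponential(self):
        z = np.linspace(0, 5, 40)
        assert np.allclose(hypoexponential_pdf(z, [2.5]), 2.5 * np.exp(-2.5 * z))

    @given(rate=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_single_rate_cdf(self, rate):
        assert hypoexponential_cdf(1.0, [rate]) == pytest.approx(
            1 - np.exp(-rate), rel=1e-12)

    @pytest.mark.parametrize("K", [1, 2, 5, 10])
    def test_quadrature_moments_match_closed_forms(self, K, scaling):
        """Mean and variance from integrating the density equal the
        closed-form sums over the per-event rates."""
        law = error_moments(K, scaling)
        hi = law.mean_error + 40 * np.sqrt(law.var_error)
        alphas = law.alphas
        norm, _ = quad(lambda z: hypoexponential_pdf(z, alphas), 0, hi, limit=400)
        mean, _ = quad(lambda z: z * hypoexponential_pdf(z, alphas), 0, hi, limit=400)
        msq, _ = quad(lambda z: z * z * hypoexponential_pdf(z, alphas), 0, hi,
                      limit=400)
        assert norm == pytest.approx(1.0, abs=1e-8)
        assert mean == pytest.approx(law.mean_error, rel=1e-6)
        assert msq - mean**2 == pytest.approx(law.var_error, rel=1e-6)

    def test_degenerate_rates_fall_back_consistently(self):
        """Near-coincident rates switch to the matrix-exponential branch,
        which must agree with the partial-fraction branch where both work."""
        z = np.linspace(0.05, 4.0, 25)
        distinct = np.array([1.0, 1.3, 2.2])
        nearly = np.array([1.0, 1.0 + 5e-6, 2.2])
        exact_equal = np.array([1.0, 1.0, 2.2])
        a = hypoexponential_pdf(z, distinct)
        b = hypoexponential_pdf(z, nearly)
        c = hypoexponential_pdf(z, exact_equal)
        assert np.allclose(b, c, rtol=1e-4)
        assert np.all(np.isfinite(a)) and np.all(np.isfinite(c))
        # CDF endpoints
        assert hypoexponential_cdf(50.0, exact_equal) == pytest.approx(1.0, abs=1e-8)

    def test_sampling_moments(self, rng):
        rates = np.array([3.0, 5.0, 9.0])
        x = sample_hypoexponential(rates, 40_000, rng)
        assert x.mean() == pytest.approx(np.sum(1 / rates), rel=0.02)
        assert x.var() == pytest.approx(np.sum(1 / rates**2), rel=0.05)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            hypoexponential_pdf(1.0, [1.0, -2.0])


class TestErrorMoments:
    def test_single_event_moments(self, scaling):
        law = error_moments(1, scaling)
        lam1 = lambda_k(1, scaling)
        assert law.mean_error == pytest.approx(lam1)
        assert law.var_error == pytest.approx(lam1**2)

    def test_mean_grows_variance_shrinks(self, scaling):
        laws = [error_moments(K, scaling) for K in range(1, 11)]
        means = [law.mean_error for law in laws]
        vars_ = [law.var_error for law in laws]
        assert np.all(np.diff(means) > 0)
        assert np.all(np.diff(vars_) < 0)

    def test_headline_trade_off(self, scaling):
        """Averaging five events: mean error up ~11%, variance down ~4x."""
        e1, e5 = error_moments(1, scaling), error_moments(5, scaling)
        assert e5.mean_error / e1.mean_error - 1 == pytest.approx(0.11, abs=0.02)
        assert e1.var_error / e5.var_error == pytest.approx(4.0, abs=0.5)

    def test_serialization(self, scaling, tmp_path):
        law = error_moments(3, scaling)
        law.to_json(tmp_path / "law.json")
        assert (tmp_path / "law.json").exists()
        assert isinstance(law, ErrorLaw)


class TestOptimalK:
    def test_mean_only_criterion_prefers_first_event(self, scaling):
        assert optimal_k(scaling, 10, "mean") == 1

    def test_variance_only_criterion_prefers_all_events(self, scaling):
        assert optimal_k(scaling, 10, "var") == 10

    def test_mse_matches_exhaustive_search(self, scaling):
        K_max = 12
        mses = [error_moments(K, scaling).mse for K in range(1, K_max + 1)]
        assert optimal_k(scaling, K_max, "mse") == int(np.argmin(mses)) + 1

    def test_unknown_criterion_rejected(self, scaling):
        with pytest.raises(ValueError):
            optimal_k(scaling, 5, "entropy")
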