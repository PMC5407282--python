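"""Core observer model: closed forms, sampling, strategies, simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from causalbind import (
    DecisionStrategy,
    LocationEstimates,
    ModelParameters,
    StimulusCondition,
    TrialLatents,
    apply_strategy,
    conditional_estimates,
    eccentricity_index,
    effective_visual_sigma,
    fused_estimate,
    likelihood_common,
    likelihood_independent,
    posterior_common,
    sample_sensory_signals,
    segregated_estimate,
    simulate_responses,
    simulate_trial,
)
from causalbind.oracles import (
    grid_fused_estimate,
    quad_likelihood_common,
    quad_likelihood_independent,
    quad_posterior_common,
)


def make_params(**overrides) -> ModelParameters:
    base = dict(
        p_common=0.3,
        mu_prior=0.5,
        sigma_prior=20.0,
        sigma_v=2.0,
        delta_sigma_v=0.4,
        delta_x_v=0.2,
        sigma_a=7.0,
        delta_x_a=-0.3,
    )
    base.update(overrides)
    return ModelParameters(**base)


@pytest.mark.parametrize(
    "location,k",
    [(-13.0, -2), (-6.5, -1), (0.0, 0), (6.5, 1), (13.0, 2)],
)
def test_eccentricity_index_maps_speakers(location, k):
    assert eccentricity_index(location) == k


def test_eccentricity_index_rejects_unknown_location():
    with pytest.raises(ValueError, match="7.7"):
        eccentricity_index(7.7)


@pytest.mark.parametrize(
    "sigma_v,delta,k,expected",
    [(2.0, 0.5, 0, 2.0), (2.0, 0.5, -2, 3.0), (2.0, -0.5, 2, 3.0)],
)
def test_effective_visual_sigma_scales_with_eccentricity(sigma_v, delta, k, expected):
    p = make_params(sigma_v=sigma_v, delta_sigma_v=delta)
    assert effective_visual_sigma(p, k) == pytest.approx(expected)


def test_parameter_validation():
    with pytest.raises(ValueError):
        make_params(p_common=1.5)
    with pytest.raises(ValueError):
        make_params(sigma_a=-1.0)
    with pytest.raises(ValueError):
        StimulusCondition()  # no modality at all


def test_sample_sensory_signals_moments(rng):
    """Sampled measurements follow the biased, eccentricity-scaled normals."""
    p = make_params(sigma_v=2.0, delta_sigma_v=0.5, delta_x_v=-1.0, delta_x_a=0.0)
    cond = StimulusCondition(s_a=-13.0, s_v=13.0)  # k_v = 2 -> mean 11, sd 3
    n = 20_000
    xs_v = np.empty(n)
    xs_a = np.empty(n)
    for i in range(n):
        lat = sample_sensory_signals(p, cond, rng)
        xs_v[i], xs_a[i] = lat.x_v, lat.x_a
        assert 0.0 <= lat.xi < 1.0
    sd_v = effective_visual_sigma(p, 2)  # = 3 with delta reversed sign? no: |0.5*2| -> 3
    assert xs_v.mean() == pytest.approx(13.0 - 1.0 * 2, abs=3 * sd_v / math.sqrt(n))
    assert xs_v.std() == pytest.approx(sd_v, rel=0.05)
    assert xs_a.mean() == pytest.approx(-13.0, abs=3 * p.sigma_a / math.sqrt(n))
    assert xs_a.std() == pytest.approx(p.sigma_a, rel=0.05)


def test_sample_sensory_signals_unisensory_absent(rng):
    p = make_params()
    lat = sample_sensory_signals(p, StimulusCondition(s_a=0.0), rng)
    assert lat.x_v is None and lat.x_a is not None


def test_fused_estimate_trivial_cases():
    p = make_params(mu_prior=0.0)
    lat = TrialLatents(x_a=0.0, x_v=0.0, xi=0.5)
    assert fused_estimate(lat, p, 0) == pytest.approx(0.0)
    # flat prior, equal sensory precisions: symmetric average
    p2 = make_params(mu_prior=0.0, sigma_prior=1e9, sigma_v=7.0, delta_sigma_v=0.0, sigma_a=7.0)
    lat2 = TrialLatents(x_a=-5.0, x_v=5.0, xi=0.5)
    assert fused_estimate(lat2, p2, 1) == pytest.approx(0.0, abs=1e-9)


def test_fused_estimate_matches_grid_search(rng):
    """Closed-form MAP equals dense grid argmax of the C=1 posterior."""
    for _ in range(10):
        p = make_params(
            mu_prior=float(rng.uniform(-4, 4)),
            sigma_prior=float(rng.uniform(5, 35)),
            sigma_v=float(rng.uniform(0.5, 6)),
            sigma_a=float(rng.uniform(2, 12)),
        )
        lat = TrialLatents(
            x_a=float(rng.uniform(-20, 20)), x_v=float(rng.uniform(-20, 20)), xi=0.5
        )
        k_v = int(rng.integers(-2, 3))
        closed = fused_estimate(lat, p, k_v)
        assert closed == pytest.approx(grid_fused_estimate(lat, p, k_v, step=0.001), abs=1.5e-3)


def test_fused_estimate_requires_both_modalities():
    with pytest.raises(ValueError):
        fused_estimate(TrialLatents(x_a=1.0, x_v=None, xi=0.1), make_params(), 0)


def test_segregated_estimate_limits():
    p = make_params(mu_prior=3.0)
    assert segregated_estimate(3.0, 5.0, p) == pytest.approx(3.0)
    flat = make_params(sigma_prior=1e9)
    assert segregated_estimate(10.0, 5.0, flat) == pytest.approx(10.0, abs=1e-6)
    equal = make_params(mu_prior=0.0, sigma_prior=5.0)
    assert segregated_estimate(10.0, 5.0, equal) == pytest.approx(5.0)


def test_likelihood_common_symmetry_and_quadrature(rng):
    p = make_params(sigma_v=7.0, delta_sigma_v=0.0, sigma_a=7.0)
    a = likelihood_common(TrialLatents(x_a=3.0, x_v=-4.0, xi=0.1), p, 0)
    b = likelihood_common(TrialLatents(x_a=-4.0, x_v=3.0, xi=0.1), p, 0)
    assert a == pytest.approx(b, rel=1e-12)
    for _ in range(5):
        q = make_params(sigma_prior=float(rng.uniform(8, 30)))
        lat = TrialLatents(
            x_a=float(rng.uniform(-15, 15)), x_v=float(rng.uniform(-15, 15)), xi=0.5
        )
        assert likelihood_common(lat, q, 1) == pytest.approx(
            quad_likelihood_common(lat, q, 1), rel=1e-6
        )


def test_likelihood_common_peaks_at_prior_mean():
    """With x_a pinned at the prior mean, the marginal is maximized at x_v = mu_p."""
    p = make_params(mu_prior=2.0)
    xs = np.linspace(-20, 20, 801)
    vals = [
        likelihood_common(TrialLatents(x_a=2.0, x_v=float(x), xi=0.5), p, 0) for x in xs
    ]
    assert xs[int(np.argmax(vals))] == pytest.approx(2.0, abs=0.06)


def test_likelihood_independent_peak_and_factorization(rng):
    p = make_params(mu_prior=1.0, delta_sigma_v=0.0)
    peak = likelihood_independent(TrialLatents(x_a=1.0, x_v=1.0, xi=0.5), p, 0)
    expected = 1.0 / (
        2 * math.pi
        * math.sqrt(p.sigma_a**2 + p.sigma_prior**2)
        * math.sqrt(p.sigma_v**2 + p.sigma_prior**2)
    )
    assert peak == pytest.approx(expected, rel=1e-12)
    # independence: the visual factor is unchanged by moving x_a
    l1 = likelihood_independent(TrialLatents(x_a=0.0, x_v=5.0, xi=0.5), p, 0)
    l2 = likelihood_independent(TrialLatents(x_a=9.0, x_v=5.0, xi=0.5), p, 0)
    ratio_a = math.exp(
        -0.5 * ((0.0 - 1.0) ** 2 - (9.0 - 1.0) ** 2) / (p.sigma_a**2 + p.sigma_prior**2)
    )
    assert l1 / l2 == pytest.approx(ratio_a, rel=1e-9)
    for _ in range(5):
        lat = TrialLatents(
            x_a=float(rng.uniform(-15, 15)), x_v=float(rng.uniform(-15, 15)), xi=0.5
        )
        assert likelihood_independent(lat, p, -2) == pytest.approx(
            quad_likelihood_independent(lat, p, -2), rel=1e-6
        )


def test_posterior_common_edge_priors():
    lat = TrialLatents(x_a=-10.0, x_v=12.0, xi=0.5)
    assert posterior_common(lat, make_params(p_common=0.0), 0) == 0.0
    assert posterior_common(lat, make_params(p_common=1.0), 0) == 1.0


def test_posterior_common_matches_quadrature(rng):
    for _ in range(5):
        p = make_params(p_common=float(rng.uniform(0.1, 0.9)))
        lat = TrialLatents(
            x_a=float(rng.uniform(-15, 15)), x_v=float(rng.uniform(-15, 15)), xi=0.5
        )
        assert posterior_common(lat, p, 1) == pytest.approx(
            quad_posterior_common(lat, p, 1), abs=1e-8
        )


def test_posterior_common_no_underflow_at_huge_discrepancy():
    """Log-space evaluation survives discrepancies that underflow densities."""
    p = make_params(sigma_v=0.5, delta_sigma_v=0.0, sigma_a=0.5, p_common=0.5)
    post = posterior_common(TrialLatents(x_a=-40.0, x_v=40.0, xi=0.5), p, 0)
    assert 0.0 <= post < 1e-6


def test_posterior_common_monotone_in_p_common_and_discrepancy():
    lat = TrialLatents(x_a=-4.0, x_v=6.0, xi=0.5)
    posts = [
        posterior_common(lat, make_params(p_common=pc), 0)
        for pc in np.linspace(0.05, 0.95, 10)
    ]
    assert np.all(np.diff(posts) > 0)
    # symmetric setup: growing discrepancy lowers the common-cause posterior
    p = make_params(mu_prior=0.0, sigma_v=7.0, delta_sigma_v=0.0, sigma_a=7.0)
    posts_d = [
        posterior_common(TrialLatents(x_a=-d, x_v=d, xi=0.5), p, 0)
        for d in np.linspace(0, 20, 15)
    ]
    assert np.all(np.diff(posts_d) < 0)


def test_apply_strategy_branches():
    est = LocationEstimates(
        s_hat_a_c1=2.0, s_hat_v_c1=2.0, s_hat_a_c2=8.0, s_hat_v_c2=-3.0, p_c1=1.0
    )
    assert apply_strategy(DecisionStrategy.MODEL_AVERAGING, est, 0.5) == (2.0, 2.0)
    est6 = LocationEstimates(2.0, 2.0, 8.0, -3.0, 0.6)
    assert apply_strategy(DecisionStrategy.MODEL_SELECTION, est6, 0.9)[0] == 2.0
    est_half = LocationEstimates(2.0, 2.0, 8.0, -3.0, 0.5)  # tie -> segregate
    assert apply_strategy(DecisionStrategy.MODEL_SELECTION, est_half, 0.9)[0] == 8.0
    est0 = LocationEstimates(2.0, 2.0, 8.0, -3.0, 0.0)
    for xi in (0.0, 0.3, 0.999):
        assert apply_strategy(DecisionStrategy.PROBABILITY_MATCHING, est0, xi) == (8.0, -3.0)
    est1 = LocationEstimates(2.0, 2.0, 8.0, -3.0, 1.0)
    assert apply_strategy(DecisionStrategy.PROBABILITY_MATCHING, est1, 0.0) == (2.0, 2.0)


@settings(derandomize=True, max_examples=60)
@given(
    x_a=st.floats(-30, 30),
    x_v=st.floats(-30, 30),
    pc=st.floats(0.01, 0.99),
    xi=st.floats(0, 0.999),
)
def test_final_estimates_bracketed_by_conditionals(x_a, x_v, pc, xi):
    """Every strategy's output lies in [min, max] of the two conditional
    estimates for its modality (convex combination or branch pick)."""
    p = make_params(p_common=pc)
    lat = TrialLatents(x_a=x_a, x_v=x_v, xi=xi)
    est = conditional_estimates(lat, p, 1)
    assert est.s_hat_a_c1 == est.s_hat_v_c1  # single fused source
    assert 0.0 <= est.p_c1 <= 1.0
    for strat in DecisionStrategy:
        fa, fv = apply_strategy(strat, est, xi)
        assert min(est.s_hat_a_c1, est.s_hat_a_c2) - 1e-12 <= fa
        assert fa <= max(est.s_hat_a_c1, est.s_hat_a_c2) + 1e-12
        assert min(est.s_hat_v_c1, est.s_hat_v_c2) - 1e-12 <= fv
        assert fv <= max(est.s_hat_v_c1, est.s_hat_v_c2) + 1e-12


def test_simulate_trial_unisensory_low_noise(rng):
    p = make_params(sigma_a=1e-6, mu_prior=6.5, delta_x_a=0.0, sigma_prior=30.0)
    resp_a, resp_v = simulate_trial(p, DecisionStrategy.MODEL_AVERAGING,
                                    StimulusCondition(s_a=6.5), rng)
    assert resp_v is None
    assert resp_a == pytest.approx(6.5, abs=1e-3)


def test_zero_binding_matches_unisensory_distribution(rng):
    """With p_common = 0 the auditory responses on bisensory trials are
    indistinguishable from unisensory auditory responses at the same s_a."""
    p = make_params(p_common=0.0)
    n = 10_000
    bi_a, _ = simulate_responses(
        p, DecisionStrategy.MODEL_AVERAGING, StimulusCondition(s_a=6.5, s_v=-13.0), n, rng
    )
    uni_a, _ = simulate_responses(
        p, DecisionStrategy.MODEL_AVERAGING, StimulusCondition(s_a=6.5), n, rng
    )
    assert ks_2samp(bi_a, uni_a).pvalue > 0.01


def test_fusion_reduces_auditory_variance(rng):
    """Congruent bisensory stimulation with certain integration yields less
    variable auditory responses than certain segregation (same noise)."""
    cond = StimulusCondition(s_a=0.0, s_v=0.0)
    n = 10_000
    z_a, z_v, xi = rng.standard_normal(n), rng.standard_normal(n), rng.random(n)
    kw = dict(z_a=z_a, z_v=z_v, xi=xi)
    fused_a, _ = simulate_responses(
        make_params(p_common=1.0), DecisionStrategy.MODEL_AVERAGING, cond, n, **kw
    )
    seg_a, _ = simulate_responses(
        make_params(p_common=0.0), DecisionStrategy.MODEL_AVERAGING, cond, n, **kw
    )
    assert fused_a.var() < seg_a.var()


@pytest.mark.parametrize("strategy", list(DecisionStrategy))
def test_mirror_symmetry_of_responses(strategy, rng):
    """With no eccentricity biases and a centered prior, negating the
    stimulus locations negates the responses under mirrored noise."""
    p = make_params(mu_prior=0.0, delta_x_v=0.0, delta_x_a=0.0, delta_sigma_v=0.0)
    n = 4000
    z_a, z_v, xi = rng.standard_normal(n), rng.standard_normal(n), rng.random(n)
    ra, rv = simulate_responses(
        p, strategy, StimulusCondition(s_a=13.0, s_v=-6.5), n, z_a=z_a, z_v=z_v, xi=xi
    )
    ra_m, rv_m = simulate_responses(
        p, strategy, StimulusCondition(s_a=-13.0, s_v=6.5), n,
        z_a=-z_a, z_v=-z_v, xi=xi,
    )
    np.testing.assert_allclose(ra_m, -ra, atol=1e-10)
    np.testing.assert_allclose(rv_m, -rv, atol=1e-10)


def test_vectorized_simulation_matches_scalar_path(params):
    """simulate_responses with unit noise equals the scalar per-trial chain."""
    cond = StimulusCondition(s_a=-6.5, s_v=13.0)
    z_a = np.array([0.3, -1.2, 2.0])
    z_v = np.array([-0.5, 0.9, 0.1])
    xi = np.array([0.2, 0.8, 0.5])
    for strategy in DecisionStrategy:
        ra, rv = simulate_responses(params, strategy, cond, 3, z_a=z_a, z_v=z_v, xi=xi)
        for i in range(3):
            sv = effective_visual_sigma(params, cond.k_v)
            lat = TrialLatents(
                x_a=cond.s_a + params.delta_x_a * cond.k_a + params.sigma_a * z_a[i],
                x_v=cond.s_v + params.delta_x_v * cond.k_v + sv * z_v[i],
                xi=xi[i],
            )
            est = conditional_estimates(lat, params, cond.k_v)
            fa, fv = apply_strategy(strategy, est, xi[i])
            assert ra[i] == pytest.approx(fa, rel=1e-12)
            assert rv[i] == pytest.approx(fv, rel=1e-12)
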