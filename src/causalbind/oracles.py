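"""Brute-force numerical oracles for the closed-form model equations.

These evaluate the posterior and marginal-likelihood integrals by dense
grid search and trapezoidal quadrature directly from the Gaussian
definitions, sharing no code with the closed forms in
:mod:`causalbind.model`. They exist to cross-check the analytic
implementation (unit tests and the ``oracle-check`` CLI command); they
are far too slow to fit with.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .model import ModelParameters, TrialLatents, effective_visual_sigma

__all__ = [
    "grid_fused_estimate",
    "grid_segregated_estimate",
    "quad_likelihood_common",
    "quad_likelihood_independent",
    "quad_posterior_common",
    "oracle_report",
]


def grid_fused_estimate(
    latents: TrialLatents,
    params: ModelParameters,
    k_v: int,
    lo: float = -60.0,
    hi: float = 60.0,
    step: float = 0.001,
) -> float:
    """Argmax over a dense grid of the single-source posterior density."""
    s = np.arange(lo, hi + step, step)
    sv = effective_visual_sigma(params, k_v)
    logpost = (
        norm.logpdf(latents.x_a, s, params.sigma_a)
        + norm.logpdf(latents.x_v, s, sv)
        + norm.logpdf(s, params.mu_prior, params.sigma_prior)
    )
    return float(s[np.argmax(logpost)])


def grid_segregated_estimate(
    x: float,
    sigma: float,
    params: ModelParameters,
    lo: float = -60.0,
    hi: float = 60.0,
    step: float = 0.001,
) -> float:
    """Argmax over a dense grid of the single-modality posterior density."""
    s = np.arange(lo, hi + step, step)
    logpost = norm.logpdf(x, s, sigma) + norm.logpdf(
        s, params.mu_prior, params.sigma_prior
    )
    return float(s[np.argmax(logpost)])


def quad_likelihood_common(
    latents: TrialLatents,
    params: ModelParameters,
    k_v: int,
    lo: float = -200.0,
    hi: float = 200.0,
    step: float = 0.01,
) -> float:
    """Trapezoidal quadrature of the common-cause marginal likelihood."""
    s = np.arange(lo, hi + step, step)
    sv = effective_visual_sigma(params, k_v)
    integrand = (
        norm.pdf(latents.x_a, s, params.sigma_a)
        * norm.pdf(latents.x_v, s, sv)
        * norm.pdf(s, params.mu_prior, params.sigma_prior)
    )
    return float(np.trapezoid(integrand, s))


def quad_likelihood_independent(
    latents: TrialLatents,
    params: ModelParameters,
    k_v: int,
    lo: float = -200.0,
    hi: float = 200.0,
    step: float = 0.01,
) -> float:
    """Product of two 1-D quadratures for the independent-cause likelihood."""
    s = np.arange(lo, hi + step, step)
    sv = effective_visual_sigma(params, k_v)
    prior = norm.pdf(s, params.mu_prior, params.sigma_prior)
    la = np.trapezoid(norm.pdf(latents.x_a, s, params.sigma_a) * prior, s)
    lv = np.trapezoid(norm.pdf(latents.x_v, s, sv) * prior, s)
    return float(la * lv)


def quad_posterior_common(
    latents: TrialLatents, params: ModelParameters, k_v: int, **kw
) -> float:
    """Common-cause posterior assembled from the quadrature likelihoods."""
    l1 = quad_likelihood_common(latents, params, k_v, **kw)
    l2 = quad_likelihood_independent(latents, params, k_v, **kw)
    pc = params.p_common
    denom = pc * l1 + (1.0 - pc) * l2
    if denom == 0.0:
        raise FloatingPointError("both likelihoods underflowed in the oracle")
    return pc * l1 / denom


def _random_setting(rng: np.random.Generator):
    params = ModelParameters(
        p_common=float(rng.uniform(0.05, 0.95)),
        mu_prior=float(rng.uniform(-5, 5)),
        sigma_prior=float(rng.uniform(5, 40)),
        sigma_v=float(rng.uniform(0.5, 8)),
        delta_sigma_v=float(rng.uniform(0, 2)),
        delta_x_v=float(rng.uniform(-1, 1)),
        sigma_a=float(rng.uniform(2, 15)),
        delta_x_a=float(rng.uniform(-1, 1)),
    )
    latents = TrialLatents(
        x_a=float(rng.uniform(-25, 25)), x_v=float(rng.uniform(-25, 25)), xi=0.5
    )
    k_v = int(rng.integers(-2, 3))
    return params, latents, k_v


def oracle_report(n_sets: int = 100, seed: int = 0, fast: bool = False) -> dict:
    """Compare closed forms with the oracles on randomized settings.

    Returns the maximum errors across ``n_sets`` random parameter/latent
    draws: relative errors for the two marginal likelihoods, absolute
    error for the posterior, and absolute error (degrees) for the MAP
    estimates against grid search. ``fast`` coarsens the grids ~10x.
    """
    from . import model

    rng = np.random.default_rng(seed)
    grid_kw = {"step": 0.01} if fast else {}
    quad_kw = {"step": 0.05} if fast else {}
    report = {
        "n_sets": n_sets,
        "max_rel_err_likelihood_common": 0.0,
        "max_rel_err_likelihood_independent": 0.0,
        "max_abs_err_posterior_common": 0.0,
        "max_abs_err_fused_estimate": 0.0,
        "max_abs_err_segregated_estimate": 0.0,
    }
    for _ in range(n_sets):
        params, latents, k_v = _random_setting(rng)
        l1c = model.likelihood_common(latents, params, k_v)
        l1q = quad_likelihood_common(latents, params, k_v, **quad_kw)
        l2c = model.likelihood_independent(latents, params, k_v)
        l2q = quad_likelihood_independent(latents, params, k_v, **quad_kw)
        report["max_rel_err_likelihood_common"] = max(
            report["max_rel_err_likelihood_common"], abs(l1c - l1q) / l1q
        )
        report["max_rel_err_likelihood_independent"] = max(
            report["max_rel_err_likelihood_independent"], abs(l2c - l2q) / l2q
        )
        report["max_abs_err_posterior_common"] = max(
            report["max_abs_err_posterior_common"],
            abs(
                model.posterior_common(latents, params, k_v)
                - quad_posterior_common(latents, params, k_v, **quad_kw)
            ),
        )
        report["max_abs_err_fused_estimate"] = max(
            report["max_abs_err_fused_estimate"],
            abs(
                model.fused_estimate(latents, params, k_v)
                - grid_fused_estimate(latents, params, k_v, **grid_kw)
            ),
        )
        report["max_abs_err_segregated_estimate"] = max(
            report["max_abs_err_segregated_estimate"],
            abs(
                model.segregated_estimate(latents.x_a, params.sigma_a, params)
                - grid_segregated_estimate(latents.x_a, params.sigma_a, params, **grid_kw)
            ),
        )
    return report
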