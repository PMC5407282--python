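"""Generative Bayesian causal-inference observer for audiovisual localization.

An observer receives noisy internal measurements of auditory and visual
source azimuth, infers whether the two signals share a common cause, and
reports a location estimate for each modality. The model has eight free
parameters: the binding tendency ``p_common`` (prior probability of a
common cause), a Gaussian spatial prior (``mu_prior``, ``sigma_prior``),
and five sensory-likelihood parameters (``sigma_v``, ``delta_sigma_v``,
``delta_x_v``, ``sigma_a``, ``delta_x_a``). Eccentricity-dependent bias
and visual-noise terms are indexed by the integer position code K of the
five speaker locations.

All angles are azimuth in degrees, positive rightward, no wrap-around.
Densities are evaluated in log space internally to avoid underflow at
large audiovisual discrepancies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "LOCATIONS",
    "ModelParameters",
    "DecisionStrategy",
    "StimulusCondition",
    "TrialLatents",
    "LocationEstimates",
    "eccentricity_index",
    "effective_visual_sigma",
    "sample_sensory_signals",
    "fused_estimate",
    "segregated_estimate",
    "likelihood_common",
    "likelihood_independent",
    "log_likelihood_common",
    "log_likelihood_independent",
    "posterior_common",
    "conditional_estimates",
    "apply_strategy",
    "simulate_trial",
    "simulate_responses",
    "PARAM_NAMES",
]

#: The five speaker azimuths used in the study design (degrees).
LOCATIONS = (-13.0, -6.5, 0.0, 6.5, 13.0)

#: Canonical parameter ordering for array round-trips (fitting, I/O).
PARAM_NAMES = (
    "p_common",
    "mu_prior",
    "sigma_prior",
    "sigma_v",
    "delta_sigma_v",
    "delta_x_v",
    "sigma_a",
    "delta_x_a",
)

_LOG_2PI = math.log(2.0 * math.pi)


def eccentricity_index(location: float) -> int:
    """Map a speaker azimuth to its integer eccentricity code K.

    The five speakers sit 6.5 degrees apart, so K = location / 6.5 with
    K in {-2, -1, 0, 1, 2}.  Any other azimuth is rejected.
    """
    for loc in LOCATIONS:
        if math.isclose(location, loc, abs_tol=1e-9):
            return round(loc / 6.5)
    raise ValueError(
        f"location {location!r} is not one of the speaker azimuths {LOCATIONS}"
    )


@dataclass(frozen=True)
class ModelParameters:
    """The eight free parameters of one observer in one session.

    Attributes
    ----------
    p_common : float
        Binding tendency: prior probability that simultaneous auditory and
        visual signals share a common cause. In [0, 1].
    mu_prior, sigma_prior : float
        Mean and standard deviation (degrees) of the Gaussian spatial prior.
    sigma_v : float
        Visual likelihood s.d. at the center position (degrees).
    delta_sigma_v : float
        Visual noise scaling per eccentricity step: effective visual s.d.
        is ``sigma_v + |delta_sigma_v * K|``.
    delta_x_v, delta_x_a : float
        Eccentricity-scaled bias of the visual / auditory measurement mean
        (degrees per K step); negative values pull toward center.
    sigma_a : float
        Auditory likelihood s.d. (degrees).
    """

    p_common: float
    mu_prior: float
    sigma_prior: float
    sigma_v: float
    delta_sigma_v: float
    delta_x_v: float
    sigma_a: float
    delta_x_a: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_common <= 1.0:
            raise ValueError(f"p_common must be in [0, 1], got {self.p_common}")
        for name in ("sigma_prior", "sigma_v", "sigma_a"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ModelParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, x))))

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


class DecisionStrategy(str, Enum):
    """Read-out rule mapping the causal posterior to reported locations."""

    MODEL_AVERAGING = "model_averaging"
    MODEL_SELECTION = "model_selection"
    PROBABILITY_MATCHING = "probability_matching"


@dataclass(frozen=True)
class StimulusCondition:
    """One experimental condition: auditory and/or visual source azimuth.

    Either location may be absent (``None``) for a unisensory condition;
    present locations must be one of the five speaker azimuths.
    """

    s_a: Optional[float] = None
    s_v: Optional[float] = None

    def __post_init__(self) -> None:
        if self.s_a is None and self.s_v is None:
            raise ValueError("a condition needs at least one modality")
        # normalize to the canonical float and validate membership
        if self.s_a is not None:
            object.__setattr__(self, "s_a", LOCATIONS[eccentricity_index(self.s_a) + 2])
        if self.s_v is not None:
            object.__setattr__(self, "s_v", LOCATIONS[eccentricity_index(self.s_v) + 2])

    @property
    def k_a(self) -> Optional[int]:
        return None if self.s_a is None else eccentricity_index(self.s_a)

    @property
    def k_v(self) -> Optional[int]:
        return None if self.s_v is None else eccentricity_index(self.s_v)

    @property
    def is_bisensory(self) -> bool:
        return self.s_a is not None and self.s_v is not None

    @property
    def modalities(self) -> tuple:
        out = []
        if self.s_a is not None:
            out.append("auditory")
        if self.s_v is not None:
            out.append("visual")
        return tuple(out)


@dataclass(frozen=True)
class TrialLatents:
    """Internal measurements on one trial.

    ``xi`` is the uniform draw consumed only by the probability-matching
    read-out; it is always sampled so that strategies can be compared on
    identical noise.
    """

    x_a: Optional[float]
    x_v: Optional[float]
    xi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.xi < 1.0:
            raise ValueError(f"xi must be in [0, 1), got {self.xi}")


@dataclass(frozen=True)
class LocationEstimates:
    """Conditional location estimates and causal posterior for one trial."""

    s_hat_a_c1: float
    s_hat_v_c1: float
    s_hat_a_c2: float
    s_hat_v_c2: float
    p_c1: float


def effective_visual_sigma(params: ModelParameters, k_v: int) -> float:
    """Visual likelihood s.d. at eccentricity K: sigma_v + |delta_sigma_v * K|."""
    return params.sigma_v + abs(params.delta_sigma_v * k_v)


def sample_sensory_signals(
    params: ModelParameters, cond: StimulusCondition, rng: np.random.Generator
) -> TrialLatents:
    """Draw internal measurements for one trial of ``cond``.

    x_V ~ N(s_V + delta_x_v*K_V, sigma_v + |delta_sigma_v*K_V|),
    x_A ~ N(s_A + delta_x_a*K_A, sigma_a); absent modalities yield None.
    The bias and noise-scaling terms act only here, on the generative side;
    the observer's inference treats the measurements as unbiased.
    """
    x_a = x_v = None
    if cond.s_a is not None:
        x_a = rng.normal(cond.s_a + params.delta_x_a * cond.k_a, params.sigma_a)
    if cond.s_v is not None:
        x_v = rng.normal(
            cond.s_v + params.delta_x_v * cond.k_v,
            effective_visual_sigma(params, cond.k_v),
        )
    return TrialLatents(x_a=x_a, x_v=x_v, xi=rng.random())


def fused_estimate(latents: TrialLatents, params: ModelParameters, k_v: int) -> float:
    """MAP location under the common-cause hypothesis (C=1).

    Precision-weighted average of both measurements and the spatial prior.
    """
    if latents.x_a is None or latents.x_v is None:
        raise ValueError("fused estimate requires both modalities")
    sv = effective_visual_sigma(params, k_v)
    wv, wa = sv**-2, params.sigma_a**-2
    wp = params.sigma_prior**-2
    return (latents.x_v * wv + latents.x_a * wa + params.mu_prior * wp) / (wv + wa + wp)


def segregated_estimate(x: float, sigma: float, params: ModelParameters) -> float:
    """MAP location under independent causes (C=2) for one modality.

    The measurement shrunk toward the spatial prior; also the unisensory
    estimate.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    w, wp = sigma**-2, params.sigma_prior**-2
    return (x * w + params.mu_prior * wp) / (w + wp)


def log_likelihood_common(
    latents: TrialLatents, params: ModelParameters, k_v: int
) -> float:
    """log p(x_A, x_V | C=1): the single-source marginal likelihood.

    Closed form of the integral of the two Gaussian likelihoods against
    the Gaussian spatial prior.
    """
    if latents.x_a is None or latents.x_v is None:
        raise ValueError("common-cause likelihood requires both modalities")
    sv2 = effective_visual_sigma(params, k_v) ** 2
    sa2 = params.sigma_a**2
    sp2 = params.sigma_prior**2
    z = sv2 * sa2 + sv2 * sp2 + sa2 * sp2
    q = (
        (latents.x_v - latents.x_a) ** 2 * sp2
        + (latents.x_v - params.mu_prior) ** 2 * sa2
        + (latents.x_a - params.mu_prior) ** 2 * sv2
    )
    return -_LOG_2PI - 0.5 * math.log(z) - 0.5 * q / z


def log_likelihood_independent(
    latents: TrialLatents, params: ModelParameters, k_v: int
) -> float:
    """log p(x_A, x_V | C=2): product of two independent-source marginals."""
    if latents.x_a is None or latents.x_v is None:
        raise ValueError("independent-cause likelihood requires both modalities")
    sv2 = effective_visual_sigma(params, k_v) ** 2
    sa2 = params.sigma_a**2
    sp2 = params.sigma_prior**2
    va = sa2 + sp2
    vv = sv2 + sp2
    return (
        -_LOG_2PI
        - 0.5 * (math.log(va) + math.log(vv))
        - 0.5 * (latents.x_a - params.mu_prior) ** 2 / va
        - 0.5 * (latents.x_v - params.mu_prior) ** 2 / vv
    )


def likelihood_common(latents: TrialLatents, params: ModelParameters, k_v: int) -> float:
    return math.exp(log_likelihood_common(latents, params, k_v))


def likelihood_independent(
    latents: TrialLatents, params: ModelParameters, k_v: int
) -> float:
    return math.exp(log_likelihood_independent(latents, params, k_v))


def posterior_common(
    latents: TrialLatents, params: ModelParameters, k_v: int
) -> float:
    """p(C=1 | x_A, x_V): posterior probability of a common cause.

    Computed on the log-odds scale so extreme discrepancies cannot
    underflow to 0/0.
    """
    pc = params.p_common
    if pc == 0.0:
        return 0.0
    if pc == 1.0:
        return 1.0
    log_odds = (
        math.log(pc)
        - math.log1p(-pc)
        + log_likelihood_common(latents, params, k_v)
        - log_likelihood_independent(latents, params, k_v)
    )
    return float(expit(log_odds))


def conditional_estimates(
    latents: TrialLatents, params: ModelParameters, k_v: int
) -> LocationEstimates:
    """All conditional estimates plus the causal posterior for one trial."""
    sv = effective_visual_sigma(params, k_v)
    fused = fused_estimate(latents, params, k_v)
    return LocationEstimates(
        s_hat_a_c1=fused,
        s_hat_v_c1=fused,
        s_hat_a_c2=segregated_estimate(latents.x_a, params.sigma_a, params),
        s_hat_v_c2=segregated_estimate(latents.x_v, sv, params),
        p_c1=posterior_common(latents, params, k_v),
    )


def apply_strategy(
    strategy: DecisionStrategy, est: LocationEstimates, xi: float
) -> tuple:
    """Map conditional estimates to final reported (auditory, visual) locations.

    Model selection takes the common-cause estimates iff p(C=1|x) > .5
    (ties go to segregation); model averaging mixes the two by the
    posterior; probability matching takes the common-cause branch iff
    p(C=1|x) > xi, with xi uniform on [0, 1) so the comparison is strict
    and p(C=1|x)=1 always integrates.
    """
    p = est.p_c1
    if strategy is DecisionStrategy.MODEL_AVERAGING:
        return (
            p * est.s_hat_a_c1 + (1.0 - p) * est.s_hat_a_c2,
            p * est.s_hat_v_c1 + (1.0 - p) * est.s_hat_v_c2,
        )
    if strategy is DecisionStrategy.MODEL_SELECTION:
        take_c1 = p > 0.5
    elif strategy is DecisionStrategy.PROBABILITY_MATCHING:
        take_c1 = p > xi
    else:  # pragma: no cover
        raise ValueError(f"unknown strategy {strategy!r}")
    if take_c1:
        return est.s_hat_a_c1, est.s_hat_v_c1
    return est.s_hat_a_c2, est.s_hat_v_c2


def simulate_trial(
    params: ModelParameters,
    strategy: DecisionStrategy,
    cond: StimulusCondition,
    rng: np.random.Generator,
) -> tuple:
    """One simulated trial: returns (response_a, response_v), None if absent.

    Bisensory trials run the full causal-inference chain; unisensory
    trials report the segregated estimate of the single sampled
    measurement. No motor noise is added: all response variability comes
    from sensory sampling.
    """
    latents = sample_sensory_signals(params, cond, rng)
    if cond.is_bisensory:
        est = conditional_estimates(latents, params, cond.k_v)
        return apply_strategy(strategy, est, latents.xi)
    if cond.s_a is not None:
        return segregated_estimate(latents.x_a, params.sigma_a, params), None
    sv = effective_visual_sigma(params, cond.k_v)
    return None, segregated_estimate(latents.x_v, sv, params)


def simulate_responses(
    params: ModelParameters,
    strategy: DecisionStrategy,
    cond: StimulusCondition,
    n: int,
    rng: Optional[np.random.Generator] = None,
    *,
    z_a: Optional[np.ndarray] = None,
    z_v: Optional[np.ndarray] = None,
    xi: Optional[np.ndarray] = None,
) -> tuple:
    """Vectorized simulation of ``n`` trials of one condition.

    Returns ``(responses_a, responses_v)`` arrays (``None`` for an absent
    modality). Standard-normal noise ``z_a``/``z_v`` and uniform ``xi``
    may be supplied explicitly; the fitting objective uses this to hold
    the random draws fixed across parameter evaluations (common random
    numbers), making the likelihood a deterministic function of the
    parameters.
    """
    if rng is None and (z_a is None and z_v is None):
        raise ValueError("either rng or pre-drawn noise is required")

    resp_a = resp_v = None
    x_a = x_v = None
    if cond.s_a is not None:
        if z_a is None:
            z_a = rng.standard_normal(n)
        x_a = cond.s_a + params.delta_x_a * cond.k_a + params.sigma_a * z_a
    if cond.s_v is not None:
        if z_v is None:
            z_v = rng.standard_normal(n)
        sv = effective_visual_sigma(params, cond.k_v)
        x_v = cond.s_v + params.delta_x_v * cond.k_v + sv * z_v

    wp = params.sigma_prior**-2
    mu_wp = params.mu_prior * wp

    if not cond.is_bisensory:
        if x_a is not None:
            wa = params.sigma_a**-2
            resp_a = (x_a * wa + mu_wp) / (wa + wp)
        else:
            wv = sv**-2
            resp_v = (x_v * wv + mu_wp) / (wv + wp)
        return resp_a, resp_v

    wa = params.sigma_a**-2
    wv = sv**-2
    s_c1 = (x_v * wv + x_a * wa + mu_wp) / (wv + wa + wp)
    s_a_c2 = (x_a * wa + mu_wp) / (wa + wp)
    s_v_c2 = (x_v * wv + mu_wp) / (wv + wp)

    pc = params.p_common
    if pc == 0.0:
        post = np.zeros_like(x_a)
    elif pc == 1.0:
        post = np.ones_like(x_a)
    else:
        sv2, sa2, sp2 = sv**2, params.sigma_a**2, params.sigma_prior**2
        z_norm = sv2 * sa2 + sv2 * sp2 + sa2 * sp2
        log_l1 = (
            -_LOG_2PI
            - 0.5 * math.log(z_norm)
            - 0.5
            * (
                (x_v - x_a) ** 2 * sp2
                + (x_v - params.mu_prior) ** 2 * sa2
                + (x_a - params.mu_prior) ** 2 * sv2
            )
            / z_norm
        )
        va, vv = sa2 + sp2, sv2 + sp2
        log_l2 = (
            -_LOG_2PI
            - 0.5 * (math.log(va) + math.log(vv))
            - 0.5 * (x_a - params.mu_prior) ** 2 / va
            - 0.5 * (x_v - params.mu_prior) ** 2 / vv
        )
        post = expit(math.log(pc) - math.log1p(-pc) + log_l1 - log_l2)

    if strategy is DecisionStrategy.MODEL_AVERAGING:
        resp_a = post * s_c1 + (1.0 - post) * s_a_c2
        resp_v = post * s_c1 + (1.0 - post) * s_v_c2
    else:
        if strategy is DecisionStrategy.MODEL_SELECTION:
            take_c1 = post > 0.5
        else:
            if xi is None:
                xi = rng.random(n)
            take_c1 = post > xi
        resp_a = np.where(take_c1, s_c1, s_a_c2)
        resp_v = np.where(take_c1, s_c1, s_v_c2)
    return resp_a, resp_v
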