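"""Simulation-based maximum-likelihood fitting of the observer model.

The likelihood of a parameter vector is built by simulation: for each of
the stimulus conditions, many trials are simulated, responses are binned
into a 1-degree histogram over [-45, 45] degrees, a small floor mass is
added to every bin before renormalizing (so no observed response scores
-inf), and each observed response contributes the log-mass of its bin.
The random draws behind the simulation are held fixed across objective
evaluations within a fit (common random numbers), which makes the
objective a deterministic function of the parameters and lets a bounded
Nelder-Mead simplex converge.

Bounds are enforced by a sinusoidal reparameterization of the simplex
search space, the same mechanism as MATLAB's ``fminsearchbnd``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.stats import pearsonr

from .model import (
    PARAM_NAMES,
    DecisionStrategy,
    ModelParameters,
    StimulusCondition,
    simulate_responses,
)
from .rng import substream

__all__ = [
    "TrialRecord",
    "ResponseDistribution",
    "FitConfig",
    "FitResult",
    "DEFAULT_BOUNDS",
    "default_bins",
    "r2_bins",
    "predict_response_distribution",
    "draw_common_noise",
    "negative_log_likelihood",
    "minimize_bounded_simplex",
    "fit_strategy",
    "fit_subject",
    "goodness_of_fit",
]

#: Parameter bounds for the bounded simplex search, in PARAM_NAMES order.
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "p_common": (0.0, 1.0),
    "mu_prior": (-20.0, 20.0),
    "sigma_prior": (0.1, 45.0),
    "sigma_v": (0.1, 45.0),
    "delta_sigma_v": (0.0, 10.0),
    "delta_x_v": (-5.0, 5.0),
    "sigma_a": (0.1, 45.0),
    "delta_x_a": (-5.0, 5.0),
}

#: Mass added to every histogram bin before renormalization.
FLOOR_MASS = 1e-5


def default_bins() -> np.ndarray:
    """1-degree bin edges covering the response range [-45, 45] degrees."""
    return np.arange(-45.0, 46.0, 1.0)


def r2_bins() -> np.ndarray:
    """5-degree bin edges used for the goodness-of-fit statistic.

    Coarser than the likelihood bins on purpose: with 15 trials per
    condition the observed frequencies of 90 one-degree bins are mostly
    sampling noise, which would cap R-squared well below 1 even at the
    generating parameters; 5-degree bins make R-squared a stable summary.
    """
    return np.arange(-45.0, 46.0, 5.0)


@dataclass(frozen=True)
class TrialRecord:
    """One observed trial: condition plus the recorded response(s)."""

    subject_id: str
    session: str  # "pre" | "post"
    condition: StimulusCondition
    response_a: Optional[float] = None
    response_v: Optional[float] = None

    def __post_init__(self) -> None:
        if self.session not in ("pre", "post"):
            raise ValueError(f"session must be 'pre' or 'post', got {self.session!r}")
        if (self.response_a is None) != (self.condition.s_a is None):
            raise ValueError("auditory response must be present iff s_a is present")
        if (self.response_v is None) != (self.condition.s_v is None):
            raise ValueError("visual response must be present iff s_v is present")
        for r in (self.response_a, self.response_v):
            if r is not None and not math.isfinite(r):
                raise ValueError("responses must be finite")


@dataclass(frozen=True)
class ResponseDistribution:
    """Predicted binned response probabilities for one condition/modality."""

    condition: StimulusCondition
    modality: str  # "auditory" | "visual"
    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        if not abs(self.probabilities.sum() - 1.0) < 1e-12:
            raise ValueError("probabilities must sum to 1")
        if np.any(self.probabilities <= 0):
            raise ValueError("probabilities must be strictly positive (floored)")


def _histogram_probs(responses: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Floor-smoothed, normalized histogram of simulated responses."""
    counts, _ = np.histogram(np.clip(responses, bin_edges[0], bin_edges[-1]), bin_edges)
    nbins = len(bin_edges) - 1
    p = counts / responses.size + FLOOR_MASS
    return p / (1.0 + nbins * FLOOR_MASS)


def predict_response_distribution(
    params: ModelParameters,
    strategy: DecisionStrategy,
    cond: StimulusCondition,
    n_sim: int,
    bins: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    *,
    noise: Optional[dict] = None,
) -> Dict[str, ResponseDistribution]:
    """Simulated response distribution of one condition, per modality.

    Returns a dict keyed by ``"auditory"`` / ``"visual"`` for the
    modalities present in the condition.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    bins = default_bins() if bins is None else np.asarray(bins, dtype=float)
    kwargs = {} if noise is None else noise
    resp_a, resp_v = simulate_responses(params, strategy, cond, n_sim, rng, **kwargs)
    out = {}
    if resp_a is not None:
        out["auditory"] = ResponseDistribution(cond, "auditory", bins, _histogram_probs(resp_a, bins))
    if resp_v is not None:
        out["visual"] = ResponseDistribution(cond, "visual", bins, _histogram_probs(resp_v, bins))
    return out


def _condition_key(cond: StimulusCondition):
    return (
        cond.s_a if cond.s_a is not None else -99.0,
        cond.s_v if cond.s_v is not None else -99.0,
    )


def draw_common_noise(
    conditions: Sequence[StimulusCondition], n_sim: int, seed: int
) -> Dict[StimulusCondition, dict]:
    """Pre-draw the simulation noise for each condition, keyed by condition.

    The same draws are reused for every objective evaluation within one
    fit, so the simulated-likelihood surface is deterministic.
    """
    noise = {}
    for cond in sorted(set(conditions), key=_condition_key):
        rng = substream(seed, "noise", f"{cond.s_a}|{cond.s_v}")
        noise[cond] = {
            "z_a": rng.standard_normal(n_sim) if cond.s_a is not None else None,
            "z_v": rng.standard_normal(n_sim) if cond.s_v is not None else None,
            "xi": rng.random(n_sim),
        }
    return noise


def _observed_bin_counts(
    trials: Sequence[TrialRecord], bins: np.ndarray
) -> Tuple[Dict[StimulusCondition, dict], int]:
    """Per-condition, per-modality bin counts of the observed responses.

    Responses outside the bin range are clipped into the edge bins; the
    clip count is returned so callers can warn.
    """
    nbins = len(bins) - 1
    by_cond: Dict[StimulusCondition, dict] = {}
    n_clipped = 0
    for t in trials:
        entry = by_cond.setdefault(
            t.condition,
            {
                "auditory": np.zeros(nbins) if t.condition.s_a is not None else None,
                "visual": np.zeros(nbins) if t.condition.s_v is not None else None,
            },
        )
        for modality, resp in (("auditory", t.response_a), ("visual", t.response_v)):
            if resp is None:
                continue
            if resp < bins[0] or resp > bins[-1]:
                n_clipped += 1
            idx = min(max(int(np.searchsorted(bins, resp, side="right")) - 1, 0), nbins - 1)
            entry[modality][idx] += 1
    return by_cond, n_clipped


def negative_log_likelihood(
    params: ModelParameters,
    strategy: DecisionStrategy,
    trials: Sequence[TrialRecord],
    n_sim: int = 10_000,
    bins: Optional[np.ndarray] = None,
    seed: int = 0,
    *,
    noise: Optional[Dict[StimulusCondition, dict]] = None,
    _counts: Optional[Dict[StimulusCondition, dict]] = None,
) -> float:
    """Negative log-likelihood of ``params`` under ``strategy`` for ``trials``.

    For each condition present in the data a simulated response histogram
    is built once; each observed response contributes minus the log-mass
    of its bin (both modalities on bisensory trials). Deterministic given
    ``seed``.
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    bins = default_bins() if bins is None else np.asarray(bins, dtype=float)
    if _counts is None:
        _counts, n_clipped = _observed_bin_counts(trials, bins)
        if n_clipped:
            warnings.warn(
                f"{n_clipped} response(s) outside the bin range were clipped to edge bins"
            )
    if noise is None:
        noise = draw_common_noise(list(_counts), n_sim, seed)

    nll = 0.0
    for cond, counts in _counts.items():
        dists = predict_response_distribution(
            params, strategy, cond, n_sim, bins, noise=noise[cond]
        )
        for modality, c in counts.items():
            if c is not None:
                nll -= float(c @ np.log(dists[modality].probabilities))
    return nll


# --- bounded simplex -------------------------------------------------------

def _to_unbounded(x: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    frac = np.clip((x - lb) / (ub - lb), 1e-3, 1.0 - 1e-3)
    return np.arcsin(2.0 * frac - 1.0)


def _to_bounded(u: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    return lb + (ub - lb) * (np.sin(u) + 1.0) / 2.0


def minimize_bounded_simplex(
    func,
    x0: np.ndarray,
    bounds: Sequence[Tuple[float, float]],
    max_evals: int = 2000,
    xatol: float = 1e-3,
    fatol: float = 1e-3,
):
    """Nelder-Mead inside box bounds via sinusoidal reparameterization.

    Each coordinate is mapped ``x = lb + (ub - lb) * (sin(u) + 1) / 2`` and
    the simplex runs unconstrained in ``u``; every candidate therefore
    satisfies the bounds exactly.
    Returns ``(x_best, f_best, success)``.
    """
    lb = np.array([b[0] for b in bounds], dtype=float)
    ub = np.array([b[1] for b in bounds], dtype=float)
    u0 = _to_unbounded(np.asarray(x0, dtype=float), lb, ub)
    # explicit initial simplex: the default perturbs zero coordinates by
    # only 2.5e-4, which freezes any parameter whose start maps to u=0
    n = u0.size
    simplex = np.tile(u0, (n + 1, 1))
    for i in range(n):
        simplex[i + 1, i] += 0.25
    res = minimize(
        lambda u: func(_to_bounded(u, lb, ub)),
        u0,
        method="Nelder-Mead",
        options={
            "maxfev": max_evals,
            "xatol": xatol,
            "fatol": fatol,
            "adaptive": True,
            "initial_simplex": simplex,
        },
    )
    return _to_bounded(res.x, lb, ub), float(res.fun), bool(res.success)


@dataclass
class FitConfig:
    """Settings for one maximum-likelihood fit."""

    n_sim: int = 10_000
    n_restarts: int = 3
    max_evals: int = 2000
    xatol: float = 1e-3
    fatol: float = 1e-3
    bins: Optional[np.ndarray] = None
    bounds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    seed: int = 0

    def bin_edges(self) -> np.ndarray:
        return default_bins() if self.bins is None else np.asarray(self.bins, float)


#: Neutral simplex starting point: indifferent binding, weak central prior,
#: typical visual/auditory noise, no biases.
NEUTRAL_START = {
    "p_common": 0.5,
    "mu_prior": 0.0,
    "sigma_prior": 20.0,
    "sigma_v": 3.0,
    "delta_sigma_v": 0.0,
    "delta_x_v": 0.0,
    "sigma_a": 8.0,
    "delta_x_a": 0.0,
}


@dataclass
class FitResult:
    """Outcome of fitting one subject/session."""

    params: ModelParameters
    strategy: DecisionStrategy
    loglik_by_strategy: Dict[str, float]
    r_squared: Optional[float]
    n_sim: int
    seed: int
    converged: bool
    n_restarts: int
    subject_id: Optional[str] = None
    session: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "session": self.session,
            "params": self.params.to_dict(),
            "strategy": self.strategy.value,
            "loglik_by_strategy": {k: float(v) for k, v in self.loglik_by_strategy.items()},
            "r_squared": None if self.r_squared is None else float(self.r_squared),
            "r_squared_definition": "r2_binned_5deg",
            "n_sim": self.n_sim,
            "seed": self.seed,
            "converged": self.converged,
            "n_restarts": self.n_restarts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            params=ModelParameters(**d["params"]),
            strategy=DecisionStrategy(d["strategy"]),
            loglik_by_strategy=dict(d["loglik_by_strategy"]),
            r_squared=d.get("r_squared"),
            n_sim=d["n_sim"],
            seed=d["seed"],
            converged=d["converged"],
            n_restarts=d["n_restarts"],
            subject_id=d.get("subject_id"),
            session=d.get("session"),
        )


def fit_strategy(
    trials: Sequence[TrialRecord],
    strategy: DecisionStrategy,
    config: Optional[FitConfig] = None,
) -> Tuple[ModelParameters, float]:
    """Fit the eight parameters under one decision strategy.

    Bounded-simplex minimization of the simulated negative log-likelihood
    from ``n_restarts`` starting points (one neutral, the rest uniform
    within bounds from the seeded stream). Returns the best restart's
    parameters and its log-likelihood.
    """
    config = config or FitConfig()
    bins = config.bin_edges()
    counts, n_clipped = _observed_bin_counts(trials, bins)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} response(s) outside the bin range were clipped to edge bins"
        )
    noise = draw_common_noise(list(counts), config.n_sim, config.seed)
    bounds = [config.bounds[name] for name in PARAM_NAMES]

    def objective(x: np.ndarray) -> float:
        return negative_log_likelihood(
            ModelParameters.from_array(x),
            strategy,
            trials,
            n_sim=config.n_sim,
            bins=bins,
            noise=noise,
            _counts=counts,
        )

    start_rng = substream(config.seed, "restarts", strategy.value)
    starts = [np.array([NEUTRAL_START[n] for n in PARAM_NAMES])]
    for _ in range(config.n_restarts - 1):
        starts.append(
            np.array([start_rng.uniform(lo, hi) for lo, hi in bounds])
        )

    best_x, best_f, any_success = None, np.inf, False
    for x0 in starts:
        x, f, ok = minimize_bounded_simplex(
            objective, x0, bounds, config.max_evals, config.xatol, config.fatol
        )
        any_success = any_success or ok
        if f < best_f:
            best_x, best_f = x, f
    if not any_success:
        warnings.warn(f"no restart converged for strategy {strategy.value}")
    return ModelParameters.from_array(best_x), -best_f


def fit_subject(
    trials: Sequence[TrialRecord],
    config: Optional[FitConfig] = None,
    subject_id: Optional[str] = None,
    session: Optional[str] = None,
) -> FitResult:
    """Fit all three decision strategies and keep the best.

    The three strategies have equal parameter counts, so selection is by
    raw maximum log-likelihood with no complexity penalty.
    """
    config = config or FitConfig()
    results = {}
    for strategy in DecisionStrategy:
        results[strategy] = fit_strategy(trials, strategy, config)
    best = max(DecisionStrategy, key=lambda s: results[s][1])
    params, loglik = results[best]
    fit = FitResult(
        params=params,
        strategy=best,
        loglik_by_strategy={s.value: results[s][1] for s in DecisionStrategy},
        r_squared=None,
        n_sim=config.n_sim,
        seed=config.seed,
        converged=True,
        n_restarts=config.n_restarts,
        subject_id=subject_id,
        session=session,
    )
    fit.r_squared = goodness_of_fit(trials, fit)
    return fit


def goodness_of_fit(
    trials: Sequence[TrialRecord],
    fit: FitResult,
    bins: Optional[np.ndarray] = None,
) -> Optional[float]:
    """R-squared of the fit: squared Pearson correlation between observed
    and predicted binned response frequencies, concatenated over every
    condition and modality, on the coarse ``r2_bins`` grid by default.
    Clipped to [0, 1]; None (with a warning) if either vector is constant.
    """
    bins = r2_bins() if bins is None else np.asarray(bins, dtype=float)
    counts, _ = _observed_bin_counts(trials, bins)
    observed, predicted = [], []
    for cond, per_mod in sorted(counts.items(), key=lambda kv: _condition_key(kv[0])):
        noise_seed = substream(fit.seed, "gof").integers(2**31)
        dists = predict_response_distribution(
            fit.params,
            fit.strategy,
            cond,
            fit.n_sim,
            bins,
            noise=draw_common_noise([cond], fit.n_sim, int(noise_seed))[cond],
        )
        for modality, c in per_mod.items():
            if c is None:
                continue
            observed.append(c / c.sum())
            predicted.append(dists[modality].probabilities)
    obs = np.concatenate(observed)
    pred = np.concatenate(predicted)
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        warnings.warn("goodness of fit undefined: constant frequency vector")
        return None
    r = pearsonr(obs, pred).statistic
    return float(np.clip(r**2, 0.0, 1.0))
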