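"""Synthetic observers and cohorts emulating the study design.

The default design mirrors the localization task: 5 unisensory auditory
conditions, 5 unisensory visual conditions and the 5x5 cross-product of
bisensory conditions (35 conditions), 15 trials each, 525 trials per
session, trials shuffled into pseudorandom order. Cohorts draw each
subject's ground-truth parameters from configurable population
distributions, hold them fixed across sessions except for an injected
additive pre-to-post shift of the binding tendency, and assign each
subject a single decision strategy for both sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitting import DEFAULT_BOUNDS, TrialRecord
from .model import (
    LOCATIONS,
    PARAM_NAMES,
    DecisionStrategy,
    ModelParameters,
    StimulusCondition,
    simulate_trial,
)
from .rng import substream

__all__ = [
    "DesignSpec",
    "ParameterDistributions",
    "CohortSpec",
    "build_design",
    "expand_trials",
    "sample_subject_params",
    "simulate_subject_sessions",
    "simulate_cohort",
]


@dataclass(frozen=True)
class DesignSpec:
    """Stimulus design: locations, repetitions, unisensory inclusion."""

    locations: Tuple[float, ...] = LOCATIONS
    n_reps: int = 15
    include_unisensory: bool = True

    def __post_init__(self) -> None:
        if len(self.locations) == 0:
            raise ValueError("locations must be non-empty")
        if len(set(self.locations)) != len(self.locations):
            raise ValueError(f"locations must be distinct, got {self.locations}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def build_design(spec: Optional[DesignSpec] = None) -> List[Tuple[StimulusCondition, int]]:
    """All stimulus conditions with repetition counts, deterministic order.

    With L locations: L unisensory-auditory + L unisensory-visual
    conditions (if included) followed by the L x L bisensory grid.
    """
    spec = spec or DesignSpec()
    out: List[Tuple[StimulusCondition, int]] = []
    if spec.include_unisensory:
        for loc in spec.locations:
            out.append((StimulusCondition(s_a=loc), spec.n_reps))
        for loc in spec.locations:
            out.append((StimulusCondition(s_v=loc), spec.n_reps))
    for s_a in spec.locations:
        for s_v in spec.locations:
            out.append((StimulusCondition(s_a=s_a, s_v=s_v), spec.n_reps))
    return out


def expand_trials(
    design: Sequence[Tuple[StimulusCondition, int]], rng: np.random.Generator
) -> List[StimulusCondition]:
    """Expand the design to a shuffled trial-level condition sequence."""
    trials: List[StimulusCondition] = []
    for cond, reps in design:
        trials.extend([cond] * reps)
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def _lognormal(rng: np.random.Generator, median: float, sigma_log: float) -> float:
    return float(median * np.exp(sigma_log * rng.standard_normal()))


@dataclass(frozen=True)
class ParameterDistributions:
    """Population laws for ground-truth observer parameters.

    Defaults put auditory noise well above visual noise with a weak,
    roughly central spatial prior and small eccentricity biases — the
    qualitative regime the observer model assumes. ``fixed`` pins any
    subset of parameters to exact values (point masses).

    - p_common ~ Beta(beta_a, beta_b), default Beta(2, 4)
    - sigma_a, sigma_v, sigma_prior ~ log-normal around their medians
    - mu_prior, delta_x_v, delta_x_a ~ Normal; delta_sigma_v ~ |Normal|
    """

    beta_a: float = 2.0
    beta_b: float = 4.0
    sigma_a_median: float = 8.0
    sigma_a_logsd: float = 0.4
    sigma_v_median: float = 2.0
    sigma_v_logsd: float = 0.4
    sigma_prior_median: float = 25.0
    sigma_prior_logsd: float = 0.3
    mu_prior_sd: float = 2.0
    delta_x_sd: float = 0.5
    delta_sigma_v_sd: float = 0.5
    fixed: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.fixed) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")


def sample_subject_params(
    dists: Optional[ParameterDistributions], rng: np.random.Generator
) -> ModelParameters:
    """Draw one observer's ground-truth parameters, clipped to the
    fitting bounds so every synthetic subject is recoverable in principle."""
    dists = dists or ParameterDistributions()
    draw = {
        "p_common": float(rng.beta(dists.beta_a, dists.beta_b)),
        "mu_prior": float(rng.normal(0.0, dists.mu_prior_sd)),
        "sigma_prior": _lognormal(rng, dists.sigma_prior_median, dists.sigma_prior_logsd),
        "sigma_v": _lognormal(rng, dists.sigma_v_median, dists.sigma_v_logsd),
        "delta_sigma_v": abs(float(rng.normal(0.0, dists.delta_sigma_v_sd))),
        "delta_x_v": float(rng.normal(0.0, dists.delta_x_sd)),
        "sigma_a": _lognormal(rng, dists.sigma_a_median, dists.sigma_a_logsd),
        "delta_x_a": float(rng.normal(0.0, dists.delta_x_sd)),
    }
    draw.update(dists.fixed)
    for name, (lo, hi) in DEFAULT_BOUNDS.items():
        draw[name] = float(np.clip(draw[name], lo, hi))
    return ModelParameters(**draw)


def simulate_subject_sessions(
    params_pre: ModelParameters,
    params_post: ModelParameters,
    strategy: DecisionStrategy,
    design: Sequence[Tuple[StimulusCondition, int]],
    seed: int,
    subject_id: str = "s00",
) -> List[TrialRecord]:
    """Simulate both sessions of one subject over the given design."""
    records: List[TrialRecord] = []
    for session, params in (("pre", params_pre), ("post", params_post)):
        order_rng = substream(seed, subject_id, session, "order")
        trial_rng = substream(seed, subject_id, session, "latents")
        for cond in expand_trials(design, order_rng):
            resp_a, resp_v = simulate_trial(params, strategy, cond, trial_rng)
            records.append(
                TrialRecord(
                    subject_id=subject_id,
                    session=session,
                    condition=cond,
                    response_a=resp_a,
                    response_v=resp_v,
                )
            )
    return records


@dataclass(frozen=True)
class CohortSpec:
    """One synthetic experiment cohort.

    ``delta_p_common`` is the additive pre-to-post shift injected into
    each subject's binding tendency (clipped to [0, 1]); all other
    parameters are held fixed across sessions. ``strategy_mix`` gives the
    population proportions of the three decision strategies; each subject
    keeps one strategy for both sessions.
    """

    experiment_label: str = "exp1"
    n_subjects: int = 25
    param_distributions: ParameterDistributions = field(
        default_factory=ParameterDistributions
    )
    delta_p_common: float = 0.0
    strategy_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "model_averaging": 1 / 3,
            "model_selection": 1 / 3,
            "probability_matching": 1 / 3,
        }
    )
    design: DesignSpec = field(default_factory=DesignSpec)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        total = sum(self.strategy_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"strategy proportions must sum to 1, got {total}")


def simulate_cohort(spec: CohortSpec) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: (trials table, ground-truth table).

    The trials table has one row per trial (columns ``subject_id``,
    ``session``, ``s_a``, ``s_v``, ``response_a``, ``response_v``); the
    truth table carries each subject's true parameters for both sessions
    and the assigned strategy. Byte-deterministic given ``master_seed``.
    """
    design = build_design(spec.design)
    strategies = list(spec.strategy_mix)
    probs = np.array([spec.strategy_mix[s] for s in strategies])

    trial_rows, truth_rows = [], []
    for i in range(spec.n_subjects):
        subject_id = f"{spec.experiment_label}_s{i:03d}"
        subj_rng = substream(spec.master_seed, subject_id, "params")
        params_pre = sample_subject_params(spec.param_distributions, subj_rng)
        p_post = float(np.clip(params_pre.p_common + spec.delta_p_common, 0.0, 1.0))
        params_post = ModelParameters(**{**params_pre.to_dict(), "p_common": p_post})
        strategy = DecisionStrategy(
            strategies[subj_rng.choice(len(strategies), p=probs)]
        )
        records = simulate_subject_sessions(
            params_pre, params_post, strategy, design, spec.master_seed, subject_id
        )
        for r in records:
            trial_rows.append(
                {
                    "subject_id": r.subject_id,
                    "session": r.session,
                    "s_a": r.condition.s_a,
                    "s_v": r.condition.s_v,
                    "response_a": r.response_a,
                    "response_v": r.response_v,
                }
            )
        row = {
            "experiment": spec.experiment_label,
            "subject_id": subject_id,
            "strategy": strategy.value,
        }
        for name in PARAM_NAMES:
            row[f"{name}_pre"] = getattr(params_pre, name)
            row[f"{name}_post"] = getattr(params_post, name)
        truth_rows.append(row)

    trial_cols = ["subject_id", "session", "s_a", "s_v", "response_a", "response_v"]
    truth_cols = ["experiment", "subject_id", "strategy"] + [
        f"{n}_{s}" for n in PARAM_NAMES for s in ("pre", "post")
    ]
    return (
        pd.DataFrame(trial_rows, columns=trial_cols),
        pd.DataFrame(truth_rows, columns=truth_cols),
    )
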