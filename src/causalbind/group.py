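"""Group-level statistics on fitted binding tendencies.

Per-subject difference scores (post-test minus pre-test binding
tendency), a single-pass Cook's-distance outlier exclusion based on the
OLS regression of post-test on pre-test values, a within-experiment
percentile bootstrap of the mean difference score, and a
between-experiment bootstrap of the difference of group means against a
control experiment. All inference here is bootstrap-based; no parametric
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rng import substream

__all__ = [
    "GroupAnalysisResult",
    "difference_scores",
    "cooks_exclusion",
    "bootstrap_mean_ci",
    "bootstrap_between",
    "run_table2",
]

#: Versus-control CI endpoints within this distance of zero are "marginal".
MARGINAL_BAND = 0.01


@dataclass
class GroupAnalysisResult:
    """A bootstrap distribution summary for one analysis."""

    experiment_label: str
    scores: np.ndarray
    excluded_ids: List[str]
    boot_mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    contains_zero: bool
    samples: Optional[np.ndarray] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "experiment_label": self.experiment_label,
            "scores": [float(s) for s in self.scores],
            "excluded_ids": list(self.excluded_ids),
            "boot_mean": float(self.boot_mean),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "n_boot": int(self.n_boot),
            "seed": int(self.seed),
            "contains_zero": bool(self.contains_zero),
        }


def difference_scores(
    fits_pre: Dict[str, float], fits_post: Dict[str, float]
) -> pd.Series:
    """Per-subject post-minus-pre binding tendency, ordered by subject id.

    Inputs map subject id to fitted ``p_common`` for each session; the
    two sessions must cover exactly the same subjects.
    """
    missing_post = sorted(set(fits_pre) - set(fits_post))
    missing_pre = sorted(set(fits_post) - set(fits_pre))
    if missing_post or missing_pre:
        raise ValueError(
            f"unmatched subjects: missing post={missing_post}, missing pre={missing_pre}"
        )
    ids = sorted(fits_pre)
    return pd.Series(
        [fits_post[i] - fits_pre[i] for i in ids], index=ids, name="delta_p_common"
    )


def cooks_exclusion(
    pre: np.ndarray, post: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Single-pass outlier screen by Cook's distance.

    Fits OLS of post-test on pre-test binding tendency (slope plus
    intercept), computes Cook's distance D_i for each subject, and drops
    subjects with D_i > 4 * mean(D). Returns (retained boolean mask,
    all D_i). Not iterated. If the pre-test scores have zero variance the
    regression is intercept-only.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    n = pre.size
    if n < 4:
        raise ValueError(f"need at least 4 subjects for Cook's diagnostics, got {n}")
    if np.ptp(pre) == 0:
        warnings.warn("pre-test scores have zero variance; using intercept-only model")
        design = np.ones((n, 1))
    else:
        design = sm.add_constant(pre)
    fit = sm.OLS(post, design).fit()
    # exact fit: residuals are rounding noise and D_i = e_i^2 * h / (p s^2 ...)
    # becomes 0/0 garbage; all distances are truly zero, nothing to exclude
    scale = max(1.0, float(np.max(np.abs(post))))
    if np.max(np.abs(fit.resid)) <= 1e-10 * scale:
        return np.ones(n, dtype=bool), np.zeros(n)
    cooks = fit.get_influence().cooks_distance[0]
    retained = cooks <= 4.0 * cooks.mean()
    return retained, cooks


def bootstrap_mean_ci(
    scores: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    label: str = "",
    excluded_ids: Optional[List[str]] = None,
) -> GroupAnalysisResult:
    """Percentile bootstrap of the mean difference score.

    Draws ``n_boot`` resamples of size n with replacement, records the
    mean of the resample means and the 2.5th/97.5th percentiles, and
    flags whether the interval contains 0.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    rng = substream(seed, "boot-within", label)
    idx = rng.integers(0, scores.size, size=(n_boot, scores.size))
    means = scores[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return GroupAnalysisResult(
        experiment_label=label,
        scores=scores,
        excluded_ids=excluded_ids or [],
        boot_mean=float(means.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        contains_zero=bool(lo <= 0.0 <= hi),
        samples=means,
    )


def bootstrap_between(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    label: str = "",
) -> GroupAnalysisResult:
    """Percentile bootstrap of mean(a) - mean(b) for two experiments.

    Each iteration independently resamples both groups with replacement
    (each to its own size) and records the difference of resample means.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = substream(seed, "boot-between", label)
    means_a = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    means_b = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    diffs = means_a - means_b
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return GroupAnalysisResult(
        experiment_label=label,
        scores=np.concatenate([a, b]),
        excluded_ids=[],
        boot_mean=float(diffs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        contains_zero=bool(lo <= 0.0 <= hi),
        samples=diffs,
    )


def _categorical_call(
    within: GroupAnalysisResult, versus: Optional[GroupAnalysisResult]
) -> str:
    """Map the two CIs to a change category.

    The within-experiment CI must exclude 0 for any call; the
    versus-control CI then decides strength — "marginal" when its
    endpoint nearest zero sits within MARGINAL_BAND of 0.
    """
    if within.contains_zero:
        return "none"
    direction = "increase" if within.boot_mean > 0 else "decrease"
    if versus is None:
        return direction
    near_edge = versus.ci_low if within.boot_mean > 0 else versus.ci_high
    if not versus.contains_zero and abs(near_edge) > MARGINAL_BAND:
        return direction
    if abs(near_edge) <= MARGINAL_BAND:
        return f"marginal {direction}"
    return "none"


def run_table2(
    p_common_by_experiment: Dict[str, Tuple[Dict[str, float], Dict[str, float]]],
    control_label: str,
    n_boot: int = 10_000,
    seed: int = 0,
    apply_cooks: bool = True,
) -> Tuple[pd.DataFrame, dict]:
    """The full group pipeline for a suite of experiments.

    Input maps experiment label to ``(fits_pre, fits_post)`` dicts of
    subject id -> fitted binding tendency. For each experiment: Cook's
    exclusion on the pre/post scatter, within-experiment bootstrap of the
    mean difference score, versus-control bootstrap, and a categorical
    call. Returns the summary table plus an audit dict (seeds, resample
    counts, exclusions, Cook diagnostics).
    """
    if control_label not in p_common_by_experiment:
        raise ValueError(f"control experiment {control_label!r} not in input")

    retained_scores: Dict[str, np.ndarray] = {}
    excluded: Dict[str, List[str]] = {}
    cooks_all: Dict[str, list] = {}
    for label, (fits_pre, fits_post) in p_common_by_experiment.items():
        scores = difference_scores(fits_pre, fits_post)
        ids = list(scores.index)
        pre = np.array([fits_pre[i] for i in ids])
        post = np.array([fits_post[i] for i in ids])
        if apply_cooks and len(ids) >= 4:
            mask, cooks = cooks_exclusion(pre, post)
        else:
            mask, cooks = np.ones(len(ids), bool), np.zeros(len(ids))
        retained_scores[label] = scores.values[mask]
        excluded[label] = [i for i, keep in zip(ids, mask) if not keep]
        cooks_all[label] = [float(c) for c in cooks]

    rows = []
    audit = {
        "seed": seed,
        "n_boot": n_boot,
        "control": control_label,
        "marginal_band": MARGINAL_BAND,
        "cooks_rule": "D_i > 4 * mean(D), OLS post ~ pre" if apply_cooks else "disabled",
        "excluded": excluded,
        "cooks_distance": cooks_all,
        "experiments": {},
    }
    for label, scores in retained_scores.items():
        within = bootstrap_mean_ci(
            scores, n_boot, seed, label=label, excluded_ids=excluded[label]
        )
        versus = None
        if label != control_label:
            versus = bootstrap_between(
                scores, retained_scores[control_label], n_boot, seed, label=label
            )
        call = _categorical_call(within, versus)
        rows.append(
            {
                "experiment": label,
                "n_retained": scores.size,
                "n_excluded": len(excluded[label]),
                "boot_mean": within.boot_mean,
                "ci_low": within.ci_low,
                "ci_high": within.ci_high,
                "vs_control_mean": np.nan if versus is None else versus.boot_mean,
                "vs_control_ci_low": np.nan if versus is None else versus.ci_low,
                "vs_control_ci_high": np.nan if versus is None else versus.ci_high,
                "call": call,
            }
        )
        audit["experiments"][label] = {
            "within": within.to_dict(),
            "versus_control": None if versus is None else versus.to_dict(),
            "call": call,
        }
    return pd.DataFrame(rows), audit
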