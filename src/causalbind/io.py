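"""File round-tripping: trial tables, fit-result JSON, configuration.

Trial tables are comma-separated UTF-8 text with a header
``subject_id,session,s_a,s_v,response_a,response_v``; an empty field
means the value is absent (unisensory trials), decimals use a dot.
Fit results are one JSON document per subject/session. Configuration is
YAML (plain key-value).
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, TrialRecord
from .model import StimulusCondition

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "frame_to_records",
    "write_fit_result",
    "read_fit_result",
    "load_config",
    "dump_config",
]

TRIAL_COLUMNS = ["subject_id", "session", "s_a", "s_v", "response_a", "response_v"]


class TrialTableError(ValueError):
    """A trial table failed schema validation."""


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def frame_to_records(df: pd.DataFrame, source: str = "<frame>") -> List[TrialRecord]:
    """Validate a trial table and convert it to TrialRecord objects.

    Every malformed row is reported with its (1-based, header-inclusive)
    row number; any failure rejects the whole table.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{source}: missing columns {missing}")
    records, problems = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            cond = StimulusCondition(s_a=_opt(row.s_a), s_v=_opt(row.s_v))
            records.append(
                TrialRecord(
                    subject_id=str(row.subject_id),
                    session=str(row.session),
                    condition=cond,
                    response_a=_opt(row.response_a),
                    response_v=_opt(row.response_v),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        detail = "; ".join(problems[:10])
        more = f" (+{len(problems) - 10} more)" if len(problems) > 10 else ""
        raise TrialTableError(f"{source}: {len(problems)} bad row(s): {detail}{more}")
    return records


def read_trials(path) -> List[TrialRecord]:
    """Read and validate a comma-separated trial table."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "session": str})
    return frame_to_records(df, source=path.name)


def trials_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "session": r.session,
            "s_a": r.condition.s_a,
            "s_v": r.condition.s_v,
            "response_a": r.response_a,
            "response_v": r.response_v,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(records_or_frame, path) -> None:
    """Write a trial table (empty field = absent value)."""
    df = (
        records_or_frame
        if isinstance(records_or_frame, pd.DataFrame)
        else trials_to_frame(records_or_frame)
    )
    df.to_csv(path, index=False, float_format="%.6g")


def _version_stamps() -> Dict[str, str]:
    import scipy
    import statsmodels

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def write_fit_result(fit: FitResult, path, config_echo: Optional[dict] = None) -> None:
    doc = fit.to_dict()
    doc["config"] = config_echo or {}
    doc["versions"] = _version_stamps()
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_fit_result(path) -> FitResult:
    return FitResult.from_dict(json.loads(Path(path).read_text()))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
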