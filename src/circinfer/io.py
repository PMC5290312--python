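"""Trial-table reading/writing and schema validation.

The on-disk format is a UTF-8 CSV with one row per trial and columns
``participant_id, block, trial, basket_left, basket_right, p_red_right,
confidence[, rt]``. Lines starting with ``#`` are provenance comments
(seed, config) and are skipped on read. Validation errors name the offending
rows and columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import TaskTrial
from .synth import ResponseRecord

REQUIRED_COLUMNS = (
    "participant_id",
    "block",
    "trial",
    "basket_left",
    "basket_right",
    "p_red_right",
    "confidence",
)


class TrialTableError(ValueError):
    """Raised when a trial table fails schema validation."""


def _offenders(mask: pd.Series, limit: int = 10) -> list[int]:
    return mask[mask].index.tolist()[:limit]


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and ranges; return a copy with derived logit columns."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing required columns: {missing}")
    problems: list[str] = []
    for col in ("basket_left", "basket_right"):
        bad = ~(pd.to_numeric(df[col], errors="coerce") > 0)
        if bad.any():
            problems.append(f"{col} must be > 0; offending rows {_offenders(bad)}")
    for col, lo, hi in (("p_red_right", 0.0, 1.0), ("confidence", 0.0, 1.0)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~((vals >= lo) & (vals <= hi))
        if bad.any():
            problems.append(f"{col} must lie in [{lo}, {hi}]; offending rows {_offenders(bad)}")
    dup = df.duplicated(subset=["participant_id", "block", "trial"])
    if dup.any():
        problems.append(f"duplicate (participant_id, block, trial) keys at rows {_offenders(dup)}")
    if problems:
        raise TrialTableError("; ".join(problems))

    out = df.copy()
    out["prior_logit"] = np.log(out["basket_right"] / out["basket_left"])
    p = out["p_red_right"].astype(float)
    with np.errstate(divide="ignore"):
        out["likelihood_logit"] = np.log(p) - np.log1p(-p)
    out["is_ambiguous"] = (p > 0.0) & (p < 1.0)
    return out


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV, attaching derived logits."""
    df = pd.read_csv(path, comment="#")
    return validate_trial_table(df)


def write_trial_table(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a trial table as CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in df.columns if c not in ("prior_logit", "likelihood_logit", "is_ambiguous")]
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df[cols].to_csv(fh, index=False)


def participant_records(
    df: pd.DataFrame,
) -> dict[str, tuple[list[TaskTrial], list[ResponseRecord]]]:
    """Split a validated table into per-participant trial/response lists."""
    out: dict[str, tuple[list[TaskTrial], list[ResponseRecord]]] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values(["block", "trial"])
        trials = [
            TaskTrial(basket_left=row.basket_left, basket_right=row.basket_right, p_red_right=row.p_red_right)
            for row in grp.itertuples()
        ]
        rts = grp["rt"].tolist() if "rt" in grp.columns else [None] * len(grp)
        responses = [
            ResponseRecord(confidence=float(c), rt=None if rt is None or pd.isna(rt) else float(rt))
            for c, rt in zip(grp["confidence"], rts)
        ]
        out[str(pid)] = (trials, responses)
    return out
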