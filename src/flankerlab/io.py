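"""Trial-table CSV schema, validation, and pipeline configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import design
from .design import EXPERIMENTS, TrialSpec

COLUMNS = (
    "subject_id",
    "experiment",
    "block_index",
    "block_condition",
    "trial_index",
    "is_practice",
    "congruency",
    "target_direction",
    "soa_ms",
    "t_delta_ms",
    "location",
    "response",
    "rt_ms",
)

_ENUMS = {
    "experiment": set(EXPERIMENTS),
    "block_condition": {design.FIXED, design.VARIABLE, design.NA},
    "congruency": set(design.CONGRUENCIES),
    "target_direction": set(design.DIRECTIONS),
    "location": {design.FIXED_CENTER, *design.OFFSET_LOCATIONS},
    "response": {design.LEFT, design.RIGHT, "none"},
}


class SchemaError(ValueError):
    """Trial table violates the interchange schema."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid trial table:\n  " + "\n  ".join(self.problems))


def specs_to_frame(specs: Sequence[TrialSpec], subject_id: Optional[int] = None) -> pd.DataFrame:
    """Serialize a design (no responses) into the trial-table schema."""
    df = pd.DataFrame(
        {
            "experiment": [s.experiment for s in specs],
            "block_index": [s.block_index for s in specs],
            "block_condition": [s.block_condition for s in specs],
            "trial_index": [s.trial_index for s in specs],
            "is_practice": [s.is_practice for s in specs],
            "congruency": [s.congruency for s in specs],
            "target_direction": [s.target_direction for s in specs],
            "soa_ms": pd.array([s.soa_ms for s in specs], dtype="Int64"),
            "t_delta_ms": pd.array([s.t_delta_ms for s in specs], dtype="Int64"),
            "location": [s.location for s in specs],
        }
    )
    if subject_id is not None:
        df.insert(0, "subject_id", subject_id)
    return df


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the schema; returns a typed copy.

    Problems are collected and reported together, each naming the offending
    rows (0-based positions in the table).
    """
    problems: list[str] = []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError([f"missing columns: {missing}"])

    out = df.loc[:, list(COLUMNS)].copy()
    out = out.reset_index(drop=True)

    for col, levels in _ENUMS.items():
        bad = out.index[~out[col].astype(str).isin(levels)].tolist()
        if bad:
            vals = sorted(set(out.loc[bad, col].astype(str)))
            problems.append(f"column {col!r}: unknown level(s) {vals} at rows {bad[:20]}")

    for col in ("subject_id", "block_index", "trial_index"):
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[coerced.isna()].tolist()
        if bad:
            problems.append(f"column {col!r}: malformed number at rows {bad[:20]}")
        else:
            out[col] = coerced.astype(int)

    for col in ("soa_ms", "t_delta_ms", "rt_ms"):
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[coerced.isna() & out[col].notna() & (out[col].astype(str) != "")].tolist()
        if bad:
            problems.append(f"column {col!r}: malformed number at rows {bad[:20]}")
        out[col] = pd.array(coerced, dtype="Int64")

    if out["is_practice"].dtype != bool:
        mapped = out["is_practice"].astype(str).str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        bad = out.index[mapped.isna()].tolist()
        if bad:
            problems.append(f"column 'is_practice': not boolean at rows {bad[:20]}")
        else:
            out["is_practice"] = mapped.astype(bool)

    if not problems:
        dup = out.duplicated(subset=["subject_id", "block_index", "trial_index"])
        bad = out.index[dup].tolist()
        if bad:
            problems.append(f"duplicate (subject, block, trial) keys at rows {bad[:20]}")

    if problems:
        raise SchemaError(problems)
    return out


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    df = pd.read_csv(path, dtype={"soa_ms": "Int64", "t_delta_ms": "Int64", "rt_ms": "Int64"})
    return validate_trials(df)


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in COLUMNS if c in df.columns])


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; all randomness flows from ``seed``."""

    experiment: str = design.EXP1
    n_subjects: int = 40
    seed: int = 0
    counterbalance: str = "ABBA"       # EXP3 only
    balanced_locations: bool = False   # EXP3 only
    rt_cutoff_ms: int = 200
    min_trials: int = 10
    score_weights: Optional[tuple[float, float]] = None
    one_sided_simple_effects: bool = False
    make_plots: bool = False
    preset_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.counterbalance not in ("ABBA", "BAAB"):
            raise ValueError("counterbalance must be ABBA or BAAB")
        if self.rt_cutoff_ms < 0 or self.min_trials < 1:
            raise ValueError("invalid analysis thresholds")
        if self.score_weights is not None:
            w = tuple(self.score_weights)
            if len(w) != 2 or abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("score_weights must be two values summing to 1")
            self.score_weights = w

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if d["score_weights"] is not None:
            d["score_weights"] = list(d["score_weights"])
        return json.dumps(d, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if d.get("score_weights") is not None:
            d["score_weights"] = tuple(d["score_weights"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def default_score_weights(experiment: str) -> Optional[tuple[float, float]]:
    """Block-score weighting used by each design: the contrast-change
    experiments weight accuracy 80/20, the location experiment 75/25, and
    the timing experiment uses the unweighted product form."""
    if experiment in (design.EXP2A, design.EXP2B):
        return (0.8, 0.2)
    if experiment == design.EXP3:
        return (0.75, 0.25)
    return None
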