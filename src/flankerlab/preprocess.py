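"""Response classification, exclusion rules, and carry-over labeling.

Timing is referenced to target onset throughout; a negative RT therefore
means the key went down before the target appeared (a premature response).
Responses faster than the cutoff (default 200 ms) are counted as errors for
every analysis.
"""

from __future__ import annotations

import pandas as pd

from .design import EXP3, FIXED, VARIABLE

RT_CUTOFF_MS = 200

# carry-over labels
FIRST = "first"     # first trial of a block, excluded everywhere
SAME = "same"       # variable trial repeating the previous trial's location
DIFF = "diff"       # variable trial changing location
FIXED_TRIAL = "fixed"  # non-first trial of a fixed block (retained)


class MalformedTableError(ValueError):
    """Rows violate the trial-table contract; offending rows are listed."""

    def __init__(self, message: str, rows):
        self.rows = list(rows)
        super().__init__(f"{message} (rows: {self.rows})")


def classify_trials(table: pd.DataFrame, rt_cutoff_ms: int = RT_CUTOFF_MS) -> pd.DataFrame:
    """Append ``premature``, ``correct`` and ``usable_for_rt`` flags.

    A trial is correct only when a response was made, it matches the target
    direction, and the RT is at or beyond the cutoff.  ``usable_for_rt``
    marks the trials entering any RT statistic (correct by that definition).
    Idempotent: reapplying yields identical flags.
    """
    df = table.copy()
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")

    bad = df.index[(df["response"] == "none") & rt.notna()]
    if len(bad):
        raise MalformedTableError("RT present on trials without a response", bad)

    responded = df["response"].isin(["left", "right"])
    df["premature"] = (rt < 0).fillna(False) & responded
    matches = responded & (df["response"] == df["target_direction"])
    df["correct"] = matches & (rt >= rt_cutoff_ms).fillna(False)
    df["usable_for_rt"] = df["correct"]
    return df


def label_carryover(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Label each EXP3 trial by its relation to the preceding trial.

    Within each (subject, block): the first trial is labeled ``first`` and
    excluded from all analyses; variable-block trials are ``same`` or
    ``diff`` according to whether their location repeats the immediately
    preceding trial's; fixed-block trials are ``fixed``.  Returns the labeled
    table and the per-subject count of retained fixed trials.
    """
    df = table.copy()
    if not (df["experiment"] == EXP3).all():
        raise ValueError("carry-over labeling applies to EXP3 tables only")

    grouped = df.groupby(["subject_id", "block_index"], sort=False)
    if not (grouped["trial_index"].diff().dropna() == 1).all():
        raise ValueError("table must be ordered by (subject, block, trial)")

    prev_loc = grouped["location"].shift(1)
    is_first = prev_loc.isna()
    is_variable = df["block_condition"] == VARIABLE

    labels = pd.Series(FIXED_TRIAL, index=df.index, dtype=object)
    labels[is_variable & (df["location"] == prev_loc)] = SAME
    labels[is_variable & prev_loc.notna() & (df["location"] != prev_loc)] = DIFF
    labels[is_first] = FIRST
    df["carryover"] = labels

    retained_fixed = (
        df[(df["carryover"] == FIXED_TRIAL) & (df["block_condition"] == FIXED)]
        .groupby("subject_id")
        .size()
    )
    return df, retained_fixed


def analysis_condition_key(table: pd.DataFrame) -> pd.Series:
    """Condition key used by the downstream summaries.

    EXP1: the SOA in ms.  EXP2: the contrast-change time ("none" for the
    constant condition).  EXP3: the three location conditions derived from
    the carry-over labels; ``first`` trials map to NA and drop out.
    """
    exp = table["experiment"]
    keys = pd.Series(pd.NA, index=table.index, dtype=object)

    m1 = exp == "EXP1"
    if m1.any():
        keys[m1] = table.loc[m1, "soa_ms"].astype("Int64").astype(str)

    m2 = exp.isin(["EXP2A", "EXP2B"])
    if m2.any():
        td = table.loc[m2, "t_delta_ms"]
        keys[m2] = td.map(lambda v: "none" if pd.isna(v) else str(int(v)))

    m3 = exp == EXP3
    if m3.any():
        if "carryover" not in table.columns:
            raise ValueError("EXP3 tables need label_carryover before summarizing")
        mapping = {FIXED_TRIAL: "fixed", SAME: "var_same", DIFF: "var_diff"}
        keys[m3] = table.loc[m3, "carryover"].map(mapping)

    return keys
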