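"""Condition summaries, congruency effects, within-subject error bars, and
the block feedback score."""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import CONGRUENT, INCONGRUENT
from .preprocess import analysis_condition_key

LOG_UPPER = math.log(3000.0)
LOG_REF = math.log(1300.0)


def summarize_conditions(
    table: pd.DataFrame, condition_key: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Per subject x condition x congruency: mean error rate and median
    correct RT.

    ``table`` must be classified (see :func:`~flankerlab.preprocess.classify_trials`).
    Practice trials and trials with a missing condition key are excluded.
    Cells with no trials at all cannot appear; cells with no usable RTs get a
    missing median and are flagged.
    """
    df = table.loc[~table["is_practice"]].copy()
    if condition_key is None:
        condition_key = analysis_condition_key(df)
    else:
        condition_key = condition_key.loc[df.index]
    df["condition"] = condition_key
    df = df[df["condition"].notna()]

    def _cell(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        n_correct = int(g["correct"].sum())
        rts = g.loc[g["usable_for_rt"], "rt_ms"].astype(float)
        return pd.Series(
            {
                "n_trials": n,
                "n_correct": n_correct,
                "er": 1.0 - n_correct / n,
                "median_rt_ms": float(rts.median()) if len(rts) else np.nan,
                "n_rt": len(rts),
            }
        )

    out = (
        df.groupby(["subject_id", "condition", "congruency"], sort=True)
        .apply(_cell, include_groups=False)
        .reset_index()
    )
    out["flagged_empty"] = out["n_rt"] == 0
    if out["flagged_empty"].any():
        k = int(out["flagged_empty"].sum())
        warnings.warn(f"{k} summary cell(s) have no usable RTs and carry a missing median")
    out = out.astype({"n_trials": int, "n_correct": int, "n_rt": int})
    return out


def compute_fce(summaries: pd.DataFrame) -> pd.DataFrame:
    """Flanker congruency effect per subject x condition:
    incongruent minus congruent, for error rate and median RT."""
    wide = summaries.pivot_table(
        index=["subject_id", "condition"],
        columns="congruency",
        values=["er", "median_rt_ms"],
        aggfunc="first",
    )
    for level in (CONGRUENT, INCONGRUENT):
        if ("er", level) not in wide.columns:
            raise ValueError(f"missing congruency level {level!r} in summaries")
    out = pd.DataFrame(
        {
            "fce_er": wide[("er", INCONGRUENT)] - wide[("er", CONGRUENT)],
            "fce_rt_ms": wide[("median_rt_ms", INCONGRUENT)]
            - wide[("median_rt_ms", CONGRUENT)],
        }
    ).reset_index()
    return out


def within_subject_se(values: np.ndarray) -> np.ndarray:
    """Within-subject standard error per condition.

    ``values`` is a complete subjects x conditions matrix.  Each subject's
    scores are centered on their own mean and the grand mean is added back;
    the per-condition SE of the centered scores is then inflated by
    sqrt(k / (k - 1)) to correct the bias the centering introduces.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a 2-D subjects x conditions matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.isnan(x).any():
        raise ValueError("cells must be complete")
    centered = x - x.mean(axis=1, keepdims=True) + x.mean()
    se = centered.std(axis=0, ddof=1) / math.sqrt(n)
    return se * math.sqrt(k / (k - 1))


def composite_score(
    rts_ms: Sequence[float],
    n_total: int,
    n_correct: int,
    weights: Optional[tuple[float, float]] = None,
) -> tuple[float, float, float]:
    """Block feedback score combining speed and accuracy.

    speed averages, over all trials of the block, a log-compressed credit for
    each responded trial: (ln 3000 - ln(rt + 1000)) / (ln 3000 - ln 1300);
    unanswered trials contribute zero.  accuracy is the fraction correct.
    The unweighted score is ((accuracy - 0.5) / 0.5) * speed * 100.  With
    ``weights`` = (w_accuracy, w_speed) summing to 1 the score is instead the
    convex combination 100 * (w_acc * (accuracy - 0.5)/0.5 + w_speed * speed).
    Scores are clipped to [0, 100].

    Returns ``(speed, accuracy, score)``.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if n_correct > n_total:
        raise ValueError("n_correct cannot exceed n_total")
    rts = np.asarray(list(rts_ms), dtype=float)
    if np.any(rts <= -1000):
        raise ValueError("response times must exceed -1000 ms")

    denom = LOG_UPPER - LOG_REF
    terms = (LOG_UPPER - np.log(rts + 1000.0)) / denom
    speed = float(terms.sum() / n_total)
    accuracy = n_correct / n_total
    if weights is None:
        score = (accuracy - 0.5) / 0.5 * speed * 100.0
    else:
        w_acc, w_speed = weights
        if not math.isclose(w_acc + w_speed, 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
        score = 100.0 * (w_acc * (accuracy - 0.5) / 0.5 + w_speed * speed)
    return speed, accuracy, float(np.clip(score, 0.0, 100.0))
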