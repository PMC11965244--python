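"""Distributional congruency-effect analysis (delta plots).

Per subject and condition, correct RTs from each congruency level are
reduced to nine decile values (10%..90%).  The x-axis of the delta plot is
the mean of the two congruency values at each decile; the y-axis is their
difference (incongruent - congruent).  A least-squares line through the nine
points summarizes how interference changes across the RT distribution, and
group inference tests the mean slope against zero per condition, with a
Benjamini-Hochberg step-up adjustment across the conditions of an
experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PERCENTILE_LEVELS = tuple(range(10, 100, 10))
MIN_TRIALS_DEFAULT = 10


class InsufficientTrialsError(ValueError):
    """Too few correct RTs to estimate the nine deciles."""


@dataclass
class DeltaPlot:
    subject_id: object
    condition: object
    bin_rt_ms: np.ndarray   # 9 values, nondecreasing
    fce_rt_ms: np.ndarray   # 9 values
    slope: Optional[float] = None
    intercept_ms: Optional[float] = None


def rt_percentiles(
    rts: Sequence[float],
    levels: Sequence[int] = PERCENTILE_LEVELS,
    min_trials: int = MIN_TRIALS_DEFAULT,
) -> np.ndarray:
    """Decile estimates with linear interpolation between order statistics."""
    x = np.asarray(list(rts), dtype=float)
    if len(x) < min_trials:
        raise InsufficientTrialsError(
            f"need at least {min_trials} correct RTs, got {len(x)}"
        )
    return np.percentile(x, list(levels), method="linear")


def subject_delta(
    congruent_rts: Sequence[float],
    incongruent_rts: Sequence[float],
    subject_id=None,
    condition=None,
    min_trials: int = MIN_TRIALS_DEFAULT,
) -> DeltaPlot:
    """Nine (bin RT, congruency effect) pairs for one subject x condition."""
    q_c = rt_percentiles(congruent_rts, min_trials=min_trials)
    q_i = rt_percentiles(incongruent_rts, min_trials=min_trials)
    return DeltaPlot(
        subject_id=subject_id,
        condition=condition,
        bin_rt_ms=(q_c + q_i) / 2.0,
        fce_rt_ms=q_i - q_c,
    )


def fit_slope(dp: DeltaPlot) -> tuple[float, float]:
    """Ordinary least squares of the congruency effect on bin RT.

    Returns (slope, intercept); a degenerate x-axis (all bins equal) yields
    NaN slope/intercept and leaves the plot flagged via those NaNs.
    """
    x = np.asarray(dp.bin_rt_ms, dtype=float)
    y = np.asarray(dp.fce_rt_ms, dtype=float)
    if x.shape != (len(PERCENTILE_LEVELS),) or y.shape != x.shape:
        raise ValueError("delta plot must carry exactly nine valid bins")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0.0:
        dp.slope, dp.intercept_ms = math.nan, math.nan
        return math.nan, math.nan
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    dp.slope, dp.intercept_ms = slope, intercept
    return slope, intercept


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def group_slope_test(slopes_by_condition: dict) -> pd.DataFrame:
    """One-sample two-sided t-test of the mean slope per condition, with a
    BH adjustment across the experiment's conditions and Cohen's d.

    Zero-variance slopes with a nonzero mean are reported with infinite t
    and flagged.
    """
    rows = []
    for cond, slopes in slopes_by_condition.items():
        s = np.asarray(list(slopes), dtype=float)
        n = len(s)
        if n < 2:
            raise ValueError(f"condition {cond!r} needs at least 2 subjects")
        mean = s.mean()
        sd = s.std(ddof=1)
        degenerate = sd == 0.0
        if degenerate:
            t = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
            p = 1.0 if mean == 0.0 else 0.0
            d = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        else:
            t = mean / (sd / math.sqrt(n))
            p = 2.0 * stats.t.sf(abs(t), n - 1)
            d = mean / sd
        rows.append(
            {
                "condition": cond,
                "n": n,
                "mean_slope": mean,
                "t": t,
                "df": n - 1,
                "p_raw": p,
                "cohens_d": d,
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def group_delta_plot(plots: Sequence[DeltaPlot]) -> tuple[np.ndarray, np.ndarray]:
    """Group curve: mean of bin RTs and of congruency effects across
    subjects, per decile."""
    if not plots:
        raise ValueError("no delta plots supplied")
    xs = np.vstack([np.asarray(p.bin_rt_ms, dtype=float) for p in plots])
    ys = np.vstack([np.asarray(p.fce_rt_ms, dtype=float) for p in plots])
    return xs.mean(axis=0), ys.mean(axis=0)


def plot_group_delta(group_curves: dict, path) -> None:
    """Write a figure of group delta-plot curves (one line per condition).

    ``group_curves`` maps condition -> {"bin_rt_ms": [...], "fce_rt_ms": [...]}.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, curve in group_curves.items():
        ax.plot(curve["bin_rt_ms"], curve["fce_rt_ms"], marker="o", label=str(cond))
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.set_xlabel("bin RT (ms)")
    ax.set_ylabel("congruency effect (ms)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def orthogonal_poly_contrasts(k: int, max_degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial contrast vectors over level indices 1..k.

    Rows are degrees 1..max_degree, each with zero sum, unit norm, and
    mutually orthogonal (Gram-Schmidt on the Vandermonde columns).
    """
    x = np.arange(1, k + 1, dtype=float)
    basis = [np.ones(k) / math.sqrt(k)]
    out = []
    for deg in range(1, max_degree + 1):
        v = x**deg
        for b in basis:
            v = v - (v @ b) * b
        v = v / np.linalg.norm(v)
        basis.append(v)
        out.append(v)
    return np.vstack(out)


def polynomial_contrasts(fce_by_subject: np.ndarray) -> pd.DataFrame:
    """Linear and quadratic trend tests over the nine decile bins.

    ``fce_by_subject`` is a complete subjects x 9 matrix of congruency
    effects.  Contrasts are taken over bin index (1..9), not bin RT, so
    orthogonality holds by construction; each subject's contrast score is
    tested against zero with a one-sample t.
    """
    y = np.asarray(fce_by_subject, dtype=float)
    if y.ndim != 2 or y.shape[1] != len(PERCENTILE_LEVELS):
        raise ValueError("need a subjects x 9 matrix of congruency effects")
    if np.isnan(y).any():
        raise ValueError("bins must be complete")
    contrasts = orthogonal_poly_contrasts(y.shape[1], max_degree=2)
    rows = []
    for name, c in zip(("linear", "quadratic"), contrasts):
        scores = y @ c
        t, p = stats.ttest_1samp(scores, 0.0)
        rows.append(
            {
                "trend": name,
                "estimate": scores.mean(),
                "t": float(t),
                "df": len(scores) - 1,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
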