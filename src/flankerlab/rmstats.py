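"""Repeated-measures inference: two-way within-subject ANOVA with
Greenhouse-Geisser adjustment, simple effects, the carry-over contrast, and
noncentral power computations."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

PAIRED_T = "paired_t"
WITHIN_F = "within_f"


@dataclass(frozen=True)
class PowerSpec:
    test: str                 # PAIRED_T | WITHIN_F
    effect: float             # Cohen's d (paired t) or partial eta-squared (F)
    n: int
    alpha: float = 0.05
    two_sided: bool = True

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.effect < 0:
            raise ValueError("effect size must be nonnegative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _helmert(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (columns sum to zero)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser (Box) epsilon from a k x k covariance of
    within-condition scores, via the double-centered matrix; bounded in
    [1/(k-1), 1]."""
    s = np.asarray(cov, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    k = s.shape[0]
    if k == 2:
        return 1.0
    row = s.mean(axis=1, keepdims=True)
    col = s.mean(axis=0, keepdims=True)
    centered = s - row - col + s.mean()
    num = np.trace(centered) ** 2
    den = (k - 1) * np.sum(centered**2)
    if den == 0.0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _effect_epsilon(cell_means: np.ndarray, contrast: np.ndarray) -> float:
    """Epsilon for one within effect: project the n x k cell means onto the
    effect's orthonormal contrast space and apply the Box formula."""
    z = cell_means @ contrast
    df = contrast.shape[1]
    if df == 1:
        return 1.0
    s = np.cov(z, rowvar=False)
    num = np.trace(s) ** 2
    den = df * np.sum(s**2)
    if den == 0.0:
        return 1.0
    return float(np.clip(num / den, 1.0 / df, 1.0))


def rm_anova_2way(
    data: pd.DataFrame,
    dv: str,
    within: tuple[str, str],
    subject: str = "subject_id",
) -> pd.DataFrame:
    """Classical two-way within-subject ANOVA on balanced cell means.

    Each effect is tested against its own effect-by-subject interaction.
    Greenhouse-Geisser epsilon deflates both degrees of freedom for effects
    with more than one numerator df, and the reported p-value uses the
    adjusted df.  Partial eta-squared is SS_effect / (SS_effect + SS_error).
    """
    fa, fb = within
    cells = data.pivot_table(index=subject, columns=[fa, fb], values=dv, aggfunc="mean")
    if cells.isna().any().any():
        raise ValueError("missing subject x condition cells")
    a_levels = cells.columns.get_level_values(0).unique()
    b_levels = cells.columns.get_level_values(1).unique()
    p, q = len(a_levels), len(b_levels)
    n = len(cells)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    cells = cells.reindex(columns=pd.MultiIndex.from_product([a_levels, b_levels]))
    y = cells.to_numpy().reshape(n, p, q)

    m = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * q * np.sum((m_a - m) ** 2)
    ss_b = n * p * np.sum((m_b - m) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    ss_as = q * np.sum((m_sa - m_a[None, :] - m_s[:, None] + m) ** 2)
    ss_bs = p * np.sum((m_sb - m_b[None, :] - m_s[:, None] + m) ** 2)
    resid = (
        y
        - m_ab[None, :, :]
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - m
    )
    ss_abs = np.sum(resid**2)

    flat = y.reshape(n, p * q)
    c_a = _helmert(p)
    c_b = _helmert(q)
    ones_q = np.ones((q, 1)) / q
    ones_p = np.ones((p, 1)) / p
    eps = {
        fa: _effect_epsilon(flat, np.kron(c_a, ones_q)),
        fb: _effect_epsilon(flat, np.kron(ones_p, c_b)),
        f"{fa} x {fb}": _effect_epsilon(flat, np.kron(c_a, c_b)),
    }

    total_within = float(np.sum((y - m_s[:, None, None]) ** 2))
    tol = 1e-12 * max(1.0, total_within)

    rows = []
    for name, ss_eff, ss_err, df1, df2 in (
        (fa, ss_a, ss_as, p - 1, (p - 1) * (n - 1)),
        (fb, ss_b, ss_bs, q - 1, (q - 1) * (n - 1)),
        (f"{fa} x {fb}", ss_ab, ss_abs, (p - 1) * (q - 1), (p - 1) * (q - 1) * (n - 1)),
    ):
        e = eps[name]
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        if ss_err <= tol:
            f_val, p_val, flagged = math.nan, math.nan, True
        else:
            f_val = ms_eff / ms_err
            p_val = float(stats.f.sf(f_val, e * df1, e * df2))
            flagged = False
        rows.append(
            {
                "effect": name,
                "ss_effect": ss_eff,
                "ss_error": ss_err,
                "df1": df1,
                "df2": df2,
                "epsilon_gg": e,
                "df1_adj": e * df1,
                "df2_adj": e * df2,
                "F": f_val,
                "p_adjusted": p_val,
                "partial_eta_sq": ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def paired_t(x: np.ndarray, y: np.ndarray, one_sided: bool = False) -> dict:
    """Paired t-test of x - y; one-sided mode tests mean(x - y) > 0."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
    else:
        t = mean / (sd / math.sqrt(n))
    if one_sided:
        p = float(stats.t.sf(t, n - 1))
    else:
        p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return {"estimate": mean, "t": t, "df": n - 1, "p": p, "n": n}


def simple_effects(
    fce_values: pd.DataFrame,
    value: str = "fce_rt_ms",
    one_sided: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition congruency tests plus pairwise condition comparisons.

    ``fce_values`` is the tidy subject x condition congruency-effect table
    from :func:`flankerlab.fce.compute_fce`.  The first frame tests each
    condition's mean effect against zero; the second compares effects
    between every pair of conditions with a paired t-test.
    """
    wide = fce_values.pivot(index="subject_id", columns="condition", values=value)
    if wide.isna().any().any():
        raise ValueError("missing subject x condition cells")
    conds = list(wide.columns)

    per_condition = []
    for c in conds:
        res = paired_t(wide[c].to_numpy(), np.zeros(len(wide)), one_sided=one_sided)
        res["condition"] = c
        per_condition.append(res)

    pairwise = []
    for i, c1 in enumerate(conds):
        for c2 in conds[i + 1 :]:
            res = paired_t(wide[c1].to_numpy(), wide[c2].to_numpy(), one_sided=one_sided)
            res["condition_a"] = c1
            res["condition_b"] = c2
            pairwise.append(res)
    return pd.DataFrame(per_condition), pd.DataFrame(pairwise)


def carryover_contrast(
    summaries: pd.DataFrame, confidence: float = 0.95
) -> dict:
    """Congruency-specific carry-over effect in the variable blocks.

    Per subject and congruency level, the carry-over effect is the median-RT
    difference between location-change and location-repeat trials
    (var_diff - var_same).  The congruency difference of those effects is
    tested with a paired t and reported with a confidence interval.
    Subjects lacking either variable cell are dropped with a warning.
    """
    import warnings

    sub = summaries[summaries["condition"].isin(["var_same", "var_diff"])]
    wide = sub.pivot_table(
        index="subject_id",
        columns=["congruency", "condition"],
        values="median_rt_ms",
        aggfunc="first",
    )
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        warnings.warn(f"excluding {dropped} subject(s) with incomplete carry-over cells")
    if len(complete) < 2:
        raise ValueError("need at least 2 complete subjects")

    carry = {}
    for cong in ("congruent", "incongruent"):
        carry[cong] = (
            complete[(cong, "var_diff")] - complete[(cong, "var_same")]
        ).to_numpy()

    diff = carry["incongruent"] - carry["congruent"]
    n = len(diff)
    res = paired_t(carry["incongruent"], carry["congruent"])
    se = diff.std(ddof=1) / math.sqrt(n) if n > 1 else math.nan
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
    return {
        "carryover_congruent_ms": float(carry["congruent"].mean()),
        "carryover_incongruent_ms": float(carry["incongruent"].mean()),
        "difference_ms": float(res["estimate"]),
        "ci_low_ms": float(res["estimate"] - tcrit * se),
        "ci_high_ms": float(res["estimate"] + tcrit * se),
        "t": res["t"],
        "df": res["df"],
        "p": res["p"],
        "n": n,
    }


def power(spec: PowerSpec) -> float:
    """Power of a one-df within-subject test at the spec's sample size.

    PAIRED_T: noncentral t with ncp = d * sqrt(n), df = n - 1, against the
    (two-sided by default) alpha critical value.  WITHIN_F: noncentral F
    with df = (1, n - 1) and ncp = n * f^2 where f^2 = eta / (1 - eta) for
    partial eta-squared ``eta``.
    """
    n, alpha = spec.n, spec.alpha
    if spec.test == PAIRED_T:
        ncp = spec.effect * math.sqrt(n)
        df = n - 1
        if spec.two_sided:
            tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
            return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
        tcrit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(tcrit, df, ncp))
    if spec.test == WITHIN_F:
        eta = spec.effect
        if eta >= 1.0:
            raise ValueError("partial eta-squared must be < 1")
        f2 = eta / (1.0 - eta)
        ncp = n * f2
        fcrit = stats.f.ppf(1.0 - alpha, 1, n - 1)
        return float(stats.ncf.sf(fcrit, 1, n - 1, ncp))
    raise ValueError(f"unknown test {spec.test!r}")
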