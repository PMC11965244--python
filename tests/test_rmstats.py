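import math

import numpy as np
import pandas as pd
import pytest

from conftest import flat_design

from flankerlab import preprocess, rmstats, simulate
from flankerlab.design import CONGRUENT, EXP3, INCONGRUENT
from flankerlab.rmstats import (
    PAIRED_T,
    WITHIN_F,
    PowerSpec,
    carryover_contrast,
    gg_epsilon,
    paired_t,
    power,
    rm_anova_2way,
    simple_effects,
)


def _tidy(y):
    """subjects x A x B array -> tidy frame."""
    n, p, q = y.shape
    rows = []
    for s in range(n):
        for a in range(p):
            for b in range(q):
                rows.append(
                    {"subject_id": s, "A": f"a{a}", "B": f"b{b}", "y": y[s, a, b]}
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_zero_condition_variation_flagged(self):
        rng = np.random.default_rng(0)
        y = np.repeat(rng.normal(size=(6, 1, 1)), 6, axis=1).reshape(6, 3, 2)
        out = rm_anova_2way(_tidy(y), dv="y", within=("A", "B"))
        # no condition signal and no condition noise: zero SS everywhere
        assert out["flagged"].all()
        assert np.allclose(out["ss_effect"], 0.0)

    def test_f_equals_t_squared_on_2x2(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(10, 2, 2))
        out = rm_anova_2way(_tidy(y), dv="y", within=("A", "B")).set_index("effect")
        # main effect of A == paired t on the B-averaged A contrast
        contrast = y.mean(axis=2)[:, 0] - y.mean(axis=2)[:, 1]
        t = contrast.mean() / (contrast.std(ddof=1) / np.sqrt(len(contrast)))
        assert out.loc["A", "F"] == pytest.approx(t**2)
        # interaction == paired t on the double difference
        dd = (y[:, 0, 0] - y[:, 0, 1]) - (y[:, 1, 0] - y[:, 1, 1])
        t_i = dd.mean() / (dd.std(ddof=1) / np.sqrt(len(dd)))
        assert out.loc["A x B", "F"] == pytest.approx(t_i**2)

    def test_ss_conservation(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(8, 4, 3))
        out = rm_anova_2way(_tidy(y), dv="y", within=("A", "B"))
        total_within = np.sum((y - y.mean(axis=(1, 2), keepdims=True)) ** 2)
        parts = out["ss_effect"].sum() + out["ss_error"].sum()
        assert parts == pytest.approx(total_within, rel=1e-8)

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        y = rng.normal(size=(9, 3, 2)) + np.arange(3)[None, :, None]
        df = _tidy(y)
        ours = rm_anova_2way(df, dv="y", within=("A", "B")).set_index("effect")
        theirs = pg.rm_anova(
            data=df, dv="y", within=["A", "B"], subject="subject_id", detailed=True
        ).set_index("Source")
        for our_key, pg_key in (("A", "A"), ("B", "B"), ("A x B", "A * B")):
            assert ours.loc[our_key, "ss_effect"] == pytest.approx(
                theirs.loc[pg_key, "SS"]
            )
            assert ours.loc[our_key, "F"] == pytest.approx(theirs.loc[pg_key, "F"])
            assert ours.loc[our_key, "epsilon_gg"] == pytest.approx(
                theirs.loc[pg_key, "eps"], abs=1e-9
            )
            assert ours.loc[our_key, "p_adjusted"] == pytest.approx(
                theirs.loc[pg_key, "p_GG_corr"], abs=1e-9
            )

    def test_projection_oracle_small(self):
        # brute-force via explicit marginal means, written with loops
        rng = np.random.default_rng(4)
        y = rng.normal(size=(5, 3, 2))
        out = rm_anova_2way(_tidy(y), dv="y", within=("A", "B")).set_index("effect")
        n, p, q = y.shape
        grand = y.mean()
        ss_a = 0.0
        for a in range(p):
            ss_a += n * q * (y[:, a, :].mean() - grand) ** 2
        ss_as = 0.0
        for s in range(n):
            for a in range(p):
                ss_as += q * (
                    y[s, a, :].mean() - y[:, a, :].mean() - y[s].mean() + grand
                ) ** 2
        f_a = (ss_a / (p - 1)) / (ss_as / ((p - 1) * (n - 1)))
        assert out.loc["A", "ss_effect"] == pytest.approx(ss_a)
        assert out.loc["A", "ss_error"] == pytest.approx(ss_as)
        assert out.loc["A", "F"] == pytest.approx(f_a)

    def test_adjusted_p_not_smaller_when_f_large(self):
        # deflating both df is conservative in the rejection region (F >= 1);
        # for tiny F the adjusted p can drop below the raw one, so only
        # signal-bearing effects are checked
        rng = np.random.default_rng(5)
        y = rng.normal(size=(12, 4, 2)) + np.linspace(0, 3, 4)[None, :, None]
        out = rm_anova_2way(_tidy(y), dv="y", within=("A", "B"))
        from scipy import stats

        for row in out.itertuples():
            if row.F >= 1.0:
                p_unadj = stats.f.sf(row.F, row.df1, row.df2)
                assert row.p_adjusted >= p_unadj - 1e-12

    def test_missing_cells_rejected(self):
        df = _tidy(np.random.default_rng(0).normal(size=(4, 2, 2)))
        with pytest.raises(ValueError):
            rm_anova_2way(df.iloc[:-1], dv="y", within=("A", "B"))


def _eigen_epsilon(cov):
    k = cov.shape[0]
    center = np.eye(k) - np.ones((k, k)) / k
    lam = np.linalg.eigvalsh(center @ cov @ center)
    lam = lam[lam > 1e-12]
    return lam.sum() ** 2 / ((k - 1) * np.sum(lam**2))


class TestGgEpsilon:
    def test_two_levels(self):
        assert gg_epsilon(np.array([[2.0, 0.3], [0.3, 1.0]])) == 1.0

    def test_compound_symmetry(self):
        k = 5
        cov = np.full((k, k), 0.4) + np.eye(k) * 1.6
        assert gg_epsilon(cov) == pytest.approx(1.0)

    def test_matches_eigenvalue_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = rng.normal(size=(12, 5))
            cov = a.T @ a / 11
            eps = gg_epsilon(cov)
            assert eps == pytest.approx(_eigen_epsilon(cov), abs=1e-9)
            assert 1 / 4 <= eps <= 1.0

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        data = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("wxyz"))
        ours = gg_epsilon(np.cov(data.to_numpy(), rowvar=False))
        theirs = float(pg.epsilon(data, correction="gg"))
        assert ours == pytest.approx(theirs, abs=1e-9)


class TestSimpleEffects:
    def _fce_frame(self, values):
        rows = []
        for s, by_cond in enumerate(values):
            for c, v in by_cond.items():
                rows.append({"subject_id": s, "condition": c, "fce_rt_ms": v})
        return pd.DataFrame(rows)

    def test_zero_effects(self):
        df = self._fce_frame([{"x": 0.0, "y": 0.0}] * 4)
        per_cond, pairwise = simple_effects(df)
        assert (per_cond["estimate"] == 0).all()
        assert (pairwise["estimate"] == 0).all()

    def test_matches_paired_t_oracle(self):
        df = self._fce_frame([{"x": 12.0, "y": 30.0}, {"x": 8.0, "y": 26.0}, {"x": 10.0, "y": 40.0}])
        per_cond, pairwise = simple_effects(df)
        x = np.array([12.0, 8.0, 10.0])
        t_x = x.mean() / (x.std(ddof=1) / np.sqrt(3))
        got = per_cond.set_index("condition").loc["x"]
        assert got["t"] == pytest.approx(t_x)
        d = x - np.array([30.0, 26.0, 40.0])
        t_xy = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert pairwise.iloc[0]["t"] == pytest.approx(t_xy)

    def test_one_sided_halves_p(self):
        df = self._fce_frame(
            [{"x": 12.0, "y": 1.0}, {"x": 8.0, "y": -1.0}, {"x": 10.0, "y": 0.5}]
        )
        two, _ = simple_effects(df, one_sided=False)
        one, _ = simple_effects(df, one_sided=True)
        x2 = two.set_index("condition").loc["x", "p"]
        x1 = one.set_index("condition").loc["x", "p"]
        assert x1 == pytest.approx(x2 / 2)


def _exp3_summaries(n_subjects, kappa_fce, kappa_rt=10.0, seed=0):
    from flankerlab import design, fce

    specs = design.build_exp3("ABBA", seed)
    cells = {
        "fixed": simulate.CellParams(40, 0, 0.02, 0.06),
        "variable": simulate.CellParams(55, 0, 0.02, 0.08),
    }
    params = simulate.GenParams(
        EXP3,
        simulate.Population(),
        cells,
        kappa_rt_ms=kappa_rt,
        kappa_fce_ms=kappa_fce,
        timeout_ms=1e9,
        rng_seed=seed,
    )
    table = simulate.simulate_experiment(specs, n_subjects, params, seed=seed)
    table = preprocess.classify_trials(table)
    table, _ = preprocess.label_carryover(table)
    return fce.summarize_conditions(table)


class TestCarryover:
    def test_null_effect(self):
        summaries = _exp3_summaries(20, kappa_fce=0.0, kappa_rt=0.0, seed=1)
        res = carryover_contrast(summaries)
        assert abs(res["difference_ms"]) < 8.0
        assert res["ci_low_ms"] < 0 < res["ci_high_ms"]

    def test_recovers_kappa(self):
        summaries = _exp3_summaries(60, kappa_fce=20.0, seed=2)
        res = carryover_contrast(summaries)
        assert res["difference_ms"] == pytest.approx(20.0, abs=6.0)
        assert res["p"] < 0.01

    def test_ci_coverage_under_null(self):
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            summaries = _exp3_summaries(10, kappa_fce=0.0, kappa_rt=0.0, seed=100 + rep)
            res = carryover_contrast(summaries)
            if res["ci_low_ms"] <= 0.0 <= res["ci_high_ms"]:
                hits += 1
        # nominal 95%: allow binomial slack at 60 replicates
        assert hits / n_rep >= 0.85


class TestPower:
    def test_zero_effect_gives_alpha(self):
        assert power(PowerSpec(PAIRED_T, 0.0, 20, alpha=0.05)) == pytest.approx(0.05)

    def test_reported_bounds(self):
        assert power(PowerSpec(PAIRED_T, 0.93, 23)) > 0.95
        assert power(PowerSpec(WITHIN_F, 0.61, 40)) > 0.95

    def test_monotone_in_n_and_effect(self):
        p_n = [power(PowerSpec(PAIRED_T, 0.5, n)) for n in (5, 10, 20, 40, 80)]
        assert np.all(np.diff(p_n) > 0)
        p_d = [power(PowerSpec(PAIRED_T, d, 20)) for d in (0.0, 0.2, 0.5, 0.8, 1.2)]
        assert np.all(np.diff(p_d) > 0)

    def test_continuity_at_zero(self):
        assert power(PowerSpec(PAIRED_T, 1e-9, 20)) == pytest.approx(0.05, abs=1e-6)

    def test_one_sided_exceeds_two_sided(self):
        two = power(PowerSpec(PAIRED_T, 0.5, 20, two_sided=True))
        one = power(PowerSpec(PAIRED_T, 0.5, 20, two_sided=False))
        assert one > two

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            PowerSpec(PAIRED_T, 0.5, 1)
        with pytest.raises(ValueError):
            PowerSpec(PAIRED_T, -0.5, 10)
        with pytest.raises(ValueError):
            power(PowerSpec(WITHIN_F, 1.0, 10))


class TestPairedT:
    def test_against_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 15))
        ours = paired_t(x, y)
        t, p = stats.ttest_rel(x, y)
        assert ours["t"] == pytest.approx(float(t))
        assert ours["p"] == pytest.approx(float(p))
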