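"""End-to-end driver: design -> simulate -> classify -> summarize -> infer.

``run_pipeline`` is deterministic given the config (the seed drives every
random draw) and produces a results bundle: tidy CSV tables plus a
machine-readable ``results.json`` and a run log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, design, deltaplot, fce, preprocess, rmstats, simulate
from .design import EXP1, EXP2A, EXP2B, EXP3
from .io import PipelineConfig, default_score_weights, validate_trials, write_trials

log = logging.getLogger("flankerlab")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def build_design(config: PipelineConfig) -> list[design.TrialSpec]:
    if config.experiment == EXP1:
        return design.build_exp1(config.seed)
    if config.experiment == EXP2A:
        return design.build_exp2("A", config.seed)
    if config.experiment == EXP2B:
        return design.build_exp2("B", config.seed)
    return design.build_exp3(
        config.counterbalance, config.seed, balanced_locations=config.balanced_locations
    )


def simulate_trials(config: PipelineConfig) -> pd.DataFrame:
    """Build the design and simulate responses for every subject."""
    specs = build_design(config)
    params = simulate.preset_canonical(config.experiment, seed=config.seed)
    if config.preset_overrides:
        params = _apply_overrides(params, config.preset_overrides)
    table = simulate.simulate_experiment(specs, config.n_subjects, params, seed=config.seed)
    return validate_trials(table)


def _apply_overrides(params: simulate.GenParams, overrides: dict) -> simulate.GenParams:
    import dataclasses

    cell_over = overrides.get("cells", {})
    cells = dict(params.cells)
    for key, kv in cell_over.items():
        cells[key] = dataclasses.replace(cells[key], **kv)
    top = {k: v for k, v in overrides.items() if k != "cells"}
    return dataclasses.replace(params, cells=cells, **top)


def analyze_trials(config: PipelineConfig, table: pd.DataFrame) -> dict:
    """Run the full analysis chain on a validated trial table."""
    results: dict = {}

    stage = "classify"
    try:
        table = preprocess.classify_trials(table, rt_cutoff_ms=config.rt_cutoff_ms)
        if config.experiment == EXP3:
            table, retained_fixed = preprocess.label_carryover(table)
            results["retained_fixed_per_subject"] = {
                str(k): int(v) for k, v in retained_fixed.items()
            }
        log.info("stage %s: %d rows", stage, len(table))

        stage = "scores"
        results["block_scores"] = _block_scores(config, table)

        stage = "summaries"
        summaries = fce.summarize_conditions(table)
        fce_values = fce.compute_fce(summaries)
        log.info("stage %s: %d summary cells", stage, len(summaries))

        stage = "within_subject_se"
        results["within_subject_se"] = _fce_error_bars(fce_values)

        stage = "anova"
        factor = {"EXP1": "soa", "EXP2A": "t_delta", "EXP2B": "t_delta", "EXP3": "location"}[
            config.experiment
        ]
        anova_er = rmstats.rm_anova_2way(
            summaries.rename(columns={"condition": factor}),
            dv="er",
            within=(factor, "congruency"),
        )
        anova_rt = rmstats.rm_anova_2way(
            summaries.rename(columns={"condition": factor}),
            dv="median_rt_ms",
            within=(factor, "congruency"),
        )

        stage = "simple_effects"
        per_cond, pairwise = rmstats.simple_effects(
            fce_values, one_sided=config.one_sided_simple_effects
        )

        stage = "delta_plots"
        delta_table, slope_tests, group_curves = _delta_analysis(config, table)

        results.update(
            {
                "anova_er": anova_er.to_dict(orient="records"),
                "anova_rt": anova_rt.to_dict(orient="records"),
                "simple_effects": per_cond.to_dict(orient="records"),
                "pairwise_fce": pairwise.to_dict(orient="records"),
                "slope_tests": slope_tests.to_dict(orient="records"),
                "group_delta": group_curves,
            }
        )

        if config.experiment == EXP3:
            stage = "carryover"
            results["carryover_contrast"] = rmstats.carryover_contrast(summaries)
            stage = "polynomial_contrasts"
            results["polynomial_contrasts"] = _poly_contrasts(delta_table)

        results["_tables"] = {
            "summaries": summaries,
            "fce": fce_values,
            "delta": delta_table,
            "anova_er": anova_er,
            "anova_rt": anova_rt,
            "slopes": slope_tests,
        }
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise PipelineError(stage, exc) from exc
    return results


def _block_scores(config: PipelineConfig, table: pd.DataFrame) -> list[dict]:
    weights = config.score_weights or default_score_weights(config.experiment)
    rows = []
    exp_trials = table[~table["is_practice"]]
    for (sid, block), g in exp_trials.groupby(["subject_id", "block_index"]):
        responded = g["rt_ms"].notna() & (g["response"] != "none")
        rts = g.loc[responded, "rt_ms"].astype(float)
        speed, accuracy, score = fce.composite_score(
            rts, n_total=len(g), n_correct=int(g["correct"].sum()), weights=weights
        )
        rows.append(
            {
                "subject_id": int(sid),
                "block_index": int(block),
                "speed": speed,
                "accuracy": accuracy,
                "score": score,
            }
        )
    return rows


def _fce_error_bars(fce_values: pd.DataFrame) -> dict:
    out = {}
    for col in ("fce_er", "fce_rt_ms"):
        wide = fce_values.pivot(index="subject_id", columns="condition", values=col)
        if wide.isna().any().any() or wide.shape[0] < 2 or wide.shape[1] < 2:
            continue
        se = fce.within_subject_se(wide.to_numpy())
        out[col] = {str(c): float(s) for c, s in zip(wide.columns, se)}
    return out


def _delta_analysis(config: PipelineConfig, table: pd.DataFrame):
    df = table[~table["is_practice"]].copy()
    df["condition"] = preprocess.analysis_condition_key(df)
    df = df[df["condition"].notna() & df["usable_for_rt"]]

    plots: list[deltaplot.DeltaPlot] = []
    skipped = 0
    for (sid, cond), g in df.groupby(["subject_id", "condition"]):
        c_rts = g.loc[g["congruency"] == design.CONGRUENT, "rt_ms"].astype(float)
        i_rts = g.loc[g["congruency"] == design.INCONGRUENT, "rt_ms"].astype(float)
        try:
            dp = deltaplot.subject_delta(
                c_rts, i_rts, subject_id=sid, condition=cond, min_trials=config.min_trials
            )
        except deltaplot.InsufficientTrialsError:
            skipped += 1
            continue
        deltaplot.fit_slope(dp)
        plots.append(dp)
    if skipped:
        log.warning("delta plots: skipped %d subject x condition cells", skipped)

    delta_rows = []
    for dp in plots:
        for lvl, x, y in zip(deltaplot.PERCENTILE_LEVELS, dp.bin_rt_ms, dp.fce_rt_ms):
            delta_rows.append(
                {
                    "subject_id": dp.subject_id,
                    "condition": dp.condition,
                    "percentile": lvl,
                    "bin_rt_ms": x,
                    "fce_rt_ms": y,
                    "slope": dp.slope,
                    "intercept_ms": dp.intercept_ms,
                }
            )
    delta_table = pd.DataFrame(delta_rows)

    slopes_by_cond = {
        cond: [dp.slope for dp in plots if dp.condition == cond]
        for cond in sorted({dp.condition for dp in plots})
    }
    slope_tests = deltaplot.group_slope_test(slopes_by_cond)

    group_curves = {}
    for cond in slopes_by_cond:
        cond_plots = [dp for dp in plots if dp.condition == cond]
        gx, gy = deltaplot.group_delta_plot(cond_plots)
        group_curves[str(cond)] = {"bin_rt_ms": gx.tolist(), "fce_rt_ms": gy.tolist()}
    return delta_table, slope_tests, group_curves


def _poly_contrasts(delta_table: pd.DataFrame) -> dict:
    out = {}
    for cond, g in delta_table.groupby("condition"):
        wide = g.pivot(index="subject_id", columns="percentile", values="fce_rt_ms")
        if wide.isna().any().any():
            continue
        res = deltaplot.polynomial_contrasts(wide.to_numpy())
        out[str(cond)] = res.to_dict(orient="records")
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Simulate, analyze, and write the results bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("flankerlab %s config=%s", __version__, config.digest())
        table = simulate_trials(config)
        log.info("simulated %d rows", len(table))
        write_trials(table, outdir / "trials.csv")
        results = analyze_trials(config, table)
    finally:
        log.removeHandler(handler)
        handler.close()

    tables = results.pop("_tables")
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    pd.DataFrame(results["block_scores"]).to_csv(outdir / "scores.csv", index=False)
    if config.make_plots and results.get("group_delta"):
        deltaplot.plot_group_delta(results["group_delta"], outdir / "delta_plots.png")

    payload = {
        "schema_version": 1,
        "package_version": __version__,
        "config": json.loads(config.to_json()),
        "config_digest": config.digest(),
        "results": _jsonable(results),
    }
    (outdir / "results.json").write_text(json.dumps(payload, sort_keys=True, indent=2))
    return payload


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if obj is pd.NA:
        return None
    return obj
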