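"""End-to-end pipeline: simulate -> label -> fit risk model -> disparities
-> microsimulation, with one master seed, per-stage derived seeds, CSV
artifacts and a manifest recording everything needed to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import disparities as disp
from . import labels as lab
from . import microsim as ms
from . import riskmodel as rm
from . import synthetic as syn
from .config import PipelineConfig, stage_seed

log = logging.getLogger("leadwater")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Run every stage and write all artifacts; returns the output directory.

    Artifacts: blocks.csv, tests.csv, survey.csv, block_labels.csv,
    draw_summary.csv, predictions.csv, model_report.txt, disparities.csv,
    microsim_summary.csv and manifest.json (config hash, stage seeds, file
    checksums).
    """
    config.validate()  # includes the slope-CI check, before any compute
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {stage: stage_seed(config.seed, stage)
             for stage in ("blocks", "tests", "survey", "model", "microsim")}
    log.info("pipeline start: seed=%d stage_seeds=%s", config.seed, seeds)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc

    blocks = stage("simulate", lambda: syn.generate_blocks(
        config.n_blocks, config.generator, seeds["blocks"]))
    tests = stage("simulate", lambda: syn.generate_tests(
        blocks, config.generator, seeds["tests"]))
    survey = stage("simulate", lambda: syn.generate_survey(
        blocks, config.generator, seeds["survey"]))
    blocks["tested"] = blocks["block_id"].isin(tests["block_id"])

    labels = stage("label", lambda: lab.label_blocks(
        tests, draw=config.risk.outcome_draw))
    summary = stage("label", lambda: lab.summarize_draws(tests))

    def _fit():
        if config.risk.unit == "tests":
            frame = rm.make_test_unit_frame(tests, blocks, config.risk.outcome_draw)
        else:
            frame = blocks.merge(labels[["block_id", "contaminated"]], on="block_id",
                                 how="inner")
        return rm.fit_risk_model(frame, config.risk, seeds["model"])

    fit = stage("fit-risk", _fit)
    predictions = stage("fit-risk", lambda: rm.predict_blocks(fit, blocks))

    disparity = stage("disparities", lambda: disp.disparity_table(
        blocks, labels, predictions, adjust_risk=config.disparities.adjust_risk,
        robust_se=config.disparities.robust_se))

    mc = config.microsim
    er = ms.ExposureResponse(
        slope_point=mc.slope_point, slope_ci_low=mc.slope_ci_low,
        slope_ci_high=mc.slope_ci_high, max_concentration_ppb=mc.top_code_ppb,
        exposure_days=mc.exposure_days)
    result = stage("microsim", lambda: ms.run_microsim(
        blocks, labels, predictions, fit.ppv, fit.npv, survey, er, tests,
        n_reps=mc.n_reps, seed=seeds["microsim"], region_level=mc.region_level,
        ppv_npv_counts=(fit.heldout_confusion
                        if mc.propagate_ppv_npv_uncertainty else None)))

    files = {
        "blocks.csv": blocks, "tests.csv": tests, "survey.csv": survey,
        "block_labels.csv": labels, "draw_summary.csv": summary,
        "predictions.csv": predictions, "disparities.csv": disparity,
        "microsim_summary.csv": result.summary,
    }
    files["microsim_table.csv"] = ms.format_summary(result.summary)
    for name, df in files.items():
        df.to_csv(out / name, index=False)

    report = [
        f"model: {fit.model_type} params={fit.params}",
        f"held-out AUROC: {fit.auroc_heldout:.4f}",
        f"threshold: {fit.threshold}",
        f"PPV: {fit.ppv:.4f}", f"NPV: {fit.npv:.4f}",
        "global importance (mean |contribution|):",
    ]
    try:
        attr = rm.feature_attributions(fit, blocks)
        for feat, value in rm.global_importance(attr).items():
            report.append(f"  {feat}: {value:.4f}")
    except rm.AttributionUnavailableError:
        report.append("  (unavailable for this model type)")
    (out / "model_report.txt").write_text("\n".join(report) + "\n")

    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": config.content_hash(),
        "files": {name: _sha256(out / name)
                  for name in list(files) + ["model_report.txt"]},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(config.to_yaml())
    log.info("pipeline done: %s", out)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# CSV schema validation

_SCHEMAS: dict[str, dict] = {
    "blocks.csv": {
        "required": ["block_id", "block_group_id", "tract_id", "community_area_id",
                     "population", "pop_asian", "pop_black", "pop_hispanic",
                     "pop_white", "n_children_under5", "n_children_5to9",
                     "n_buildings", "median_building_age"],
        "nonnegative": ["population", "pop_asian", "pop_black", "pop_hispanic",
                        "pop_white", "n_children_under5", "n_children_5to9",
                        "n_buildings", "median_building_age"],
    },
    "tests.csv": {
        "required": ["block_id", "draw1_ppb", "draw2_ppb", "draw3_ppb"],
        "nonnegative": ["draw1_ppb", "draw2_ppb", "draw3_ppb"],
    },
    "survey.csv": {
        "required": ["group_or_area", "p_unfiltered_tap", "p_filtered_tap",
                     "p_bottled", "p_other"],
        "proportions": ["p_unfiltered_tap", "p_filtered_tap", "p_bottled", "p_other"],
        "simplex": ["p_unfiltered_tap", "p_filtered_tap", "p_bottled", "p_other"],
    },
    "block_labels.csv": {
        "required": ["block_id", "n_tests", "n_detect", "contaminated"],
        "nonnegative": ["n_tests", "n_detect"],
    },
    "predictions.csv": {
        "required": ["block_id", "p_contaminated", "predicted_label"],
        "proportions": ["p_contaminated"],
    },
}


def validate_schemas(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Validate CSV artifacts against their expected schemas.

    ``paths`` maps schema names (e.g. ``"tests.csv"``) to file paths.
    Returns a report with one row per file: ``passed`` and, on failure,
    the reason and first offending row index.
    """
    rows = []
    for name, path in paths.items():
        schema = _SCHEMAS.get(name)
        row = {"file": name, "path": str(path), "passed": True,
               "reason": "", "first_bad_row": -1}
        if schema is None:
            row.update(passed=False, reason=f"no schema registered for {name!r}")
            rows.append(row)
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            row.update(passed=False, reason=f"unreadable: {exc}")
            rows.append(row)
            continue
        missing = [c for c in schema["required"] if c not in df.columns]
        if missing:
            row.update(passed=False, reason=f"missing columns {missing}")
            rows.append(row)
            continue
        for col in schema.get("nonnegative", []):
            bad = df.index[pd.to_numeric(df[col], errors="coerce") < 0]
            if len(bad):
                row.update(passed=False, reason=f"negative value in {col!r}",
                           first_bad_row=int(bad[0]))
                break
        else:
            for col in schema.get("proportions", []):
                v = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[(v < 0) | (v > 1)]
                if len(bad):
                    row.update(passed=False, reason=f"{col!r} outside [0, 1]",
                               first_bad_row=int(bad[0]))
                    break
            else:
                if "simplex" in schema:
                    total = df[schema["simplex"]].sum(axis=1)
                    bad = df.index[(total - 1.0).abs() > 1e-9]
                    if len(bad):
                        row.update(passed=False,
                                   reason="source proportions do not sum to 1",
                                   first_bad_row=int(bad[0]))
        rows.append(row)
    return pd.DataFrame(rows)
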