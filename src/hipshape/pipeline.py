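"""End-to-end orchestration: simulate -> align -> fit -> score -> outcomes -> associate.

``run_pipeline`` drives the whole analysis on a synthetic cohort and
writes a report bundle: aligned landmark scores, the serialized shape
model, +/-2 SD mode-shape outlines (SVG; dashed = +2 SD, solid = -2 SD),
the association battery results table, and a run log with versions,
seed, stage timings and row counts.  Outputs are pure functions of the
configuration and seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .association import bonferroni_threshold, default_battery, run_association_battery
from .model import PointDistributionModel, flag_outliers, score_shapes
from .procrustes import GeneralizedProcrustesAlignment
from .simulate import SimulationConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, with the analysis defaults.

    Thresholds carry the analysis conventions: Croft >= 2 (moderate
    RHOA, primary) and >= 3 (severe, sensitivity); osteophyte cut-offs
    grade >= 1 and >= 2; |score| > 4 SD flags images for review;
    operator accuracy <= 3 px; Bonferroni alpha 0.05 over 10 modes.
    """

    out_dir: str = "hipshape_run"
    n: int = 500
    seed: int = 0
    k_modes: int = 10
    croft_thresholds: tuple = (2, 3)
    osteophyte_grades: tuple = (1, 2)
    outlier_sd: float = 4.0
    qc_threshold_px: float = 3.0
    alpha: float = 0.05
    drop_flagged: bool = False
    gpa_tol: float = 1e-8
    gpa_max_iter: int = 100
    n_svg_modes: int = 4
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**payload)
        cfg.croft_thresholds = tuple(cfg.croft_thresholds)
        cfg.osteophyte_grades = tuple(cfg.osteophyte_grades)
        return cfg


def _draw_mode_svg(model: PointDistributionModel, segments: dict, mode: int,
                   path: Path) -> None:
    k = model.components_.shape[0]
    plus = model.inverse_transform(np.eye(k)[mode - 1] * 2.0).reshape(-1, 2)
    minus = model.inverse_transform(np.eye(k)[mode - 1] * -2.0).reshape(-1, 2)
    fig, ax = plt.subplots(figsize=(4, 4))
    for lo, hi in segments.values():
        ax.plot(minus[lo:hi, 0], minus[lo:hi, 1], "k-", lw=1.2)
        ax.plot(plus[lo:hi, 0], plus[lo:hi, 1], "k--", lw=1.2)
    ax.invert_yaxis()  # pixel frame: y increases downward
    ax.set_aspect("equal")
    ax.set_title(f"Mode {mode}: dashed +2 SD, solid -2 SD")
    ax.axis("off")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns paths and the results table.

    Stages: cohort simulation, generalized Procrustes alignment, shape
    model fit and scoring, outlier flagging, outcome construction, and
    the association battery.  Any stage error halts the run with a
    stage-named diagnostic; outputs written so far are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    t0 = time.perf_counter()

    def stage(name):
        log.append({"stage": name, "t": round(time.perf_counter() - t0, 3)})

    def fail(name, exc):
        log.append({"stage": name, "error": f"{type(exc).__name__}: {exc}"})
        (out / "run_log.json").write_text(json.dumps(_log_payload(), indent=1))
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    def _log_payload():
        from . import __version__ as pkg_version

        return {
            "hipshape_version": pkg_version,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "config": asdict(config),
            "events": log,
        }

    try:
        sim = SimulationConfig(n=config.n, seed=config.seed, **config.simulation)
        cohort = generate_cohort(sim)
        cohort.write(out / "cohort")
        stage("simulate")
        log.append({"stage": "simulate", "n_images": len(cohort.landmarks)})
    except Exception as exc:  # noqa: BLE001 - stage diagnostics
        fail("simulate", exc)

    try:
        gpa_est = GeneralizedProcrustesAlignment(
            tol=config.gpa_tol, max_iter=config.gpa_max_iter
        ).fit(cohort.landmarks)
        aligned = gpa_est.aligned_set_()
        stage("align")
        log.append({"stage": "align", "iterations": aligned.iterations,
                    "converged": bool(aligned.converged)})
    except Exception as exc:
        fail("align", exc)

    try:
        model = PointDistributionModel(n_modes=config.k_modes).fit(aligned)
        model.to_json(out / "model.json",
                      metadata={"seed": config.seed, "n_train": int(config.n)})
        scores = score_shapes(model, aligned)
        flagged = flag_outliers(scores, threshold=config.outlier_sd)
        scores_df = pd.DataFrame(
            [s.scores for s in scores],
            columns=[f"mode_{j + 1}" for j in range(config.k_modes)],
        )
        scores_df.insert(0, "image_id", [s.image_id for s in scores])
        if config.drop_flagged and flagged:
            drop = {f[0] for f in flagged}
            scores_df = scores_df[~scores_df["image_id"].isin(drop)]
        scores_df.to_csv(out / "scores.csv", index=False)
        pd.DataFrame(flagged, columns=["image_id", "mode", "score"]).to_csv(
            out / "flagged_outliers.csv", index=False
        )
        for j in range(1, min(config.n_svg_modes, config.k_modes) + 1):
            _draw_mode_svg(model, cohort.template.segments, j,
                           out / f"mode_{j}_shape.svg")
        stage("fit_score")
        log.append({"stage": "fit_score", "n_flagged": len(flagged),
                    "variance_explained_pct": round(model.variance_explained(), 2)})
    except Exception as exc:
        fail("fit_score", exc)

    try:
        outcomes_df = cohort.readings.merge(cohort.pain, on="image_id")
        outcomes_df.to_csv(out / "outcomes.csv", index=False)
        stage("outcomes")
    except Exception as exc:
        fail("outcomes", exc)

    try:
        battery = default_battery(
            croft_thresholds=config.croft_thresholds,
            osteophyte_grades=config.osteophyte_grades,
        )
        results = run_association_battery(
            scores_df, outcomes_df, cohort.covariates, battery=battery,
            n_modes=config.k_modes, alpha=config.alpha,
        )
        results.to_csv(out / "results.csv", index=False, float_format="%.10g")
        stage("associate")
        log.append({
            "stage": "associate", "n_rows": len(results),
            "bonferroni_p": bonferroni_threshold(config.alpha, config.k_modes),
            "n_significant": int(results["significant"].sum()),
        })
    except Exception as exc:
        fail("associate", exc)

    (out / "run_log.json").write_text(json.dumps(_log_payload(), indent=1))
    return {
        "out_dir": out,
        "results": results,
        "model": model,
        "scores": scores_df,
        "flagged": flagged,
        "aligned": aligned,
        "cohort": cohort,
        "paths": {
            "results": out / "results.csv",
            "model": out / "model.json",
            "scores": out / "scores.csv",
            "log": out / "run_log.json",
        },
    }
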