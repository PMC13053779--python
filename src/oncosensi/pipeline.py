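"""End-to-end pipeline: simulate -> quantify -> DRC -> Z-score -> index -> evaluate.

``run_pipeline`` executes the screening workflow on either a synthetic
plate + cohort or the packaged patient table, emitting per-stage CSVs and
a deterministic evaluation report (same config + seed => byte-identical
JSON).  Each stage validates its inputs and aborts with the stage name on
failure.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import arm, cohort_stats, dose_response, model as osmodel, synthetic
from . import evaluation, table1, viability
from .plate import PlateLayout

DOSE_LADDER = (0.0, 2.0, 4.0, 8.0)


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: str = "table1"          # 'table1', 'synthetic', or a CSV path
    model: str = "eq2_hpv"          # 'eq1' | 'eq2_hpv' | 'refit'
    cutoff: float = 0.0
    ridge_penalty: float = 0.5      # used by 'refit' on separation
    simulate_plate: bool = False
    plate_noise_sd: float = 0.0
    dose_noise_sd: float = 0.0
    quant_threshold: float = 20.0
    out_dir: "str | None" = None

    @classmethod
    def from_file(cls, path: "str | Path") -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage '{stage}' failed: {detail}")
        self.stage = stage


def _select_model(cfg: PipelineConfig, z: pd.DataFrame, labels: np.ndarray):
    if cfg.model == "eq1":
        return osmodel.PUBLISHED_MODEL
    if cfg.model == "eq2_hpv":
        return osmodel.PUBLISHED_MODEL_HPV
    if cfg.model == "refit":
        try:
            return osmodel.fit_logistic(z["z_growth_rate"], z["z_rt_auc"], labels)
        except osmodel.SeparationError:
            return osmodel.fit_logistic(
                z["z_growth_rate"], z["z_rt_auc"], labels,
                ridge_penalty=cfg.ridge_penalty,
            )
    raise StageError("score", f"unknown model selection {cfg.model!r}")


def image_stage(cfg: PipelineConfig, out: "Path | None") -> dict:
    """Simulated plate -> quantified areas -> per-dose DRC AUC.

    One synthetic patient plate: a 0/2/4/8 Gy column-group ladder is
    scheduled, delivered, imaged on days 1 and 5, and quantified; viability
    per dose is the day-5 pillar area as percent of the day-5 unirradiated
    mean, and the stage reports the trapezoid AUC from both the quantified
    and the ground-truth areas (identical in the noiseless case).
    """
    unit_time = arm.fit_unit_time(arm.ArmCalibration())
    schedule = arm.build_schedule(DOSE_LADDER, unit_time)
    rate = 60.0 / unit_time
    dose_map = arm.simulate_delivery(
        schedule, rate, noise_sd=cfg.dose_noise_sd, seed=cfg.seed,
    )
    spec = synthetic.SyntheticPlateSpec(noise_sd=cfg.plate_noise_sd, seed=cfg.seed)
    images, truth = synthetic.generate_plate_images(
        spec, dose_map, synthetic.SurvivalModelParams(), days=[1, 5],
        plate_id="synthetic", out_dir=out,
    )
    layout = spec.layout()
    qcfg = viability.QuantConfig(intensity_threshold=cfg.quant_threshold)

    def _auc_from_areas(area_by_pillar: np.ndarray) -> float:
        dose_cols = dose_map[0]  # dose constant within a column
        control = area_by_pillar[:, np.isclose(dose_cols, 0.0)].mean()
        viab = [
            float(np.mean([
                viability.normalize_viability(a, control)
                for a in area_by_pillar[:, np.isclose(dose_cols, d)].ravel()
            ]))
            for d in DOSE_LADDER
        ]
        return dose_response.auc_trapezoid(
            doses_gy=DOSE_LADDER, viability_pct=viab)

    quant5 = viability.pillar_areas(images[5], layout, qcfg)
    truth5 = (
        truth[truth["day"] == 5]
        .pivot(index="pillar_row", columns="pillar_col", values="true_area_px")
        .to_numpy()
    )
    quant1 = viability.pillar_areas(images[1], layout, qcfg)
    growth = viability.growth_rate(
        float(quant5[:, :6].sum()), float(quant1[:, :6].sum()))
    result = {
        "auc_quantified": _auc_from_areas(quant5),
        "auc_ground_truth": _auc_from_areas(truth5),
        "growth_rate_pct": growth,
        "total_schedule_time_s": schedule.total_time_s,
    }
    if out is not None:
        truth.to_csv(out / "plate_ground_truth.csv", index=False)
        pd.DataFrame({
            "row": np.repeat(np.arange(16), 24),
            "col": np.tile(np.arange(24), 16),
            "dose_gy": dose_map.ravel(),
        }).to_csv(out / "dose_map.csv", index=False)
    return result


def cohort_stage(cfg: PipelineConfig, out: "Path | None") -> dict:
    """Cohort -> frozen Z-scores -> OncoSensi index -> ROC / RFS report."""
    if cfg.cohort == "table1":
        cohort = table1.table1_fixture()
    elif cfg.cohort == "synthetic":
        cohort, _ = synthetic.generate_cohort(
            synthetic.SyntheticCohortSpec(n_patients=60, seed=cfg.seed))
    else:
        cohort = pd.read_csv(cfg.cohort)
    required = {"patient_id", "set", "hpv", "recur", "rt_auc", "growth_rate"}
    missing = required - set(cohort.columns)
    if missing:
        raise StageError("zscore", f"cohort is missing columns {sorted(missing)}")

    test = cohort[cohort["set"] == "test"].reset_index(drop=True)
    stats = cohort_stats.freeze_reference(test)
    z = cohort_stats.standardize_cohort(test, stats)
    labels = (test["recur"] == "yes").to_numpy().astype(int)
    if labels.sum() in (0, len(labels)):
        raise StageError("evaluate", "test set has a single outcome class")

    mdl = _select_model(cfg, z, labels)
    lp = osmodel.linear_predictor(
        mdl, z["z_growth_rate"], z["z_rt_auc"],
        z["z_hpv"] if mdl.uses_hpv else None,
    )
    lp = np.asarray(lp, dtype=float)
    index, (lp_mean, lp_sd) = osmodel.oncosensi_index(lp)
    group = osmodel.classify(index, cfg.cutoff)

    roc = evaluation.roc_auc(lp, labels)
    sens, spec = evaluation.sensitivity_specificity(index, labels, cfg.cutoff)
    times = test["rfs_days"].to_numpy(dtype=float)
    report = {
        "model": {
            "selection": cfg.model,
            "beta0": mdl.beta0,
            "beta_growth": mdl.beta_growth,
            "beta_auc": mdl.beta_auc,
            "beta_hpv": mdl.beta_hpv,
        },
        "index_reference": {"lp_mean": lp_mean, "lp_sd": lp_sd},
        "roc_auc": roc.auc,
        "sensitivity": sens,
        "specificity": spec,
    }
    masks = {"sensitive": group == "sensitive", "resistant": group == "resistant"}
    if all(m.any() for m in masks.values()):
        report["one_year_rfs_by_group"] = {
            name: evaluation.one_year_rfs(times[m], labels[m])
            for name, m in masks.items()
        }
        lr = evaluation.log_rank(
            times[masks["sensitive"]], labels[masks["sensitive"]],
            times[masks["resistant"]], labels[masks["resistant"]],
        )
        report["log_rank"] = {"chi_square": lr.chi_square, "p_value": lr.p_value}

    scores = pd.DataFrame({
        "patient_id": test["patient_id"],
        "lp": lp,
        "index": index,
        "label": group,
    })
    if out is not None:
        z.assign(patient_id=test["patient_id"]).to_csv(out / "zscores.csv", index=False)
        scores.to_csv(out / "scores.csv", index=False)
        stats.to_json(out / "reference_stats.json")
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages and write the report bundle."""
    out = None
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "config": asdict(cfg),
    }
    stages = []
    if cfg.simulate_plate:
        stages.append(("simulate", image_stage))
    stages.append(("evaluate", cohort_stage))
    for name, fn in stages:
        try:
            report[name] = fn(cfg, out)
        except StageError:
            raise
        except Exception as err:  # surface the failing stage
            raise StageError(name, str(err)) from err
    text = json.dumps(report, indent=2, sort_keys=True)
    if out is not None:
        (out / "report.json").write_text(text + "\n")
        (out / "run.log").write_text(
            f"oncosensi {__version__} seed={cfg.seed} config={cfg.digest()}\n"
        )
    return report
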