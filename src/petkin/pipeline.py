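"""End-to-end cohort analysis.

For each animal: fit the plasma input function, fit both compartment
models, run Logan and Patlak graphical analyses, and compute the SUV of
the late lesion uptake.  At cohort level: regress SUV, Vd and BP on the
CD25+ cell count, compare models by AIC, and derive the limit of
detection from the control-region binding potentials.

Any per-animal stage failure is recorded and the run continues for the
remaining animals (partial-results contract).  The pipeline is a pure
function of (cohort, config): rerunning with the same inputs produces
byte-identical report files.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .compartment import compare_models, fit_compartment_model
from .graphical import logan_analysis, patlak_analysis
from .input_function import fit_biexponential
from .quantify import limit_of_detection, linear_regression, suv
from .tac import CohortRecord

__all__ = ["AnalysisConfig", "PipelineReport", "run_pipeline", "write_report"]


@dataclass
class AnalysisConfig:
    """Tunable settings of the cohort analysis."""

    t_star_logan: float = 3.0  # min
    t_star_patlak: float = 15.0  # min
    weights: str | None = None  # None (uniform) or "durations"
    lod_multiplier: float = 2.0  # SDs above the control mean
    use_fitted_input: bool = True  # fit the biexponential to the plasma TAC
    suv_window_min: float = 45.0  # average lesion uptake from here to scan end
    seed: int = 0

    def __post_init__(self):
        if self.t_star_logan < 0 or self.t_star_patlak < 0:
            raise ValueError("delay times must be >= 0")
        if self.lod_multiplier <= 0:
            raise ValueError("lod_multiplier must be > 0")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineReport:
    per_animal: pd.DataFrame
    regressions: dict  # measure -> RegressionResult
    lod: object | None
    model_preference: dict
    errors: dict  # animal_id -> stage -> message
    log: list = field(default_factory=list)
    notices: list = field(default_factory=list)


def _late_mean_conc(lesion, window_start: float) -> float:
    keep = lesion.times >= window_start
    if not keep.any():
        keep = lesion.times >= lesion.times[-1]
    return float(lesion.values[keep].mean())


def run_pipeline(cohort: list[CohortRecord], config: AnalysisConfig | None = None) -> PipelineReport:
    """Run the full analysis over a cohort and collect a report bundle."""
    config = config or AnalysisConfig()
    rows, errors, control_bps = [], {}, []
    log = [f"config {config.digest()} seed {config.seed} n_animals {len(cohort)}"]
    for rec in cohort:
        row = {
            "animal_id": rec.animal_id,
            "cd25_cells_1e6": rec.cd25_cells,
            "dose_MBq": rec.injected_dose,
            "weight_g": rec.body_weight,
        }
        err = {}

        def stage(name, fn):
            try:
                out = fn()
                log.append(f"{rec.animal_id} {name} ok")
                return out
            except Exception as exc:  # per-animal failures must not stop the run
                err[name] = str(exc)
                log.append(f"{rec.animal_id} {name} FAILED: {exc}")
                return None

        input_fn = rec.plasma
        if config.use_fitted_input:
            ifit = stage("fit_input", lambda: fit_biexponential(rec.plasma))
            if ifit is not None:
                input_fn = ifit.params
                row.update(
                    {f"input_{k}": v for k, v in ifit.params.to_dict().items()}
                )

        f1 = stage(
            "fit_1tc",
            lambda: fit_compartment_model(
                rec.lesion, input_fn, "1TCMR", weights=config.weights
            ),
        )
        f2 = stage(
            "fit_2tc",
            lambda: fit_compartment_model(
                rec.lesion, input_fn, "2TCMR", weights=config.weights
            ),
        )
        if f1 is not None:
            row.update({"vd_1tc": f1.vd, "aic_1tc": f1.aic, "rss_1tc": f1.rss})
        if f2 is not None:
            row.update(
                {
                    "K1": f2.params.k1, "k2": f2.params.k2,
                    "k3": f2.params.k3, "k4": f2.params.k4,
                    "bp": f2.bp, "vd_2tc": f2.vd,
                    "aic_2tc": f2.aic, "rss_2tc": f2.rss,
                }
            )
        if f1 is not None and f2 is not None:
            cmpres = stage("compare_models", lambda: compare_models(f1, f2))
            if cmpres is not None:
                row["preferred_model"] = cmpres.preferred
                row["delta_aic"] = cmpres.delta_aic

        lg = stage(
            "logan",
            lambda: logan_analysis(rec.lesion, input_fn, t_star=config.t_star_logan),
        )
        if lg is not None:
            row.update({"logan_vd": lg.slope, "logan_r2": lg.r_squared})
        pk = stage(
            "patlak",
            lambda: patlak_analysis(rec.lesion, input_fn, t_star=config.t_star_patlak),
        )
        if pk is not None:
            row.update({"patlak_ki": pk.slope, "patlak_r2": pk.r_squared})

        sv = stage(
            "suv",
            lambda: suv(
                # kBq/ml -> MBq/g assuming unit tissue density (1 g/ml)
                _late_mean_conc(rec.lesion, config.suv_window_min) * 1e-3,
                rec.injected_dose,
                rec.body_weight,
            ),
        )
        if sv is not None:
            row["suv"] = sv

        if rec.control is not None:
            cf = stage(
                "fit_control",
                lambda: fit_compartment_model(
                    rec.control, input_fn, "2TCMR", weights=config.weights
                ),
            )
            if cf is not None:
                row["control_bp"] = cf.bp
                control_bps.append(cf.bp)

        rows.append(row)
        if err:
            errors[rec.animal_id] = err

    per_animal = pd.DataFrame(rows)
    notices = []

    regressions = {}
    for measure in ("suv", "vd_2tc", "logan_vd", "bp"):
        if measure not in per_animal.columns:
            continue
        sub = per_animal.dropna(subset=[measure])
        if len(sub) < 3 or sub["cd25_cells_1e6"].nunique() < 2:
            notices.append(f"regression of {measure} skipped: fewer than 3 usable animals")
            continue
        regressions[measure] = linear_regression(
            sub["cd25_cells_1e6"].to_numpy(), sub[measure].to_numpy()
        )

    model_preference = {}
    if "preferred_model" in per_animal.columns:
        counts = per_animal["preferred_model"].value_counts()
        model_preference = {str(k): int(v) for k, v in counts.items()}

    lod = None
    if len(control_bps) >= 2 and "bp" in regressions:
        try:
            lod = limit_of_detection(
                control_bps, regressions["bp"], multiplier=config.lod_multiplier
            )
        except ValueError as exc:
            notices.append(f"LOD skipped: {exc}")
    else:
        notices.append("LOD skipped: needs >= 2 control BPs and a BP regression")

    return PipelineReport(
        per_animal=per_animal,
        regressions=regressions,
        lod=lod,
        model_preference=model_preference,
        errors=errors,
        log=log,
        notices=notices,
    )


def write_report(report: PipelineReport, directory) -> None:
    """Serialize the report bundle: per-animal CSV, regressions CSV, LOD
    block, run log, and a human-readable summary."""
    os.makedirs(directory, exist_ok=True)
    report.per_animal.to_csv(
        os.path.join(directory, "per_animal.csv"), index=False, float_format="%.10g"
    )
    reg_rows = [
        {"measure": m, **r.to_dict()} for m, r in report.regressions.items()
    ]
    pd.DataFrame(reg_rows).to_csv(
        os.path.join(directory, "regressions.csv"), index=False, float_format="%.10g"
    )
    with open(os.path.join(directory, "run.log"), "w") as fh:
        fh.write("\n".join(report.log) + "\n")
    lines = ["cohort analysis summary", "======================="]
    for m, r in report.regressions.items():
        lines.append(
            f"{m} vs cells: slope={r.slope:.4g} intercept={r.intercept:.4g} "
            f"R2={r.r_squared:.3f} p={r.p_value:.3g} "
            f"{'significant' if r.significant else 'not significant'}"
        )
    if report.model_preference:
        lines.append(f"model preference (AIC): {report.model_preference}")
    if report.lod is not None:
        lod = report.lod
        lines.append(
            f"LOD: control BP {lod.control_mean_bp:.2f} +/- {lod.control_sd_bp:.2f} "
            f"-> BP {lod.lod_bp:.2f} -> ~{lod.min_detectable_cells:,.0f} cells"
        )
    for n in report.notices:
        lines.append(f"notice: {n}")
    for animal, err in report.errors.items():
        for stage_name, msg in err.items():
            lines.append(f"error: {animal} {stage_name}: {msg}")
    with open(os.path.join(directory, "summary.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
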