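"""Pipeline orchestration and report rendering.

``run_pipeline`` chains generate -> nca -> be -> fit -> simulate, persisting
every intermediate artifact (long CSV for concentrations, per-subject CSV
for NCA, JSON for model parameters and BE results) so each step's output is
re-readable by the step that consumes it.  Human-readable tables mirror the
conventional clinical-PK report layout: arm summaries as "mean +/- CV%" with
median (range) for Tmax, and a bioequivalence table with geometric LS means,
intrasubject CV%, and the ratio with its 90% CI, flagged when inside the
0.8-1.25 limits.

Rounding happens only at render time; persisted artifacts carry full
precision.  Logs go to stderr, data to files/stdout.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import bioequivalence as be
from . import compartmental as comp
from . import nca as nca_mod
from . import study_data, synthetic

__all__ = [
    "PipelineConfig",
    "PipelineStepError",
    "run_pipeline",
    "render_arm_summary_table",
    "render_be_table",
    "render_simulation_report",
    "nca_table",
]

logger = logging.getLogger("pkbridge")

STEP_ORDER = ("generate", "nca", "be", "fit", "simulate")

#: Exposure metrics analysed for bioequivalence by default.
BE_METRICS = ("cmax", "auc_last", "dn_cmax", "dn_auc_last")


class PipelineStepError(RuntimeError):
    def __init__(self, step: str, message: str):
        super().__init__(f"step '{step}' failed: {message}")
        self.step = step


@dataclass
class PipelineConfig:
    """What to run and where artifacts live.

    ``paths`` keys: ``out_dir`` (always), ``study_csv``/``design_config``
    (inputs when 'generate' is not among the steps), ``params_json`` (input
    for 'simulate' when 'fit' is not run).  ``options``: ``study`` label,
    ``seed``, ``n_subjects`` for the generator; ``contrasts`` (list of
    (test, reference)) and ``metrics`` for BE; ``fit_treatment``, ``dose``,
    ``tau``, ``n_doses`` for fit/simulate.
    """

    steps: tuple[str, ...]
    paths: dict[str, str] = field(default_factory=dict)
    options: dict[str, Any] = field(default_factory=dict)
    rounding: int = 3
    log_level: str = "info"

    def __post_init__(self) -> None:
        unknown = [s for s in self.steps if s not in STEP_ORDER]
        if unknown:
            raise ValueError(f"unknown step(s): {unknown}")
        order = [STEP_ORDER.index(s) for s in self.steps]
        if order != sorted(order):
            raise ValueError("steps must respect the order generate < nca < be < fit < simulate")
        if "out_dir" not in self.paths:
            raise ValueError("paths.out_dir is required")


def _fmt(x: float | None, nd: int) -> str:
    return "" if x is None or (isinstance(x, float) and not np.isfinite(x)) else f"{x:.{nd}f}"


def render_arm_summary_table(
    summaries: dict[str, dict[str, nca_mod.ArmSummary]], rounding: int = 2
) -> str:
    """Arm-summary table: one row per metric, one column per treatment.

    Values render as "mean +/- CV%"; Tmax additionally as "median (min-max)".
    """
    arms = list(summaries)
    rows = []
    metrics = sorted({m for a in summaries.values() for m in a}, key=str)
    for m in metrics:
        row: dict[str, str] = {"metric": m}
        for arm in arms:
            s = summaries[arm].get(m)
            if s is None or s.n == 0:
                row[arm] = ""
            elif m == "tmax":
                row[arm] = (
                    f"{_fmt(s.mean, rounding)} ± {_fmt(s.cv_pct, 1)}%; "
                    f"median {_fmt(s.median, rounding)} ({_fmt(s.min, rounding)}-{_fmt(s.max, rounding)})"
                )
            else:
                row[arm] = f"{_fmt(s.mean, rounding)} ± {_fmt(s.cv_pct, 1)}%"
        rows.append(row)
    return pd.DataFrame(rows).to_string(index=False)


def render_be_table(results: Sequence[be.BEResult], rounding: int = 3) -> pd.DataFrame:
    """Bioequivalence table: geometric LS means, CV%, ratio with 90% CI.

    Ratio and CI are rounded to ``rounding`` decimals; rows inside the
    0.8-1.25 limits are flagged with '*' (footnote convention).
    """
    rows = []
    for r in results:
        nd = rounding
        rows.append(
            {
                "metric": r.metric or "",
                "test": r.test,
                "reference": r.reference,
                "gls_mean_test": round(r.gls_mean_test, 6),
                "gls_mean_reference": round(r.gls_mean_reference, 6),
                "intra_cv_pct": round(r.intra_cv_pct, 2),
                "ratio_90ci": f"{r.ratio:.{nd}f} ({r.ci90_low:.{nd}f}–{r.ci90_high:.{nd}f})"
                + ("*" if r.bioequivalent else ""),
            }
        )
    return pd.DataFrame(rows)


def render_simulation_report(
    single: dict[str, float], steady: dict[str, float], sim: comp.SimulationResult, rounding: int = 2
) -> str:
    lines = [
        "Multiple-dose simulation",
        f"  Cmax single dose : {single['cmax']:.{rounding}f} ng/mL",
        f"  Cmax steady state: {steady['cmax']:.{rounding}f} ng/mL",
        f"  Cmin single dose : {single['cmin']:.{rounding}f} ng/mL",
        f"  Cmin steady state: {steady['cmin']:.{rounding}f} ng/mL",
        f"  accumulation ratio Cmax: {sim.r_cmax:.{rounding}f}",
        f"  accumulation ratio Cmin: {sim.r_cmin:.{rounding}f}",
        f"  steady state reached at dose {sim.n_to_steady_state}",
    ]
    return "\n".join(lines)


def nca_table(
    study: study_data.CrossoverStudy, selection: nca_mod.LambdaZSelection | None = None
) -> pd.DataFrame:
    """Per-profile NCA results for a whole study as a DataFrame."""
    rows = []
    for p in study.profiles:
        dose = study.treatments[p.treatment].dose_mg
        rows.append(nca_mod.run_nca(p, dose_mg=dose, selection=selection).to_dict())
    return pd.DataFrame(rows)


def _design_schema(study: study_data.CrossoverStudy) -> dict:
    return {
        "design": study.design,
        "lloq": study.profiles[0].lloq if study.profiles else study_data.DEFAULT_LLOQ,
        "treatments": {
            c: {
                "dose_mg": r.dose_mg,
                "formulation": r.formulation,
                "interval_tau_h": r.interval_tau_h,
                "n_doses": r.n_doses,
                "admin_clock_time": r.admin_clock_time,
            }
            for c, r in study.treatments.items()
        },
        "sampling_schedule": {c: list(s) for c, s in study.sampling_schedule.items()},
    }


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the configured steps in order; return artifact paths.

    On failure a :class:`PipelineStepError` naming the step is raised;
    artifacts written by earlier steps are retained.
    """
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.paths["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    opts = config.options
    artifacts: dict[str, Path] = {}
    study: study_data.CrossoverStudy | None = None
    nca_df: pd.DataFrame | None = None
    fit_params: comp.OneCompartmentParams | None = None

    for step in config.steps:
        logger.info("running step %s", step)
        try:
            if step == "generate":
                cfg = synthetic.default_config(
                    opts.get("study", "dose_proportionality"),
                    n_subjects=opts.get("n_subjects"),
                    seed=int(opts.get("seed", 0)),
                )
                study = synthetic.generate_study(cfg)
                artifacts["study_csv"] = out / "study.csv"
                study_data.write_study(study, artifacts["study_csv"])
                artifacts["design_yaml"] = out / "design.yaml"
                import yaml

                artifacts["design_yaml"].write_text(yaml.safe_dump(_design_schema(study)))
            elif step == "nca":
                if study is None:
                    study = study_data.read_study(
                        config.paths["study_csv"], config.paths.get("design_config")
                    )
                nca_df = nca_table(study)
                artifacts["nca_csv"] = out / "nca_results.csv"
                nca_df.to_csv(artifacts["nca_csv"], index=False)
                summaries = {
                    t: {
                        m: nca_mod.summarize_arm(
                            list(nca_df[nca_df.treatment == t][m]), m
                        )
                        for m in ("cmax", "tmax", "auc_last", "auc_inf", "dn_cmax",
                                  "dn_auc_last", "t_half", "lambda_z", "early_fraction")
                    }
                    for t in sorted(nca_df.treatment.unique())
                }
                artifacts["arm_summary_txt"] = out / "arm_summary.txt"
                artifacts["arm_summary_txt"].write_text(
                    render_arm_summary_table(summaries) + "\n"
                )
            elif step == "be":
                if nca_df is None:
                    nca_df = pd.read_csv(config.paths["nca_csv"])
                if study is None:
                    study = study_data.read_study(
                        config.paths["study_csv"], config.paths.get("design_config")
                    )
                contrasts = opts.get("contrasts") or _default_contrasts(study)
                metrics = opts.get("metrics", BE_METRICS)
                results = []
                for metric in metrics:
                    if nca_df[metric].isna().all():
                        continue
                    vals = nca_df.rename(columns={"subject_id": "subject"})[
                        ["subject", "treatment", metric]
                    ].rename(columns={metric: "value"})
                    for test, ref in contrasts:
                        results.append(
                            be.fit_crossover_model(study, vals, (test, ref), metric=metric)
                        )
                artifacts["be_json"] = out / "be_results.json"
                artifacts["be_json"].write_text(
                    json.dumps([r.__dict__ for r in results], indent=2)
                )
                table = render_be_table(results, config.rounding)
                artifacts["be_table_csv"] = out / "be_table.csv"
                table.to_csv(artifacts["be_table_csv"], index=False)
                print(table.to_string(index=False))
            elif step == "fit":
                if study is None:
                    study = study_data.read_study(
                        config.paths["study_csv"], config.paths.get("design_config")
                    )
                code = opts.get("fit_treatment") or sorted(study.treatments)[0]
                profs = study.profiles_for(code)
                if not profs:
                    raise ValueError(f"no profiles for treatment {code!r}")
                times = np.asarray(profs[0].times)
                mean_conc = np.mean([p.conc_array for p in profs], axis=0)
                dose = study.treatments[code].dose_mg
                fit = comp.fit_mean_profile(times, mean_conc, dose)
                fit_params = fit.params
                artifacts["params_json"] = out / "fit_params.json"
                artifacts["params_json"].write_text(
                    json.dumps(
                        {
                            "ka": fit.params.ka,
                            "ke": fit.params.ke,
                            "tlag": fit.params.tlag,
                            "scale": fit.params.scale,
                            "rss": fit.rss,
                            "treatment": code,
                            "dose_mg": dose,
                        },
                        indent=2,
                    )
                )
            elif step == "simulate":
                if fit_params is None:
                    pj = json.loads(Path(config.paths["params_json"]).read_text())
                    fit_params = comp.OneCompartmentParams(
                        ka=pj["ka"], ke=pj["ke"], tlag=pj["tlag"], scale=pj["scale"]
                    )
                    default_dose = pj.get("dose_mg", 100.0)
                else:
                    default_dose = opts.get("dose", 100.0)
                regimen = study_data.DoseRegimen(
                    dose_mg=float(opts.get("dose", default_dose)),
                    formulation="delayed_extended",
                    interval_tau_h=float(opts.get("tau", 24.0)),
                    n_doses=int(opts.get("n_doses", 20)),
                )
                sim = comp.simulate_regimen(fit_params, regimen)
                conc_df = pd.DataFrame({"time_h": sim.times, "conc_ng_ml": sim.concentrations})
                artifacts["simulation_csv"] = out / "simulation.csv"
                conc_df.to_csv(artifacts["simulation_csv"], index=False)
                report = render_simulation_report(
                    {"cmax": sim.cmax_per_dose[0], "cmin": sim.cmin_per_dose[0]},
                    {"cmax": sim.cmax_per_dose[-1], "cmin": sim.cmin_per_dose[-1]},
                    sim,
                )
                artifacts["simulation_report_txt"] = out / "simulation_report.txt"
                artifacts["simulation_report_txt"].write_text(report + "\n")
                acc = {
                    "r_cmax": sim.r_cmax,
                    "r_cmin": sim.r_cmin,
                    "n_to_steady_state": sim.n_to_steady_state,
                    "cmax_single": float(sim.cmax_per_dose[0]),
                    "cmax_ss": float(sim.cmax_per_dose[-1]),
                    "cmin_single": float(sim.cmin_per_dose[0]),
                    "cmin_ss": float(sim.cmin_per_dose[-1]),
                }
                artifacts["accumulation_json"] = out / "accumulation.json"
                artifacts["accumulation_json"].write_text(json.dumps(acc, indent=2))
                print(report)
        except PipelineStepError:
            raise
        except Exception as exc:
            logger.error("step %s failed: %s", step, exc)
            raise PipelineStepError(step, str(exc)) from exc
    return artifacts


def _default_contrasts(study: study_data.CrossoverStudy) -> list[tuple[str, str]]:
    codes = sorted(study.treatments)
    if len(codes) == 2:
        return [(codes[0], codes[1])]
    import itertools

    return [(a, b) for a, b in itertools.combinations(codes, 2)]
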