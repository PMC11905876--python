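"""End-to-end analysis pipeline: simulate, filter, fit, select, diagnose, apply.

One master seed drives every stage through ``numpy.random.SeedSequence``
stream-splitting, so each stage is independently reproducible and a rerun
with the same configuration is byte-identical.  Every persisted artifact
embeds the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .cohort import CohortConfig, CovariateDistributions, simulate_cohort
from .covariates import CovariateEffect, PopulationModel, REFERENCE_AGE_Y, REFERENCE_WEIGHT_KG
from .dataset import apply_m1_filter, disposition_summary, write_dataset
from .estimation import FitResult, backward_eliminate, fit, forward_select
from .forest import Regimen, forest_table, renal_exposure_summary, smoothed_bootstrap
from .vpc import simulate_replicates, vpc_summary

__all__ = ["RunConfig", "run_all", "default_candidates"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 1
    out_dir: str = "certepk_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    covariate_dists: CovariateDistributions = field(default_factory=CovariateDistributions)
    n_vpc: int = 500
    n_bootstrap: int = 1000
    run_selection: bool = True
    selection_maxiter: int = 200

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where results land is not part of the science
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_candidates() -> list:
    """Covariate effects screened during stepwise selection.

    Weight and age power effects on the main structural parameters, sex as
    a proportional effect, and the renal split of clearance; the age-on-CL
    power effect is included so the intermediate model of the development
    path is reachable even though the final model drops it.
    """
    w, a = REFERENCE_WEIGHT_KG, REFERENCE_AGE_Y
    return [
        CovariateEffect("vc", "weight", "power", "wt_vc", w),
        CovariateEffect("vp", "weight", "power", "wt_vp", w),
        CovariateEffect("cl", "weight", "power", "wt_cl", w),
        CovariateEffect("cl", "age", "power", "age_cl", a),
        CovariateEffect("cl", "sex", "proportional", "sex_cl", 1.0),
        CovariateEffect("cl", "bcrcl", "linear_renal", ""),
    ]


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.digest(), "seed": config.seed}


def _write_json(path: Path, payload: dict, config: RunConfig):
    payload = {**_stamp(config), **payload}
    path.write_text(json.dumps(payload, indent=2, default=_jsonable))
    return path


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def _write_table(path: Path, df: pd.DataFrame, config: RunConfig):
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.digest()} seed={config.seed}\n")
        df.to_csv(fh, index=False, float_format="%.10g")
    return path


def run_all(config: RunConfig) -> dict:
    """Execute every stage; earlier artifacts survive later failures.

    Returns a report dict with per-stage status, the OFV trace, the final
    parameter table, VPC containment and the forest table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(("cohort", "vpc", "bootstrap"), ss.spawn(3))}
    report = {**_stamp(config), "stages": {}, "artifacts": {}}
    truth = reference.final_model()

    def stage(name, func):
        t0 = time.time()
        try:
            result = func()
            report["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
            return result
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            logger.exception("stage %r failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            return None

    # --- simulate ---------------------------------------------------------
    def _simulate():
        ds, truth_info = simulate_cohort(
            truth, config.cohort, config.covariate_dists, seed=seeds["cohort"]
        )
        write_dataset(ds, out / "simulated_dataset.csv")
        _write_json(out / "simulation_truth.json", truth_info, config)
        return ds

    ds = stage("simulate", _simulate)
    if ds is None:
        _write_json(out / "report.json", report, config)
        return report

    # --- M1 filter --------------------------------------------------------
    def _filter():
        filtered, n_excluded = apply_m1_filter(ds)
        _write_table(out / "disposition.csv", disposition_summary(ds), config)
        report["n_blq_excluded"] = n_excluded
        return filtered

    analysis_ds = stage("m1_filter", _filter)
    if analysis_ds is None:
        _write_json(out / "report.json", report, config)
        return report

    # --- fit the structural model (reference covariate structure) ---------
    def _fit():
        fr = fit(analysis_ds, truth)
        _write_json(out / "fit.json", fr.to_dict(), config)
        _write_table(out / "parameter_table.csv", fr.parameter_table(), config)
        return fr

    fit_result = stage("fit", _fit)

    # --- stepwise covariate selection --------------------------------------
    if config.run_selection:

        def _select():
            fwd = forward_select(
                analysis_ds,
                reference.base_model(),
                default_candidates(),
                maxiter=config.selection_maxiter,
            )
            bwd = backward_eliminate(
                analysis_ds, fwd.final_model, maxiter=config.selection_maxiter
            )
            trace = {"forward": fwd.steps, "backward": bwd.steps}
            _write_json(out / "selection_trace.json", trace, config)
            report["selected_effects"] = [
                f"{e.covariate}:{e.form}->{e.parameter}"
                for e in bwd.final_model.covariate_effects
            ]
            return bwd

        stage("select", _select)

    # --- VPC ---------------------------------------------------------------
    if config.n_vpc > 0 and fit_result is not None:

        def _vpc():
            reps = simulate_replicates(
                analysis_ds, fit_result, n_rep=config.n_vpc, seed=seeds["vpc"]
            )
            res = vpc_summary(analysis_ds, reps)
            _write_table(out / "vpc.csv", res.table, config)
            report["vpc_containment"] = res.containment_fraction
            return res

        stage("vpc", _vpc)
    else:
        report["stages"]["vpc"] = {"status": "skipped"}

    # --- forest + renal exposure ------------------------------------------
    if fit_result is not None:

        def _forest():
            source = (
                fit_result
                if fit_result.covariance is not None
                else reference.published_bootstrap_input()
            )
            try:
                draws = smoothed_bootstrap(source, n=config.n_bootstrap, seed=seeds["bootstrap"])
            except RuntimeError:
                # a sparse fit can report a covariance too wide for positive
                # parameters; fall back to the published parameter table
                logger.warning("fit covariance implausible; forest uses published estimates")
                draws = smoothed_bootstrap(
                    reference.published_bootstrap_input(),
                    n=config.n_bootstrap,
                    seed=seeds["bootstrap"],
                )
            tab = forest_table(draws, regimen=Regimen())
            _write_table(out / "forest.csv", tab, config)
            return tab

        stage("forest", _forest)

        def _renal():
            tab = renal_exposure_summary(analysis_ds, fit_result)
            tab = tab.assign(outliers=tab["outliers"].map(lambda v: ";".join(f"{x:.6g}" for x in v)))
            _write_table(out / "exposure_by_renal.csv", tab, config)
            return tab

        stage("exposure_by_renal", _renal)

    if fit_result is not None:
        report["ofv"] = fit_result.ofv
        report["condition_number"] = fit_result.condition_number
    _write_json(out / "report.json", report, config)
    return report
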