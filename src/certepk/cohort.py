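"""Synthetic trial cohorts emulating the certepetide first-in-human design.

The generator reproduces the study conditions: 31 subjects across rising
dose levels 0.2/0.8/1.6/3.2 mg/kg given as 1-minute IV infusions, three PK
occasions per subject (monotherapy run-in and day 1 of two chemotherapy
cycles, at least 7 days apart), samples at predose and 3, 15, 30 min and
1, 3, 6 h after the end of the infusion, and an assay LLOQ of 50 ng/mL.

Baseline covariates match the published summary: weight median 73.7 kg
(54.0-121), age median 62.1 y (42.6-79.3), 64.5% male, creatinine clearance
median ~96.8 mL/min (48.2-172).  Serum creatinine is the sampled primitive;
CrCL is always derived through Cockcroft-Gault so the strong mechanistic
correlation of CrCL with age and weight arises naturally.

Observations are simulated from a :class:`~certepk.covariates.PopulationModel`
with log-normal inter-individual random effects drawn once per subject and
combined proportional + additive residual error per sample
(``DV = IPRED * (1 + eps1) + eps2``); negative draws are truncated at zero
and flagged below quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .covariates import PopulationModel, RandomEffects, individual_params
from .dataset import (
    DEFAULT_INFUSION_DURATION,
    DEFAULT_LLOQ,
    DoseEvent,
    ObservationRecord,
    PKDataset,
    SubjectCovariates,
)
from .twocomp import conc_profile

__all__ = [
    "CohortConfig",
    "CovariateDistributions",
    "sample_covariates",
    "build_design",
    "simulate_observations",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Trial-design knobs; defaults are the study conditions."""

    n_subjects: int = 31
    dose_levels: tuple = (0.2, 0.8, 1.6, 3.2)  # mg/kg
    group_sizes: tuple = (5, 4, 12, 10)  # sums to n_subjects
    n_occasions: int = 3  # run-in, cycle-1 day-1, cycle-6 day-1
    occasion_spacing_h: float = 168.0  # >= 7 days, no carry-over
    sample_times_h: tuple = (0.05, 0.25, 0.5, 1.0, 3.0, 6.0)  # post end of infusion
    include_predose: bool = True
    infusion_duration_h: float = DEFAULT_INFUSION_DURATION
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self):
        if sum(self.group_sizes) != self.n_subjects:
            raise ValueError("group sizes must sum to n_subjects")
        if len(self.group_sizes) != len(self.dose_levels):
            raise ValueError("one group size per dose level")
        if tuple(sorted(self.sample_times_h)) != tuple(self.sample_times_h):
            raise ValueError("sample times must be sorted")

    @property
    def n_samples_per_occasion(self) -> int:
        return len(self.sample_times_h) + (1 if self.include_predose else 0)


@dataclass(frozen=True)
class CovariateDistributions:
    """Baseline covariate distributions calibrated to the trial population.

    Weight and serum creatinine are log-normal, age is normal; all three
    are truncated by rejection to the observed ranges.  The creatinine
    scale/spread were calibrated once so the derived Cockcroft-Gault CrCL
    reproduces the published median (~96.8 mL/min), range (~48-172) and
    normal-renal-function share (~61% with CrCL >= 90).
    """

    weight_median: float = 73.7  # kg
    weight_sigma_log: float = 0.17
    weight_bounds: tuple = (54.0, 121.0)
    age_mean: float = 62.1  # y
    age_sd: float = 8.5
    age_bounds: tuple = (42.6, 79.3)
    p_male: float = 0.645
    scr_median: float = 0.78  # mg/dL
    scr_sigma_log: float = 0.20
    scr_bounds: tuple = (0.4, 1.6)


def _truncated(rng, draw, lo, hi, n):
    """Rejection-sample ``n`` values of ``draw(size)`` inside [lo, hi]."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        x = draw(rng, 2 * (n - filled))
        x = x[(x >= lo) & (x <= hi)]
        take = min(len(x), n - filled)
        out[filled : filled + take] = x[:take]
        filled += take
    return out


def sample_covariates(
    cfg: CohortConfig,
    dists: CovariateDistributions | None = None,
    seed=None,
) -> list:
    """Draw baseline covariates for the cohort, reproducibly under ``seed``."""
    dists = dists or CovariateDistributions()
    rng = np.random.default_rng(seed)
    n = cfg.n_subjects
    wt = _truncated(
        rng,
        lambda r, m: np.exp(r.normal(math.log(dists.weight_median), dists.weight_sigma_log, m)),
        *dists.weight_bounds,
        n,
    )
    age = _truncated(
        rng, lambda r, m: r.normal(dists.age_mean, dists.age_sd, m), *dists.age_bounds, n
    )
    male = rng.random(n) < dists.p_male
    scr = _truncated(
        rng,
        lambda r, m: np.exp(r.normal(math.log(dists.scr_median), dists.scr_sigma_log, m)),
        *dists.scr_bounds,
        n,
    )
    out = []
    for i in range(n):
        cov = SubjectCovariates(
            weight=float(wt[i]),
            age=float(age[i]),
            sex="male" if male[i] else "female",
            serum_creatinine=float(scr[i]),
        ).with_derived_crcl()
        out.append(cov)
    return out


def build_design(covariates, cfg: CohortConfig) -> PKDataset:
    """Dose events and empty observation rows for every subject/occasion.

    Subjects are assigned to dose levels in order of the configured group
    sizes; each occasion doses ``level * weight`` mg over the infusion
    duration, with a predose sample (at the dose time) and the configured
    post-infusion samples.
    """
    ds = PKDataset(lloq=cfg.lloq)
    levels = [
        lvl for lvl, g in zip(cfg.dose_levels, cfg.group_sizes) for _ in range(g)
    ]
    for i, cov in enumerate(covariates):
        sid = f"S{i + 1:03d}"
        ds.covariates[sid] = cov
        for occ in range(cfg.n_occasions):
            t0 = occ * cfg.occasion_spacing_h
            ds.doses.append(
                DoseEvent(
                    subject_id=sid,
                    time=t0,
                    amount=levels[i] * cov.weight,
                    duration=cfg.infusion_duration_h,
                    occasion=occ,
                )
            )
            if cfg.include_predose:
                ds.observations.append(ObservationRecord(sid, t0, 0.0, blq=True))
            for s in cfg.sample_times_h:
                ds.observations.append(
                    ObservationRecord(sid, t0 + cfg.infusion_duration_h + s, 0.0)
                )
    ds.validate()
    return ds


def simulate_observations(
    skeleton: PKDataset, model: PopulationModel, seed=None
) -> tuple[PKDataset, dict]:
    """Fill a design skeleton with concentrations simulated from ``model``.

    Returns the populated dataset and a truth record holding the per-subject
    eta draws (for recovery tests).  Predose records at or before the first
    dose keep DV = 0.
    """
    rng = np.random.default_rng(seed)
    ds = skeleton.copy()
    eta_names = model.eta_names
    truth = {"eta": {}, "model": model.to_dict()}
    for sid in ds.subject_ids:
        cov = ds.covariates[sid]
        eta = {
            p: float(rng.normal(0.0, math.sqrt(model.omega2[p]))) for p in eta_names
        }
        truth["eta"][sid] = eta
        params = individual_params(model, cov, RandomEffects(eta))
        obs = ds.observations_for(sid)
        doses = ds.doses_for(sid)
        first = doses[0].time
        times = np.array([o.time for o in obs])
        ipred = conc_profile(params, doses, times)
        eps1 = rng.normal(0.0, math.sqrt(model.sigma2_prop), len(obs)) if model.sigma2_prop > 0 else np.zeros(len(obs))
        eps2 = rng.normal(0.0, math.sqrt(model.sigma2_add), len(obs)) if model.sigma2_add > 0 else np.zeros(len(obs))
        dv = np.maximum(ipred * (1.0 + eps1) + eps2, 0.0)
        for o, t, v, f in zip(obs, times, dv, ipred):
            if t <= first:
                o.dv = 0.0
            else:
                o.dv = float(v)
            o.ipred = float(f)
    ds.refresh_blq()
    return ds, truth


def simulate_cohort(
    model: PopulationModel,
    cfg: CohortConfig | None = None,
    dists: CovariateDistributions | None = None,
    seed=None,
) -> tuple[PKDataset, dict]:
    """Covariates + design + simulation in one call, split-seeded."""
    cfg = cfg or CohortConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cov, s_obs = ss.spawn(2)
    cov = sample_covariates(cfg, dists, seed=s_cov)
    skeleton = build_design(cov, cfg)
    return simulate_observations(skeleton, model, seed=s_obs)
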