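"""Visual predictive check: replicate simulation and percentile bands.

The observed design (dosing, sampling times, covariates, record structure)
is resimulated ``n_rep`` times under a fitted model with fresh random
effects and residual errors.  Within each time bin the observed 5th, 50th
and 95th percentiles are compared with the nonparametric 95% confidence
band of the same percentile across replicates (percentile-of-percentiles).
Records a replicate simulates below the quantification limit are excluded
replicate-wise, mirroring the M1 handling of the observed data.

Binning is by nominal time after dose, stratified by weight-normalised
dose level — the sparse design is nominal-time structured, so protocol
times are the natural bins; a quantile-binning fallback is available for
irregular designs.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import math

import numpy as np
import pandas as pd

from .covariates import PopulationModel
from .dataset import PKDataset, dose_level_mg_per_kg
from .estimation import EncodedData, FitResult, _individual_arrays

__all__ = ["VPCReplicates", "VPCResult", "simulate_replicates", "vpc_summary", "plot_vpc"]

logger = logging.getLogger(__name__)

PERCENTILES = (5.0, 50.0, 95.0)


@dataclass
class VPCReplicates:
    """Simulated DV arrays on the observed design."""

    enc: EncodedData
    dv: np.ndarray  # (R, S, O)
    blq: np.ndarray  # (R, S, O) bool, replicate-wise M1 exclusions
    lloq: float
    seed: object


@dataclass
class VPCResult:
    """Per-bin observed percentiles, simulated bands and containment flags."""

    table: pd.DataFrame  # rows: stratum, bin time, percentile, obs, sim lo/med/hi
    n_rep: int

    @property
    def containment_fraction(self) -> float:
        return float(self.table["contained"].mean())


def _as_model(fit_or_model) -> PopulationModel:
    return fit_or_model.estimates if isinstance(fit_or_model, FitResult) else fit_or_model


def simulate_replicates(
    ds: PKDataset, fit_or_model, n_rep: int = 500, seed=None, chunk: int = 100
) -> VPCReplicates:
    """Simulate ``n_rep`` datasets reusing the observed design of ``ds``.

    Each replicate draws new per-subject eta from Omega and new residual
    errors per record (``DV = IPRED (1 + eps1) + eps2``, floored at 0);
    simulated records below the LLOQ are flagged for replicate-wise
    exclusion, exactly as the M1 rule removes them from observed data.
    """
    model = _as_model(fit_or_model)
    enc = EncodedData(ds)
    rng = np.random.default_rng(seed)
    S, O = enc.y.shape
    names = model.eta_names
    om_sd = np.array([math.sqrt(model.omega2[p]) for p in names])
    dv = np.empty((n_rep, S, O))
    for lo in range(0, n_rep, chunk):
        hi = min(lo + chunk, n_rep)
        R = hi - lo
        eta = rng.normal(0.0, om_sd, (R, S, len(names))) if names else np.zeros((R, S, 0))
        params = []
        for k, p in enumerate(("vc", "cl", "vp", "q")):
            base = np.stack(_individual_arrays(model, enc, np.zeros((S, 0))), axis=0)[k]
            if p in names:
                base = base[None, :] * np.exp(eta[:, :, names.index(p)])
            else:
                base = np.broadcast_to(base, (R, S))
            params.append(base)
        ipred = enc.predict(*params)  # (R, S, O)
        eps1 = (
            rng.normal(0.0, math.sqrt(model.sigma2_prop), (R, S, O))
            if model.sigma2_prop > 0
            else 0.0
        )
        eps2 = (
            rng.normal(0.0, math.sqrt(model.sigma2_add), (R, S, O))
            if model.sigma2_add > 0
            else 0.0
        )
        dv[lo:hi] = np.maximum(ipred * (1.0 + eps1) + eps2, 0.0)
    blq = dv < ds.lloq
    return VPCReplicates(enc=enc, dv=dv, blq=blq, lloq=ds.lloq, seed=seed)


def _bin_keys(ds: PKDataset, enc: EncodedData, binning: str, n_quantile_bins: int = 7):
    """(stratum, bin) labels per encoded observation slot, NaN-safe."""
    S, O = enc.y.shape
    stratum = np.full((S, O), np.nan)
    tad = np.full((S, O), np.nan)
    for i, sid in enumerate(enc.subject_ids):
        doses = ds.doses_for(sid)
        for j in range(O):
            if not enc.obs_mask[i, j]:
                continue
            t = enc.obs_t[i, j]
            prior = [d for d in doses if d.time <= t]
            d = prior[-1]
            stratum[i, j] = dose_level_mg_per_kg(ds, d)
            tad[i, j] = t - d.time
    if binning == "nominal":
        bins = np.round(tad, 6)
    elif binning == "quantile":
        valid = tad[enc.obs_mask]
        edges = np.unique(np.quantile(valid, np.linspace(0, 1, n_quantile_bins + 1)))
        bins = np.full_like(tad, np.nan)
        idx = np.clip(np.searchsorted(edges, tad, side="right") - 1, 0, len(edges) - 2)
        centers = 0.5 * (edges[:-1] + edges[1:])
        bins[enc.obs_mask] = centers[idx[enc.obs_mask]]
    else:
        raise ValueError("binning must be 'nominal' or 'quantile'")
    return stratum, bins


def vpc_summary(
    ds: PKDataset,
    replicates: VPCReplicates,
    binning: str = "nominal",
    min_bin_size: int = 2,
) -> VPCResult:
    """Percentile bands per time bin, stratified by dose level.

    ``ds`` supplies the observed concentrations and must share the record
    structure of the dataset the replicates were simulated on.
    """
    enc = EncodedData(ds)
    if enc.y.shape != replicates.enc.y.shape:
        raise ValueError("observed dataset does not match the replicate design")
    stratum, bins = _bin_keys(ds, enc, binning)
    rows = []
    keys = sorted(
        {
            (s, b)
            for s, b, m in zip(stratum.ravel(), bins.ravel(), enc.obs_mask.ravel())
            if m
        }
    )
    for s, b in keys:
        cell = (stratum == s) & (bins == b) & enc.obs_mask
        obs = enc.y[cell]
        if obs.size < min_bin_size:
            logger.warning("bin (dose %s, t=%s h) has <%d observations; dropped", s, b, min_bin_size)
            continue
        obs_pct = np.percentile(obs, PERCENTILES)
        sim = replicates.dv[:, cell]  # (R, n_cell)
        keep = ~replicates.blq[:, cell]
        sim_pct = np.full((replicates.dv.shape[0], len(PERCENTILES)), np.nan)
        for r in range(sim.shape[0]):
            vals = sim[r][keep[r]]
            if vals.size >= min_bin_size:
                sim_pct[r] = np.percentile(vals, PERCENTILES)
        for k, p in enumerate(PERCENTILES):
            col = sim_pct[:, k]
            col = col[np.isfinite(col)]
            lo, med, hi = np.percentile(col, [2.5, 50.0, 97.5])
            rows.append(
                {
                    "dose_mg_per_kg": s,
                    "time_after_dose": b,
                    "percentile": p,
                    "n_obs": int(obs.size),
                    "observed": obs_pct[k],
                    "sim_lo": lo,
                    "sim_median": med,
                    "sim_hi": hi,
                    "contained": bool(lo <= obs_pct[k] <= hi),
                }
            )
    return VPCResult(table=pd.DataFrame(rows), n_rep=replicates.dv.shape[0])


def plot_vpc(result: VPCResult, path=None):
    """One panel per dose level: observed percentiles over simulated bands."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    tab = result.table
    strata = sorted(tab["dose_mg_per_kg"].unique())
    fig, axes = plt.subplots(1, len(strata), figsize=(4 * len(strata), 3.5), squeeze=False)
    for ax, s in zip(axes[0], strata):
        sub = tab[tab["dose_mg_per_kg"] == s]
        for p, color in zip(PERCENTILES, ("tab:blue", "tab:gray", "tab:blue")):
            pp = sub[sub["percentile"] == p].sort_values("time_after_dose")
            ax.fill_between(pp["time_after_dose"], pp["sim_lo"], pp["sim_hi"], alpha=0.25, color=color)
            ax.plot(pp["time_after_dose"], pp["observed"], "k--" if p != 50 else "k-")
        ax.set_yscale("log")
        ax.set_title(f"{s} mg/kg")
        ax.set_xlabel("time after dose (h)")
    axes[0][0].set_ylabel("concentration (ng/mL)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
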