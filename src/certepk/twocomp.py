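"""Closed-form two-compartment linear kinetics for intravenous infusion.

The drug is modelled with a central compartment (volume ``vc``, elimination
clearance ``cl``) exchanging with a peripheral compartment (volume ``vp``)
through a distribution clearance ``q``.  All solutions are bi-exponential
with disposition exponents ``lambda1 > lambda2 > 0`` (fast/slow), obtained
from the micro rate constants ``k10 = cl/vc``, ``k12 = q/vc``, ``k21 = q/vp``.

Units: doses in mg, volumes in L, clearances in L/h, times in h.
Concentrations are reported in ng/mL (1 mg/L = 1000 ng/mL); the conversion
lives in :data:`MG_PER_L_TO_NG_PER_ML` and nowhere else.

Steady state under repeated dosing is computed analytically via geometric
accumulation of each exponential term, never by simulating many doses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IndividualParams",
    "MicroConstants",
    "ExposureMetrics",
    "micro_constants",
    "conc_single_infusion",
    "conc_profile",
    "steady_state_conc",
    "steady_state_metrics",
    "MG_PER_L_TO_NG_PER_ML",
]

MG_PER_L_TO_NG_PER_ML = 1000.0

_TINY = 1e-300


@dataclass(frozen=True)
class IndividualParams:
    """Individual structural parameters of the two-compartment model."""

    vc: float  # central volume, L
    cl: float  # elimination clearance, L/h
    vp: float  # peripheral volume, L
    q: float  # distribution (intercompartmental) clearance, L/h

    def __post_init__(self) -> None:
        if not (self.vc > 0 and self.cl > 0 and self.vp > 0):
            raise ValueError("vc, cl and vp must be strictly positive")
        if self.q < 0:
            raise ValueError("q must be non-negative")


@dataclass(frozen=True)
class MicroConstants:
    """Micro rate constants and disposition exponents (all 1/h)."""

    k10: float
    k12: float
    k21: float
    lambda1: float
    lambda2: float


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure over one dosing interval."""

    cmax_ss: float  # ng/mL
    auc_ss: float  # ng*h/mL per interval; equals dose/cl for linear kinetics
    t_cmax: float  # h after start of infusion, within the interval


def _disposition(vc, cl, vp, q):
    """Rate constants and exponents, broadcasting over array inputs."""
    k10 = cl / vc
    k12 = q / vc
    k21 = np.where(np.asarray(vp) > 0, q / np.maximum(vp, _TINY), 0.0)
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    return k10, k12, k21, lam1, lam2


def micro_constants(p: IndividualParams) -> MicroConstants:
    """Micro constants and disposition exponents for ``p``.

    The exponents are the roots of
    ``lambda^2 - (k10 + k12 + k21) lambda + k10 k21 = 0``.
    In the ``q = 0`` limit the model degenerates to one compartment and the
    slow exponent is conventionally reported as ``k10`` (the only
    disposition rate left).
    """
    k10, k12, k21, lam1, lam2 = _disposition(p.vc, p.cl, p.vp, p.q)
    if p.q == 0.0:
        lam1, lam2 = float(k10), float(k10)
    return MicroConstants(float(k10), float(k12), float(k21), float(lam1), float(lam2))


def _biexp_coefficients(vc, cl, vp, q):
    """Bolus fractional coefficients A, B with A + B = 1 and the exponents.

    A bolus dose D gives ``c(t) = D/vc (A e^{-l1 t} + B e^{-l2 t})``.
    """
    _, _, k21, lam1, lam2 = _disposition(vc, cl, vp, q)
    denom = np.maximum(lam1 - lam2, 1e-12)
    A = (lam1 - k21) / denom
    B = (k21 - lam2) / denom
    return A, B, lam1, lam2


def _infusion_core(t, dose, duration, vc, cl, vp, q):
    """Central concentration (ng/mL) at time ``t`` after infusion start.

    Array-broadcasting core shared by every public entry point.  ``t < 0``
    yields 0; the solution is continuous at ``t == duration``.
    """
    A, B, lam1, lam2 = _biexp_coefficients(vc, cl, vp, q)
    rate = dose / duration
    tt = np.maximum(t, 0.0)
    te = np.minimum(tt, duration)

    def _term(coef, lam):
        lam_safe = np.maximum(lam, _TINY)
        val = coef / lam_safe * (-np.expm1(-lam_safe * te)) * np.exp(
            -lam_safe * (tt - te)
        )
        # lam == 0 only in the degenerate q == 0 limit where coef == 0 too
        return np.where(lam > 0, val, 0.0)

    c = rate / vc * (_term(A, lam1) + _term(B, lam2))
    return np.where(np.asarray(t) >= 0, c, 0.0) * MG_PER_L_TO_NG_PER_ML


def conc_single_infusion(p: IndividualParams, dose: float, duration: float, t):
    """Concentration after one constant-rate infusion starting at ``t = 0``.

    Parameters
    ----------
    p
        Individual structural parameters.
    dose
        Amount infused, mg.
    duration
        Infusion length, h (must be > 0; pass e.g. 1e-6 for a near-bolus).
    t
        Time(s) since infusion start, h.  Scalar or array.

    Returns
    -------
    Concentration in ng/mL, same shape as ``t``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    out = _infusion_core(np.asarray(t, dtype=float), dose, duration, p.vc, p.cl, p.vp, p.q)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def conc_profile(p: IndividualParams, doses: Sequence, times) -> np.ndarray:
    """Superposed concentration from a sequence of infusion events.

    ``doses`` is an iterable of objects with ``time``, ``amount`` and
    ``duration`` attributes (e.g. :class:`certepk.dataset.DoseEvent`),
    sorted by time.  Linearity makes the profile the plain sum of
    single-infusion contributions from every dose at or before each time.
    """
    times = np.asarray(times, dtype=float)
    total = np.zeros_like(times)
    for d in doses:
        total += _infusion_core(times - d.time, d.amount, d.duration, p.vc, p.cl, p.vp, p.q)
    return total


def steady_state_conc(p: IndividualParams, dose: float, tau: float, duration: float, t):
    """Concentration at steady state, ``t`` hours into a dosing interval.

    With interval ``tau`` the trailing contribution of all earlier doses is
    the geometric series ``e^{-lam tau} / (1 - e^{-lam tau})`` applied to
    each post-infusion exponential term, so

    ``css(t) = c1(t) + sum_i coef_i (1-e^{-lam_i T}) e^{-lam_i (t-T)}
               e^{-lam_i tau} / (1 - e^{-lam_i tau})``

    where ``c1`` is the single-dose solution and ``T`` the infusion length.
    """
    if not tau > duration:
        raise ValueError("tau must exceed the infusion duration")
    t = np.asarray(t, dtype=float)
    A, B, lam1, lam2 = _biexp_coefficients(p.vc, p.cl, p.vp, p.q)
    rate = dose / duration
    single = _infusion_core(t, dose, duration, p.vc, p.cl, p.vp, p.q)

    def _trail(coef, lam):
        lam_safe = np.maximum(lam, _TINY)
        acc = np.exp(-lam_safe * tau) / (-np.expm1(-lam_safe * tau))
        val = (
            coef
            / lam_safe
            * (-np.expm1(-lam_safe * duration))
            * np.exp(-lam_safe * (t - duration))
            * acc
        )
        return np.where(lam > 0, val, 0.0)

    trail = rate / p.vc * (_trail(A, lam1) + _trail(B, lam2)) * MG_PER_L_TO_NG_PER_ML
    return single + trail


def _interval_grid(tau: float, duration: float, n: int) -> np.ndarray:
    """Grid over one interval, dense across the infusion where Cmax lives."""
    n_inf = max(n // 5, 32)
    g1 = np.linspace(0.0, duration, n_inf)
    g2 = duration * np.geomspace(1.0, tau / duration, n - n_inf)
    return np.unique(np.concatenate([g1, g2]))


def steady_state_metrics(
    p: IndividualParams,
    dose: float,
    tau: float,
    duration: float,
    n_grid: int = 2000,
) -> ExposureMetrics:
    """Steady-state Cmax, AUC over one interval, and the time of Cmax.

    AUC is exact (``dose/cl``); Cmax comes from a dense-grid search over the
    interval (grid concentrated around the infusion, where the peak of an
    IV-infusion profile sits) followed by local parabolic refinement.
    """
    grid = _interval_grid(tau, duration, n_grid)
    css = steady_state_conc(p, dose, tau, duration, grid)
    i = int(np.argmax(css))
    t_best, c_best = grid[i], css[i]
    if 0 < i < len(grid) - 1:
        t_ref, c_ref = _parabolic_peak(
            grid[i - 1 : i + 2], css[i - 1 : i + 2]
        )
        c_check = float(steady_state_conc(p, dose, tau, duration, t_ref))
        if c_check > c_best:
            t_best, c_best = t_ref, c_check
    auc = dose / p.cl * MG_PER_L_TO_NG_PER_ML
    return ExposureMetrics(cmax_ss=float(c_best), auc_ss=float(auc), t_cmax=float(t_best))


def _parabolic_peak(x3, y3):
    """Vertex of the parabola through three points; falls back to the middle."""
    x0, x1, x2 = x3
    y0, y1, y2 = y3
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    if denom == 0:
        return x1, y1
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a >= 0:
        return x1, y1
    xv = -b / (2 * a)
    if not (min(x3) <= xv <= max(x3)):
        return x1, y1
    return xv, y1
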