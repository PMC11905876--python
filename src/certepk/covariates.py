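"""Population-to-individual parameter mapping.

A :class:`PopulationModel` holds the fixed effects (``theta``), the list of
covariate effects, the diagonal inter-individual variances (``omega2``) and
the residual-error variances.  Individual parameters are obtained as

* log-normal inter-individual variability:  ``P_i = P_typ * exp(eta_P_i)``
* power continuous covariate:               ``P_typ = theta * (x / x_ref)^theta_x``
* linear renal-function split of clearance: ``CL_typ = CL_NR + CL_R * CrCL / 90``
* proportional categorical covariate:       ``P_typ = theta * (1 + theta_x * x)``

Creatinine clearance is derived with the Cockcroft-Gault formula from age,
weight, sex and serum creatinine.  Reference covariate values follow the
usual conventions (70 kg, 60 y, CrCL 90 mL/min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .twocomp import IndividualParams

__all__ = [
    "CovariateEffect",
    "PopulationModel",
    "RandomEffects",
    "power_effect",
    "renal_cl",
    "proportional_effect",
    "cockcroft_gault",
    "typical_values",
    "individual_params",
    "STRUCTURAL_PARAMS",
    "REFERENCE_WEIGHT_KG",
    "REFERENCE_AGE_Y",
    "REFERENCE_CRCL_ML_MIN",
]

STRUCTURAL_PARAMS = ("vc", "cl", "vp", "q")

REFERENCE_WEIGHT_KG = 70.0
REFERENCE_AGE_Y = 60.0
REFERENCE_CRCL_ML_MIN = 90.0


def power_effect(theta_typical, x, xref, exponent):
    """Power covariate model ``theta * (x / xref)^exponent``."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or xref <= 0:
        raise ValueError("power covariate and its reference must be positive")
    return theta_typical * (x / xref) ** exponent


def renal_cl(cl_nr, cl_r, bcrcl, crcl_ref: float = REFERENCE_CRCL_ML_MIN):
    """Clearance split into nonrenal and renal parts, linear in CrCL.

    ``CL = CL_NR + CL_R * CrCL / 90`` with 90 mL/min the reference
    creatinine clearance; at the reference the renal part contributes
    exactly ``CL_R``.
    """
    bcrcl = np.asarray(bcrcl, dtype=float)
    if np.any(bcrcl < 0):
        raise ValueError("creatinine clearance must be non-negative")
    return cl_nr + cl_r * bcrcl / crcl_ref


def proportional_effect(theta_typical, theta_x, x):
    """Proportional categorical covariate ``theta * (1 + theta_x * x)``.

    ``theta_x`` is bounded below by -1 so the parameter stays positive.
    """
    if theta_x <= -1:
        raise ValueError("proportional effect must exceed -1")
    return theta_typical * (1.0 + theta_x * np.asarray(x, dtype=float))


def cockcroft_gault(age, weight, scr, sex):
    """Cockcroft-Gault creatinine clearance, mL/min.

    ``(140 - age) * weight / (72 * scr)``, multiplied by 0.85 for females.
    ``sex`` may be "male"/"female", or 1 (male) / 0 (female), scalar or
    array; ``scr`` is serum creatinine in mg/dL.
    """
    age = np.asarray(age, dtype=float)
    weight = np.asarray(weight, dtype=float)
    scr = np.asarray(scr, dtype=float)
    if np.any(age >= 140):
        raise ValueError("age must be below 140 years")
    if np.any(age <= 0) or np.any(weight <= 0) or np.any(scr <= 0):
        raise ValueError("age, weight and serum creatinine must be positive")
    female = _is_female(sex)
    crcl = (140.0 - age) * weight / (72.0 * scr)
    crcl = crcl * np.where(female, 0.85, 1.0)
    return float(crcl) if crcl.ndim == 0 else crcl


def _is_female(sex):
    if isinstance(sex, str):
        return np.asarray(sex.lower() in ("female", "f"))
    arr = np.asarray(sex)
    if arr.dtype.kind in "US":
        return np.char.lower(arr.astype(str)) == "female"
    return arr == 0


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate effect on one structural parameter.

    ``theta_key`` names the entry of ``PopulationModel.theta`` holding the
    effect coefficient (power exponent or proportional fraction).  For the
    ``linear_renal`` form the convention is that the clearance typical value
    is carried by the two theta entries ``"<parameter>_nr"`` and
    ``"<parameter>_r"`` instead of ``theta["<parameter>"]``; ``theta_key``
    is unused and may be empty.
    """

    parameter: str  # one of STRUCTURAL_PARAMS
    covariate: str  # 'weight', 'age', 'sex', 'bcrcl'
    form: str  # 'power', 'linear_renal', 'proportional'
    theta_key: str = ""
    reference: float = 1.0

    def __post_init__(self):
        if self.form not in ("power", "linear_renal", "proportional"):
            raise ValueError(f"unknown covariate-effect form {self.form!r}")
        if self.parameter not in STRUCTURAL_PARAMS:
            raise ValueError(f"unknown structural parameter {self.parameter!r}")


@dataclass(frozen=True)
class RandomEffects:
    """Per-subject deviations eta (log scale) keyed by structural parameter."""

    eta: Mapping[str, float]

    def get(self, name: str) -> float:
        return float(self.eta.get(name, 0.0))


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, covariate map, IIV variances and residual variances.

    ``theta`` holds every fixed effect: structural typical values (``vc``,
    ``vp``, ``q`` and either ``cl`` or the renal split ``cl_nr``/``cl_r``)
    plus covariate-effect coefficients under the names the effects declare.
    ``omega2`` holds the diagonal IIV variances keyed by structural
    parameter; omitted keys (or zeros) mean no IIV — a structural constant,
    not a parameter estimated at a bound.  ``fixed`` lists entries excluded
    from estimation (e.g. ``sigma2_add`` when the additive error is fixed
    to 0).
    """

    theta: Mapping[str, float]
    covariate_effects: tuple = ()
    omega2: Mapping[str, float] = field(default_factory=dict)
    sigma2_prop: float = 0.0
    sigma2_add: float = 0.0
    fixed: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "theta", dict(self.theta))
        object.__setattr__(self, "omega2", dict(self.omega2))
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))
        for k, v in self.theta.items():
            if not math.isfinite(v):
                raise ValueError(f"theta[{k!r}] is not finite")
        for k, v in self.omega2.items():
            if v < 0:
                raise ValueError(f"omega2[{k!r}] must be non-negative")
        if self.sigma2_prop < 0 or self.sigma2_add < 0:
            raise ValueError("residual variances must be non-negative")
        if self.sigma2_prop == 0 and self.sigma2_add == 0:
            raise ValueError("at least one residual variance must be positive")
        self._validate_theta_signs()

    def _validate_theta_signs(self):
        prop_keys = {
            e.theta_key for e in self.covariate_effects if e.form == "proportional"
        }
        structural = self._structural_theta_keys()
        for k, v in self.theta.items():
            if k in prop_keys:
                if v <= -1:
                    raise ValueError(f"proportional effect theta[{k!r}] must be > -1")
            elif k in structural and v <= 0:
                raise ValueError(f"structural theta[{k!r}] must be positive")

    def _structural_theta_keys(self):
        keys = set()
        for p in STRUCTURAL_PARAMS:
            if self.has_renal_cl and p == "cl":
                keys.update({"cl_nr", "cl_r"})
            elif p in self.theta:
                keys.add(p)
        return keys

    @property
    def has_renal_cl(self) -> bool:
        return any(e.form == "linear_renal" for e in self.covariate_effects)

    @property
    def eta_names(self) -> tuple:
        """Structural parameters carrying inter-individual variability."""
        return tuple(p for p in STRUCTURAL_PARAMS if self.omega2.get(p, 0.0) > 0)

    def with_theta(self, **updates) -> "PopulationModel":
        theta = dict(self.theta)
        theta.update(updates)
        return replace(self, theta=theta)

    def to_dict(self) -> dict:
        return {
            "theta": dict(self.theta),
            "covariate_effects": [
                {
                    "parameter": e.parameter,
                    "covariate": e.covariate,
                    "form": e.form,
                    "theta_key": e.theta_key,
                    "reference": e.reference,
                }
                for e in self.covariate_effects
            ],
            "omega2": dict(self.omega2),
            "sigma2_prop": self.sigma2_prop,
            "sigma2_add": self.sigma2_add,
            "fixed": sorted(self.fixed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        return cls(
            theta=d["theta"],
            covariate_effects=tuple(
                CovariateEffect(**e) for e in d.get("covariate_effects", [])
            ),
            omega2=d.get("omega2", {}),
            sigma2_prop=d.get("sigma2_prop", 0.0),
            sigma2_add=d.get("sigma2_add", 0.0),
            fixed=frozenset(d.get("fixed", ())),
        )


def _covariate_value(cov, name):
    """Pull a covariate from a mapping or attribute-style record."""
    if isinstance(cov, Mapping):
        if name not in cov:
            raise KeyError(f"covariate {name!r} not available for this subject")
        return cov[name]
    try:
        val = getattr(cov, name)
    except AttributeError as exc:
        raise KeyError(f"covariate {name!r} not available for this subject") from exc
    if val is None:
        raise KeyError(f"covariate {name!r} not available for this subject")
    return val


def typical_values(model: PopulationModel, cov) -> dict:
    """Typical structural parameters for a covariate vector (eta = 0).

    ``cov`` is a mapping or record exposing ``weight``, ``age``, ``sex`` and
    ``bcrcl`` as needed by the model's covariate effects; values may be
    scalars or aligned arrays (the whole population at once).
    """
    out = {}
    for p in STRUCTURAL_PARAMS:
        if p == "cl" and model.has_renal_cl:
            eff = next(e for e in model.covariate_effects if e.form == "linear_renal")
            base = renal_cl(
                model.theta["cl_nr"],
                model.theta["cl_r"],
                _covariate_value(cov, eff.covariate),
                eff.reference,
            )
        else:
            base = model.theta[p]
        for e in model.covariate_effects:
            if e.parameter != p or e.form == "linear_renal":
                continue
            x = _covariate_value(cov, e.covariate)
            if e.form == "power":
                base = power_effect(base, x, e.reference, model.theta[e.theta_key])
            elif e.form == "proportional":
                x = _categorical_indicator(x, e.covariate)
                base = proportional_effect(base, model.theta[e.theta_key], x)
        out[p] = base
    return out


def _categorical_indicator(x, covariate):
    """Map a categorical covariate to its 0/1 indicator (female = 1 for sex)."""
    if covariate == "sex":
        return _is_female(x).astype(float)
    return np.asarray(x, dtype=float)


def individual_params(
    model: PopulationModel, cov, eta: RandomEffects | None = None
) -> IndividualParams:
    """Individual parameters: covariate-adjusted typical values times e^eta."""
    tv = typical_values(model, cov)
    eta = eta or RandomEffects({})
    vals = {p: float(tv[p]) * math.exp(eta.get(p)) for p in STRUCTURAL_PARAMS}
    return IndividualParams(vc=vals["vc"], cl=vals["cl"], vp=vals["vp"], q=vals["q"])
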