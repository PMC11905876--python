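"""Published final-model parameter set for certepetide.

The reported population estimates (with 95% confidence intervals) of the
final two-compartment model serve two roles in this package: the ground
truth from which synthetic cohorts are simulated, and the input to the
smoothed-parametric-bootstrap exposure analyses when no fit of real trial
data is available.  Standard errors are back-derived from the printed CIs
(``SE = width / 3.92``, i.e. estimate +/- 1.96 SE) and assembled into a
diagonal covariance matrix; the full estimation covariance was not
published, and at these coefficient-of-variation levels the exposure-ratio
medians are insensitive to the off-diagonal terms.
"""

from __future__ import annotations

import numpy as np

from .covariates import (
    CovariateEffect,
    PopulationModel,
    REFERENCE_CRCL_ML_MIN,
    REFERENCE_WEIGHT_KG,
)

__all__ = [
    "final_model",
    "base_model",
    "FINAL_CI95",
    "final_se",
    "final_covariance",
]

# estimate and 95% CI for every estimated parameter of the final model
FINAL_CI95 = {
    "vc": (5.87, 5.23, 6.51),
    "cl_nr": (2.56, 1.41, 3.71),
    "cl_r": (4.32, 3.22, 5.42),
    "vp": (10.3, 9.51, 11.1),
    "q": (24.9, 21.7, 28.2),
    "wt_vc": (0.933, 0.602, 1.26),
    "wt_vp": (0.879, 0.558, 1.20),
    "omega2_vc": (0.0447, 0.00996, 0.0795),
    "omega2_cl": (0.0301, 0.0136, 0.0467),
    "omega2_vp": (0.0209, 0.00215, 0.0397),
    "sigma2_prop": (0.0393, 0.0333, 0.0452),
}


def final_model() -> PopulationModel:
    """The final certepetide model: weight on Vc/Vp, CrCL split of CL.

    IIV on Vc, CL and Vp (diagonal); the Q variance and the additive
    residual variance are structural zeros.  Residual error is proportional.
    """
    return PopulationModel(
        theta={
            "vc": 5.87,
            "cl_nr": 2.56,
            "cl_r": 4.32,
            "vp": 10.3,
            "q": 24.9,
            "wt_vc": 0.933,
            "wt_vp": 0.879,
        },
        covariate_effects=(
            CovariateEffect("vc", "weight", "power", "wt_vc", REFERENCE_WEIGHT_KG),
            CovariateEffect("vp", "weight", "power", "wt_vp", REFERENCE_WEIGHT_KG),
            CovariateEffect("cl", "bcrcl", "linear_renal", "", REFERENCE_CRCL_ML_MIN),
        ),
        omega2={"vc": 0.0447, "cl": 0.0301, "vp": 0.0209},
        sigma2_prop=0.0393,
        sigma2_add=0.0,
        fixed=frozenset({"sigma2_add"}),
    )


def base_model() -> PopulationModel:
    """Covariate-free starting model for stepwise selection.

    Typical clearance initialised at the reference-subject value
    ``CL_NR + CL_R`` of the final model; other entries at the final
    structural estimates.
    """
    return PopulationModel(
        theta={"vc": 5.87, "cl": 6.88, "vp": 10.3, "q": 24.9},
        covariate_effects=(),
        omega2={"vc": 0.0447, "cl": 0.0301, "vp": 0.0209},
        sigma2_prop=0.0393,
        sigma2_add=0.0,
        fixed=frozenset({"sigma2_add"}),
    )


def initial_model() -> PopulationModel:
    """Deliberately displaced starting values for fitting the final structure.

    Structural values off by 1.4-2x, exponents at 0.5, variances at 0.1 —
    a realistic exploratory-analysis starting point that exercises the
    optimiser rather than starting it at the answer.
    """
    m = final_model()
    return PopulationModel(
        theta={
            "vc": 8.0,
            "cl_nr": 1.5,
            "cl_r": 6.0,
            "vp": 15.0,
            "q": 15.0,
            "wt_vc": 0.5,
            "wt_vp": 0.5,
        },
        covariate_effects=m.covariate_effects,
        omega2={"vc": 0.1, "cl": 0.1, "vp": 0.1},
        sigma2_prop=0.1,
        sigma2_add=0.0,
        fixed=m.fixed,
    )


def final_se() -> dict:
    """Standard errors back-derived from the printed 95% CIs."""
    return {k: (hi - lo) / 3.92 for k, (_, lo, hi) in FINAL_CI95.items()}


def final_covariance() -> tuple[list, np.ndarray]:
    """Parameter names and the diagonal covariance built from the SEs."""
    names = list(FINAL_CI95)
    se = final_se()
    return names, np.diag([se[k] ** 2 for k in names])


def published_bootstrap_input():
    """``(names, mean, covariance, model)`` for the smoothed bootstrap."""
    names, cov = final_covariance()
    mean = [FINAL_CI95[k][0] for k in names]
    return names, mean, cov, final_model()
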