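"""Structural pharmacokinetic models and clinical covariate formulas.

Closed-form concentration predictions for one- and two-compartment models
after intravenous bolus dosing, with superposition over repeated doses,
log-normal individualization of parameters, multiplicative power-law
covariate effects, and the two bedside formulas used to derive covariates:
Cockcroft-Gault creatinine clearance and DuBois-DuBois body surface area.

Units are fixed by convention throughout the package: time in hours, dose
amounts in mg, concentrations in mg/L (numerically identical to ug/mL),
volumes in L and clearances in L/h.  Creatinine clearance is carried in
mL/min, the scale on which it is reported clinically and on which the
covariate model normalizes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SCR_UMOL_PER_MGDL",
    "cockcroft_gault",
    "dubois_bsa",
    "PKParamsIndividual",
    "MacroConstants",
    "CovariateEffect",
    "apply_covariates",
    "individualize",
    "predict_conc",
]

#: conversion factor between the two serum-creatinine scales:
#: Scr[mg/dL] = Scr[umol/L] / 88.4
SCR_UMOL_PER_MGDL = 88.4

#: relative root separation below which the two-compartment bolus solution
#: switches to the repeated-root closed form (guards 0/0 in the coefficients)
DEGENERATE_ROOT_RTOL = 1e-10


def _norm_sex(sex) -> str:
    if isinstance(sex, str):
        s = sex.strip().lower()
        if s in ("m", "male", "1"):
            return "male"
        if s in ("f", "female", "0"):
            return "female"
    elif sex in (0, 1):
        return "male" if sex == 1 else "female"
    raise ValueError(f"unrecognized sex specifier: {sex!r}")


def cockcroft_gault(age: float, bw: float, scr: float, sex) -> float:
    """Estimated creatinine clearance (mL/min) by Cockcroft-Gault.

    Parameters
    ----------
    age : float
        Age in years (must be < 140 for the formula to stay positive).
    bw : float
        Body weight in kg.
    scr : float
        Serum creatinine in mg/dL.  Laboratory values in umol/L must be
        divided by :data:`SCR_UMOL_PER_MGDL` first.
    sex : {"male", "female", 1, 0}
        Biological sex; the female estimate carries the 0.85 factor.

    Returns
    -------
    float
        CLcr = (140 - age) * BW / (Scr * 72), times 0.85 if female, in mL/min.
    """
    if scr <= 0:
        raise ValueError(f"serum creatinine must be positive, got {scr}")
    if bw <= 0:
        raise ValueError(f"body weight must be positive, got {bw}")
    if not 0 <= age < 140:
        raise ValueError(f"age must lie in [0, 140), got {age}")
    clcr = (140.0 - age) * bw / (scr * 72.0)
    if _norm_sex(sex) == "female":
        clcr *= 0.85
    return clcr


def dubois_bsa(bw: float, height: float) -> float:
    """Body surface area (m^2) by the DuBois and DuBois formula.

    BSA = 0.007184 * BW[kg]^0.425 * height[cm]^0.725.
    """
    if bw <= 0 or height <= 0:
        raise ValueError("body weight and height must be positive")
    return 0.007184 * bw**0.425 * height**0.725


@dataclass(frozen=True)
class PKParamsIndividual:
    """Disposition parameters of a single subject.

    ``v1``/``cl1`` are the central volume (L) and elimination clearance
    (L/h); ``v2``/``cl2`` the peripheral volume and intercompartmental
    clearance of the two-compartment model.  For a one-compartment model
    ``v2`` and ``cl2`` are ``None``.  ``cl2 == 0`` is allowed and collapses
    the two-compartment model onto the one-compartment solution.
    """

    v1: float
    cl1: float
    v2: float | None = None
    cl2: float | None = None

    def __post_init__(self):
        if not self.v1 > 0:
            raise ValueError(f"v1 must be positive, got {self.v1}")
        if not self.cl1 > 0:
            raise ValueError(f"cl1 must be positive, got {self.cl1}")
        if self.v2 is not None and not self.v2 > 0:
            raise ValueError(f"v2 must be positive, got {self.v2}")
        if self.cl2 is not None and self.cl2 < 0:
            raise ValueError(f"cl2 must be nonnegative, got {self.cl2}")

    def as_dict(self) -> dict[str, float]:
        d = {"v1": self.v1, "cl1": self.cl1}
        if self.v2 is not None:
            d["v2"] = self.v2
        if self.cl2 is not None:
            d["cl2"] = self.cl2
        return d


@dataclass(frozen=True)
class MacroConstants:
    """Micro/hybrid rate constants of the two-compartment bolus solution.

    ``k10 = cl1/v1``, ``k12 = cl2/v1``, ``k21 = cl2/v2`` (all 1/h);
    ``alpha >= beta`` are the hybrid rate constants, roots of
    ``s^2 - (k10+k12+k21) s + k10 k21``; ``coefA + coefB == 1`` are the
    dimensionless bolus coefficients so that after a dose D the central
    concentration is ``(D/v1) (coefA e^{-alpha t} + coefB e^{-beta t})``.

    ``degenerate`` flags a repeated root (``alpha ~= beta``), where the
    coefficient form is 0/0 and evaluation must use the limit expression
    ``(D/v1) e^{-alpha t} (1 + (k21 - alpha) t)``.
    """

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float
    coefA: float
    coefB: float
    degenerate: bool = False

    @classmethod
    def from_params(cls, p: PKParamsIndividual) -> "MacroConstants":
        if p.v2 is None or p.cl2 is None:
            raise ValueError("two-compartment macro constants need v2 and cl2")
        k10 = p.cl1 / p.v1
        k12 = p.cl2 / p.v1
        k21 = p.cl2 / p.v2
        a = k10 + k12 + k21
        disc = math.sqrt(max(a * a - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (a + disc)
        # product form is better conditioned than (a - disc)/2 when disc ~ a
        beta = (k10 * k21 / alpha) if alpha > 0 else 0.0
        degenerate = disc <= DEGENERATE_ROOT_RTOL * alpha
        if degenerate:
            coefA = coefB = 0.5
        else:
            coefA = (alpha - k21) / (alpha - beta)
            coefB = 1.0 - coefA
        return cls(k10, k12, k21, alpha, beta, coefA, coefB, degenerate)


@dataclass(frozen=True)
class CovariateEffect:
    """A multiplicative power-law covariate effect on one parameter.

    The targeted parameter is multiplied by ``(cov / reference)**exponent``.
    ``reference`` is the normalization constant, conventionally the cohort
    median of the covariate (e.g. 61.4 kg body weight, 61.0 mL/min
    creatinine clearance); ``None`` asks the fitting engine to re-derive it
    as the median of the dataset being fitted.
    """

    parameter: str
    covariate: str
    reference: float | None = None
    exponent: float = 0.0

    def __post_init__(self):
        if self.reference is not None and not self.reference > 0:
            raise ValueError(f"reference must be positive, got {self.reference}")


_COV_ALIASES = {"ht": "height", "wt": "bw", "weight": "bw", "scr_umol": "scr"}


def covariate_value(cov, name: str) -> float:
    """Resolve a covariate by name from a mapping or an attribute carrier."""
    key = _COV_ALIASES.get(name.lower(), name.lower())
    if isinstance(cov, Mapping):
        if key in cov:
            return float(cov[key])
    else:
        val = getattr(cov, key, None)
        if val is not None and not isinstance(val, str):
            return float(val)
    raise KeyError(f"covariate {name!r} not available on {type(cov).__name__}")


def apply_covariates(
    theta: Mapping[str, float],
    effects: Sequence[CovariateEffect],
    cov,
) -> PKParamsIndividual:
    """Typical parameters of a subject (eta = 0) from population typical values.

    Each effect multiplies its target parameter by
    ``(cov/reference)**exponent``; parameters without effects pass through.
    ``theta`` maps ``v1``/``cl1`` (and ``v2``/``cl2`` for two compartments)
    to the population typical values.
    """
    vals = dict(theta)
    for eff in effects:
        if eff.parameter not in vals:
            raise KeyError(f"effect targets unknown parameter {eff.parameter!r}")
        if eff.reference is None:
            raise ValueError(
                f"effect {eff.parameter}~{eff.covariate} has no reference value; "
                "resolve it (e.g. to the cohort median) before applying"
            )
        x = covariate_value(cov, eff.covariate)
        if x <= 0:
            raise ValueError(f"covariate {eff.covariate!r} must be positive, got {x}")
        vals[eff.parameter] = vals[eff.parameter] * (x / eff.reference) ** eff.exponent
    return PKParamsIndividual(**vals)


def individualize(
    typical: PKParamsIndividual, eta: Mapping[str, float]
) -> PKParamsIndividual:
    """Apply log-normal inter-individual deviations: P_i = TV(P) * exp(eta).

    ``eta`` maps parameter names to random-effect values; parameters absent
    from the mapping pass through unchanged.
    """
    vals = typical.as_dict()
    for name, e in eta.items():
        if name not in vals:
            raise KeyError(f"eta given for unknown parameter {name!r}")
        vals[name] = vals[name] * math.exp(e)
    return replace(typical, **vals)


def _dose_ta(dose) -> tuple[float, float]:
    if hasattr(dose, "time"):
        return float(dose.time), float(dose.amount)
    t, a = dose
    return float(t), float(a)


def predict_conc(
    t,
    doses: Sequence,
    p: PKParamsIndividual,
    n_compartments: int = 2,
):
    """Central concentration (mg/L) at time(s) ``t`` after IV bolus dosing.

    Superposes the bolus solution over all doses with dose time <= t.
    Times before the first dose predict 0.  ``doses`` may be
    :class:`~txapk.data.DoseEvent` objects or ``(time, amount)`` pairs.

    Returns a scalar for scalar ``t``, otherwise an ndarray.
    """
    tarr = np.asarray(t, dtype=float)
    scalar = tarr.ndim == 0
    tt = np.atleast_1d(tarr)
    if np.any(tt < 0):
        raise ValueError("prediction times must be nonnegative")
    conc = np.zeros_like(tt)
    if n_compartments == 1:
        k = p.cl1 / p.v1
        for d in doses:
            td, amt = _dose_ta(d)
            tau = tt - td
            m = tau >= 0
            conc[m] += amt / p.v1 * np.exp(-k * tau[m])
    elif n_compartments == 2:
        mc = MacroConstants.from_params(p)
        for d in doses:
            td, amt = _dose_ta(d)
            tau = tt - td
            m = tau >= 0
            tm = tau[m]
            if mc.degenerate:
                prof = np.exp(-mc.alpha * tm) * (1.0 + (mc.k21 - mc.alpha) * tm)
            else:
                prof = mc.coefA * np.exp(-mc.alpha * tm) + mc.coefB * np.exp(
                    -mc.beta * tm
                )
            conc[m] += amt / p.v1 * prof
    else:
        raise ValueError(f"n_compartments must be 1 or 2, got {n_compartments}")
    return float(conc[0]) if scalar else conc
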