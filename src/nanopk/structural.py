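"""Closed-form 1-compartment concentration predictions.

The disposition model is a single central compartment with first-order
elimination (rate ke = CL/V).  IV bolus doses enter the central
compartment directly; oral doses pass through a depot with first-order
absorption (rate Ka), an absorption lag time Tlag, and bioavailability
F.  All predictions return plasma concentration in ng/mL for doses in
mg/kg and volumes in L/kg: the mg/L -> ng/mL unit factor of 1000 lives
here and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DoseEvent, Route

__all__ = [
    "IndividualParams",
    "conc_iv_bolus",
    "conc_oral",
    "predict_profile",
    "oral_tmax",
    "MG_PER_L_TO_NG_PER_ML",
]

MG_PER_L_TO_NG_PER_ML = 1000.0

#: relative Ka-vs-ke gap below which the absorption term switches to its
#: ke->Ka limit form, avoiding catastrophic cancellation
_KA_KE_DEGENERACY = 1e-8


@dataclass(frozen=True)
class IndividualParams:
    """Subject-level PK parameters of the 1-compartment model.

    V    central volume of distribution, L/kg
    CL   clearance, L/h/kg
    Tlag oral absorption lag time, h
    Ka   first-order absorption rate constant, 1/h
    F    oral bioavailability fraction (may exceed 1 when used as a
         relative amplitude with covariate scaling)
    """

    V: float
    CL: float
    Tlag: float = 0.0
    Ka: float = 1.0
    F: float = 1.0

    def __post_init__(self) -> None:
        for name in ("V", "CL", "Ka", "F"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive, "
                                 f"got {getattr(self, name)}")
        if self.Tlag < 0:
            raise ValueError(f"Tlag must be >= 0, got {self.Tlag}")

    @property
    def ke(self) -> float:
        return self.CL / self.V


def conc_iv_bolus(p: IndividualParams, dose: float, t) -> np.ndarray | float:
    """Concentration after an IV bolus ``dose`` (mg/kg) at time ``t`` (h).

    C(t) = 1000 * (dose/V) * exp(-ke*t), so C(0) = 1000*dose/V ng/mL.
    """
    if not dose > 0:
        raise ValueError(f"dose must be > 0, got {dose}")
    t = np.asarray(t, dtype=float)
    return MG_PER_L_TO_NG_PER_ML * (dose / p.V) * np.exp(-p.ke * t)


def conc_oral(p: IndividualParams, dose: float, t) -> np.ndarray | float:
    """Concentration after an oral ``dose`` (mg/kg) at time ``t`` (h).

    Zero up to the lag time; thereafter the classic Bateman form with
    tau = t - Tlag,

        C = 1000 * F*dose*Ka / (V*(Ka-ke)) * (exp(-ke*tau) - exp(-Ka*tau)),

    replaced by the limit 1000 * (F*dose/V) * ke*tau*exp(-ke*tau) when
    |Ka - ke| < 1e-8 * ke.
    """
    if not dose > 0:
        raise ValueError(f"dose must be > 0, got {dose}")
    t = np.asarray(t, dtype=float)
    tau = t - p.Tlag
    ke = p.ke
    scale = MG_PER_L_TO_NG_PER_ML * p.F * dose / p.V
    with np.errstate(over="ignore"):
        if abs(p.Ka - ke) < _KA_KE_DEGENERACY * ke:
            c = scale * ke * tau * np.exp(-ke * tau)
        else:
            c = (scale * p.Ka / (p.Ka - ke)
                 * (np.exp(-ke * tau) - np.exp(-p.Ka * tau)))
    return np.where(tau > 0, c, 0.0)


def oral_tmax(p: IndividualParams) -> float:
    """Analytic time of the oral concentration peak."""
    ke = p.ke
    if abs(p.Ka - ke) < _KA_KE_DEGENERACY * ke:
        return p.Tlag + 1.0 / ke
    return p.Tlag + np.log(p.Ka / ke) / (p.Ka - ke)


def predict_profile(p: IndividualParams, doses: list[DoseEvent], times):
    """Superposition of route-appropriate closed forms over dose events.

    ``times`` must be sorted ascending.  Returns a vector the length of
    ``times``.
    """
    if not doses:
        raise ValueError("empty dose list")
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    total = np.zeros_like(times)
    for d in doses:
        rel = times - d.time
        active = rel >= 0
        rel_clipped = np.where(active, rel, 0.0)
        if d.route == Route.IV_BOLUS:
            c = conc_iv_bolus(p, d.amount, rel_clipped)
        else:
            c = conc_oral(p, d.amount, rel_clipped)
        total += np.where(active, c, 0.0)
    return total
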