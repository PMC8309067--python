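"""Non-compartmental analysis of single-dose concentration-time data.

Per-subject summary parameters computed with the linear trapezoidal
rule and a log-linear terminal fit, per arm summarized as mean +/- SD
with Welch two-sample comparisons.  Conventions:

* AUC from 0 to the first sample is anchored at (0, 0) for oral data
  and at (0, C0) for IV data, with C0 back-extrapolated log-linearly
  through the first two samples.
* The terminal rate constant k is the best log-linear fit (maximal
  adjusted R^2, ties to more points) over all candidate tails of >= 3
  points strictly after Tmax (oral) or from the first post-peak sample
  (IV), the usual WinNonlin-style "best fit" rule.
* T1/2 uses the conventional rounded constant 0.693/k.
* CL and volumes are reported in mL-based units (mL/h/kg, mL/kg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats

from .data import PKDataset, Route, SubjectRecord

__all__ = [
    "NCAResult",
    "NCAFailure",
    "lambda_z",
    "auc_0_t",
    "aumc_0_t",
    "auc_0_inf",
    "t_half",
    "clearance_iv",
    "v_terminal",
    "mrt",
    "vss",
    "dose_normalize",
    "bioavailability",
    "c0_backextrapolate",
    "delivering_efficiency",
    "analyze_subject",
    "analyze_dataset",
    "summarize_arm",
    "compare_arms",
]

#: mg/kg divided by ng·h/mL comes out in L/h/kg * 1e-6; scale to mL-based
_MG_PER_NGH = 1e6

T_HALF_CONSTANT = 0.693  # conventional rounded ln 2


class NCAFailure(ValueError):
    """Raised when a subject's data cannot support an NCA parameter."""


def lambda_z(times, concs, tmax: float | None = None,
             iv: bool = False) -> tuple[float, int, float]:
    """Terminal elimination rate constant by best log-linear tail fit.

    Returns ``(k, n_points, r2_adjusted)``.  Candidate tails have >= 3
    points, strictly after Tmax for oral data or from the first
    post-peak sample for IV data; the tail with maximal adjusted R^2
    wins, ties broken toward more points.  A non-positive slope on
    every candidate raises :class:`NCAFailure`.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if tmax is None:
        tmax = times[np.argmax(concs)]
    if iv:
        # all points from the first sample at/after the peak
        eligible = times >= tmax
    else:
        eligible = times > tmax
    t = times[eligible]
    c = concs[eligible]
    if len(t) < 3:
        raise NCAFailure(
            f"terminal fit needs >= 3 eligible points, have {len(t)}"
        )
    logc = np.log(c)
    best: tuple[float, int, float] | None = None
    for start in range(0, len(t) - 2):
        tt, ll = t[start:], logc[start:]
        n = len(tt)
        slope, intercept, r, _, _ = stats.linregress(tt, ll)
        if slope >= 0:
            continue
        r2adj = 1.0 - (1.0 - r * r) * (n - 1) / (n - 2)
        # ties (within fp dust) go to more points, i.e. earlier start
        if best is None or r2adj > best[2] + 1e-12:
            best = (-slope, n, r2adj)
    if best is None:
        raise NCAFailure("no candidate tail with a negative slope")
    return best


def auc_0_t(times, concs, c0: float | None = None) -> float:
    """Linear trapezoidal AUC from 0 to the last observation.

    The leading interval [0, t_first] is anchored at concentration 0
    (oral) or at ``c0`` (IV back-extrapolation) when given.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if len(times) < 2:
        raise NCAFailure("AUC needs >= 2 observations")
    anchor = 0.0 if c0 is None else c0
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
        concs = np.concatenate([[anchor], concs])
    return float(np.trapezoid(concs, times))


def aumc_0_t(times, concs, c0: float | None = None) -> float:
    """Linear trapezoidal area under the first-moment (t*C) curve."""
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    anchor = 0.0 if c0 is None else c0
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
        concs = np.concatenate([[anchor], concs])
    return float(np.trapezoid(times * concs, times))


def auc_0_inf(auc0t: float, c_last: float, k: float) -> float:
    """AUC extrapolated to infinity: AUC0-t + C_last/k."""
    if not k > 0:
        raise NCAFailure(f"k must be > 0, got {k}")
    return auc0t + c_last / k


def t_half(k: float) -> float:
    """Terminal half-life 0.693/k (conventional rounded constant)."""
    if not k > 0:
        raise NCAFailure(f"k must be > 0, got {k}")
    return T_HALF_CONSTANT / k


def clearance_iv(dose: float, auc0inf: float) -> float:
    """IV clearance dose/AUC0-inf in mL/h/kg (dose mg/kg, AUC ng·h/mL)."""
    return _MG_PER_NGH * dose / auc0inf


def v_terminal(dose: float, k: float, auc0inf: float) -> float:
    """Terminal-phase volume dose/(k*AUC0-inf) in mL/kg."""
    return _MG_PER_NGH * dose / (k * auc0inf)


def mrt(aumc0inf: float, auc0inf: float) -> float:
    """Mean residence time AUMC0-inf / AUC0-inf, h."""
    return aumc0inf / auc0inf


def vss(mrt_h: float, cl: float) -> float:
    """Steady-state volume MRT * CL, mL/kg."""
    return mrt_h * cl


def dose_normalize(auc0inf: float, cmax: float,
                   dose: float) -> tuple[float, float]:
    """Dose-normalized exposure: (AUC/dose in h·kg/mL, Cmax/dose in kg/mL)."""
    return auc0inf * 1e-6 / dose, cmax * 1e-6 / dose


def bioavailability(auc_oral: float, dose_oral: float,
                    auc_iv: float, dose_iv: float) -> float:
    """Absolute bioavailability, percent of dose-normalized AUC ratio."""
    return 100.0 * (auc_oral / dose_oral) / (auc_iv / dose_iv)


def c0_backextrapolate(times, concs) -> float:
    """IV concentration at t=0, log-linear through the first two samples.

    Falls back to the first observed concentration when the initial
    slope is not negative.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if len(times) < 2 or concs[1] >= concs[0]:
        return float(concs[0])
    slope = (math.log(concs[1]) - math.log(concs[0])) / (times[1] - times[0])
    return float(math.exp(math.log(concs[0]) - slope * times[0]))


def delivering_efficiency(tissue_conc: float, plasma_conc: float) -> float:
    """Tissue-to-plasma concentration ratio."""
    return tissue_conc / plasma_conc


@dataclass
class NCAResult:
    """Per-subject NCA parameters (units per field name comments)."""

    subject_id: str
    auc_0_t: float            # ng·h/mL
    auc_0_inf: float          # ng·h/mL
    aumc_0_inf: float         # ng·h²/mL
    cmax: float               # ng/mL
    tmax: float               # h, an observed time
    k: float                  # 1/h
    t_half: float             # h
    mrt: float                # h
    auc_per_dose: float       # h·kg/mL
    cmax_per_dose: float      # kg/mL
    n_lambda_points: int
    lambda_r2adj: float
    c0: float | None = None   # ng/mL, IV only
    cl: float | None = None   # mL/h/kg, IV only
    v: float | None = None    # mL/kg, IV only
    vss: float | None = None  # mL/kg, IV only


#: NCAResult fields carried into arm summaries
_SUMMARY_PARAMS = [
    "auc_0_t", "auc_0_inf", "cmax", "tmax", "k", "t_half", "mrt",
    "auc_per_dose", "cmax_per_dose", "c0", "cl", "v", "vss",
]


def analyze_subject(subject: SubjectRecord) -> NCAResult:
    """Full NCA for one subject's single-dose profile."""
    times = np.asarray(subject.times, dtype=float)
    concs = np.asarray(subject.concs, dtype=float)
    dose = subject.dose
    iv = subject.route == Route.IV_BOLUS

    imax = int(np.argmax(concs))
    cmax, tmax = float(concs[imax]), float(times[imax])
    k, n_pts, r2adj = lambda_z(times, concs, tmax=tmax, iv=iv)

    c0 = c0_backextrapolate(times, concs) if iv else None
    auc0t = auc_0_t(times, concs, c0=c0)
    aumc0t = aumc_0_t(times, concs, c0=c0)
    c_last, t_last = float(concs[-1]), float(times[-1])
    auc0inf = auc_0_inf(auc0t, c_last, k)
    aumc0inf = aumc0t + c_last * t_last / k + c_last / k**2
    mrt_h = mrt(aumc0inf, auc0inf)
    aucd, cmaxd = dose_normalize(auc0inf, cmax, dose)

    res = NCAResult(
        subject_id=subject.subject_id,
        auc_0_t=auc0t, auc_0_inf=auc0inf, aumc_0_inf=aumc0inf,
        cmax=cmax, tmax=tmax, k=k, t_half=t_half(k), mrt=mrt_h,
        auc_per_dose=aucd, cmax_per_dose=cmaxd,
        n_lambda_points=n_pts, lambda_r2adj=r2adj, c0=c0,
    )
    if iv:
        res.cl = clearance_iv(dose, auc0inf)
        res.v = v_terminal(dose, k, auc0inf)
        res.vss = vss(mrt_h, res.cl)
    return res


def analyze_dataset(dataset: PKDataset) -> pd.DataFrame:
    """NCA for every subject; one row per subject, arm labels attached."""
    rows = []
    for s in dataset.subjects:
        r = analyze_subject(s)
        row = {f.name: getattr(r, f.name) for f in fields(NCAResult)}
        row["formulation"] = s.formulation.value
        row["route"] = s.route.value
        row["dose"] = s.dose
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_arm(results: list[NCAResult]) -> pd.DataFrame:
    """Mean +/- SD per NCA parameter over one arm's subjects."""
    if len(results) < 2:
        raise NCAFailure("arm summary needs >= 2 subjects for an SD")
    rows = []
    for name in _SUMMARY_PARAMS:
        vals = [getattr(r, name) for r in results]
        if any(v is None for v in vals):
            continue
        vals = np.asarray(vals, dtype=float)
        rows.append(dict(parameter=name, mean=vals.mean(),
                         sd=vals.std(ddof=1), n=len(vals)))
    return pd.DataFrame(rows)


def compare_arms(arm_a: list[NCAResult], arm_b: list[NCAResult],
                 alpha: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-test per parameter between two arms.

    Welch's variant is used because 5-rat arms routinely show very
    unequal variances.  Returns mean/SD of both arms, the p-value, and
    a significance flag at ``alpha``.
    """
    rows = []
    for name in _SUMMARY_PARAMS:
        a = [getattr(r, name) for r in arm_a]
        b = [getattr(r, name) for r in arm_b]
        if any(v is None for v in a + b):
            continue
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise NCAFailure(f"{name}: both arms need >= 2 subjects")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(dict(
            parameter=name,
            mean_a=a.mean(), sd_a=a.std(ddof=1),
            mean_b=b.mean(), sd_b=b.std(ddof=1),
            t=t, p=p, significant=bool(p < alpha),
        ))
    return pd.DataFrame(rows)
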