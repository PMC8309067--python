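"""Nonlinear mixed-effects estimation for the 1-compartment model.

The population model couples the closed-form structural predictions of
:mod:`nanopk.structural` with

* exponential inter-individual variability, ``P_i = tvP * exp(eta_P)``
  with ``eta ~ N(0, omega^2)`` (diagonal Omega),
* a linear-fractional binary formulation covariate on any structural
  parameter, ``P = tvP * (1 + dP * code)``, and
* a residual error model, by default log-additive:
  ``log y = log f + eps``, ``eps ~ N(0, sigma^2)``.

Estimation is a first-order conditional (FOCE-style) approximate
marginal likelihood: for each subject the conditional mode eta_hat of
the joint density is located by a damped Gauss-Newton search, and the
subject's marginal -2 log-likelihood is the Laplace expression with the
Gauss-Newton curvature J'WJ + Omega^-1 evaluated at eta_hat.  Residual
variance weights are evaluated at the conditional prediction, which
retains the eta-epsilon interaction for heteroscedastic error models
(for the log-additive model the interaction is vacuous because the
log-scale variance is constant).

The user-facing surface follows the statsmodels convention: build a
:class:`PopPKModel` from a dataset, call :meth:`~PopPKModel.fit`, and
work with the returned :class:`PopPKResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .data import PKDataset, Route, SubjectRecord
from .structural import MG_PER_L_TO_NG_PER_ML, IndividualParams

__all__ = [
    "PARAM_ORDER",
    "ThetaVector",
    "OmegaMatrix",
    "SigmaValue",
    "ModelSpec",
    "FitResult",
    "PopPKModel",
    "PopPKResults",
    "individual_params",
    "subject_conditional_neg2ll",
    "foce_marginal_neg2ll",
    "aic",
    "eta_shrinkage",
    "iiv_percent",
]

#: canonical ordering of structural parameters and their random effects
PARAM_ORDER = ("V", "CL", "Tlag", "Ka", "F")

_OMEGA_FLOOR = 1e-6       # keeps Omega invertible for effects printed as 0
_PENALTY_LOGF = -60.0     # stands in for log f when f <= 0 (t <= Tlag)


@dataclass(frozen=True)
class ThetaVector:
    """Fixed effects: typical values plus optional covariate coefficients.

    Covariate coefficients follow the linear-fractional convention
    ``P = tvP * (1 + dP * code)``; a coefficient of ``None`` means the
    covariate is not in the model for that parameter.
    """

    tvV: float
    tvCL: float
    tvTlag: float = 0.0
    tvKa: float = 1.0
    tvF: float = 1.0
    dV: float | None = None
    dCL: float | None = None
    dTlag: float | None = None
    dKa: float | None = None
    dF: float | None = None

    def tv(self, name: str) -> float:
        return getattr(self, f"tv{name}")

    def d(self, name: str) -> float | None:
        return getattr(self, f"d{name}")

    def covariates(self) -> tuple[str, ...]:
        return tuple(p for p in PARAM_ORDER if self.d(p) is not None)

    def validate(self) -> None:
        for p in ("V", "CL", "Ka", "F"):
            if not self.tv(p) > 0:
                raise ValueError(f"tv{p} must be > 0, got {self.tv(p)}")
        if self.tvTlag < 0:
            raise ValueError(f"tvTlag must be >= 0, got {self.tvTlag}")
        for p in PARAM_ORDER:
            d = self.d(p)
            if d is not None and not 1.0 + d > 0:
                raise ValueError(f"1 + d{p} must be > 0, got d{p}={d}")


@dataclass(frozen=True)
class OmegaMatrix:
    """Diagonal variances of the subject-level random effects."""

    omega2: dict[str, float]

    def __post_init__(self) -> None:
        for p, v in self.omega2.items():
            if p not in PARAM_ORDER:
                raise ValueError(f"unknown random effect {p!r}")
            if v < 0:
                raise ValueError(f"omega^2_{p} must be >= 0, got {v}")

    @property
    def effects(self) -> tuple[str, ...]:
        return tuple(p for p in PARAM_ORDER if p in self.omega2)

    def variances(self, floor: float = 0.0) -> np.ndarray:
        return np.array(
            [max(self.omega2[p], floor) for p in self.effects], dtype=float
        )

    def matrix(self, floor: float = 0.0) -> np.ndarray:
        return np.diag(self.variances(floor=floor))


@dataclass(frozen=True)
class SigmaValue:
    """Residual error magnitude(s).

    For the log-additive, additive and proportional models this is a
    single SD; the mixed model carries (additive SD, proportional SD).
    """

    sigma: tuple[float, ...]

    def __post_init__(self) -> None:
        sig = tuple(float(s) for s in self.sigma) if not np.isscalar(
            self.sigma) else (float(self.sigma),)
        object.__setattr__(self, "sigma", sig)
        # zero is allowed so the generator can produce noise-free data;
        # estimation clamps sigma to its positive lower bound
        if not all(s >= 0 for s in self.sigma):
            raise ValueError(f"sigma components must be >= 0, "
                             f"got {self.sigma}")

    @property
    def value(self) -> float:
        return self.sigma[0]


# ---------------------------------------------------------------------------
# residual error contracts
# ---------------------------------------------------------------------------

class ErrorModel:
    """Residual error contract used by the FOCE machinery.

    Each model defines the observation-scale residual, the per-point
    residual variance as a function of the prediction, and whether the
    model works on the log scale (in which case the structural Jacobian
    d log f / d eta is used directly).  Only the log-additive model is
    tuned and tested for fitting; the others exist to express the model
    ladder of alternative residual structures.
    """

    name = "base"
    n_sigma = 1
    log_scale = False

    def residual(self, y, f):
        return y - f

    def variance(self, f, sigma: SigmaValue):
        raise NotImplementedError


class LogAdditiveError(ErrorModel):
    name = "log-additive"
    log_scale = True

    def residual(self, y, f):
        return np.log(y) - np.log(f)

    def variance(self, f, sigma):
        return np.full_like(np.asarray(f, dtype=float), sigma.sigma[0] ** 2)


class AdditiveError(ErrorModel):
    name = "additive"

    def variance(self, f, sigma):
        return np.full_like(np.asarray(f, dtype=float), sigma.sigma[0] ** 2)


class ProportionalError(ErrorModel):
    name = "proportional"

    def variance(self, f, sigma):
        return (sigma.sigma[0] * np.asarray(f, dtype=float)) ** 2


class PowerError(ErrorModel):
    """Variance sigma^2 * f^(2*gamma) with fixed exponent gamma."""

    name = "power"

    def __init__(self, gamma: float = 0.5):
        self.gamma = gamma

    def variance(self, f, sigma):
        return sigma.sigma[0] ** 2 * np.asarray(f, dtype=float) ** (
            2 * self.gamma)


class MixedError(ErrorModel):
    name = "mixed"
    n_sigma = 2

    def variance(self, f, sigma):
        add, prop = sigma.sigma
        return add ** 2 + (prop * np.asarray(f, dtype=float)) ** 2


ERROR_MODELS = {
    "log-additive": LogAdditiveError,
    "additive": AdditiveError,
    "proportional": ProportionalError,
    "power": PowerError,
    "mixed": MixedError,
}


@dataclass(frozen=True)
class ModelSpec:
    """Which covariate effects and random effects the model carries."""

    covariates: tuple[str, ...] = ()
    iiv: tuple[str, ...] = PARAM_ORDER
    error: str = "log-additive"

    def __post_init__(self) -> None:
        for p in self.covariates + self.iiv:
            if p not in PARAM_ORDER:
                raise ValueError(f"unknown parameter name {p!r}")
        object.__setattr__(
            self, "covariates",
            tuple(p for p in PARAM_ORDER if p in self.covariates))
        object.__setattr__(
            self, "iiv", tuple(p for p in PARAM_ORDER if p in self.iiv))
        if self.error not in ERROR_MODELS:
            raise ValueError(f"unknown error model {self.error!r}")

    @property
    def n_params(self) -> int:
        return (len(PARAM_ORDER) + len(self.covariates) + len(self.iiv)
                + ERROR_MODELS[self.error]().n_sigma)


# ---------------------------------------------------------------------------
# parameter maps
# ---------------------------------------------------------------------------

def individual_params(theta: ThetaVector, eta, form_code: int
                      ) -> IndividualParams:
    """Subject-level parameters from fixed effects, etas, and the covariate.

    ``eta`` is a 5-vector ordered as :data:`PARAM_ORDER`.
    """
    eta = np.asarray(eta, dtype=float)
    vals = {}
    for i, p in enumerate(PARAM_ORDER):
        tv = theta.tv(p)
        d = theta.d(p)
        scale = 1.0 + d * form_code if d is not None else 1.0
        if scale <= 0:
            raise ValueError(
                f"covariate coefficient d{p}={d} drives the typical value "
                f"non-positive at code {form_code}")
        vals[p] = tv * scale * math.exp(eta[i])
    return IndividualParams(V=vals["V"], CL=vals["CL"], Tlag=vals["Tlag"],
                            Ka=vals["Ka"], F=vals["F"])


# ---------------------------------------------------------------------------
# per-subject structural prediction with analytic eta-Jacobian
# ---------------------------------------------------------------------------

@dataclass
class _SubjectData:
    """Immutable per-subject arrays cached for the likelihood loop."""

    subject_id: str
    times: np.ndarray
    y: np.ndarray
    dose: float
    oral: bool
    form_code: int
    record: SubjectRecord


def _prepare(dataset: PKDataset) -> list[_SubjectData]:
    subs = []
    for s in dataset.subjects:
        subs.append(_SubjectData(
            subject_id=s.subject_id,
            times=np.asarray(s.times, dtype=float),
            y=np.asarray(s.concs, dtype=float),
            dose=s.dose,
            oral=s.route == Route.ORAL,
            form_code=s.form_code,
            record=s,
        ))
    return subs


def _sanitize(logf, J):
    """Route non-finite or underflowed predictions into the penalty branch."""
    bad = ~np.isfinite(logf) | (logf < _PENALTY_LOGF) | ~np.all(
        np.isfinite(J), axis=1)
    if bad.any():
        logf = np.where(bad, _PENALTY_LOGF, logf)
        J = np.where(bad[:, None], 0.0, J)
    return logf, J


def _logf_and_jac(sub: _SubjectData, p: IndividualParams):
    """log f(t) and d log f / d eta (n_obs x 5, PARAM_ORDER columns).

    Points with f <= 0 (oral, t <= Tlag) get the finite penalty value
    ``_PENALTY_LOGF`` and a zero Jacobian row so the likelihood stays
    finite and the optimizer is pushed away smoothly by neighbours.
    """
    t = sub.times
    n = len(t)
    J = np.zeros((n, 5))
    ke = p.ke
    if not sub.oral:
        logf = math.log(MG_PER_L_TO_NG_PER_ML * sub.dose / p.V) - ke * t
        J[:, 0] = -1.0 + ke * t        # eta_V
        J[:, 1] = -ke * t              # eta_CL
        return _sanitize(logf, J)

    tau = t - p.Tlag
    ok = tau > 0
    logf = np.full(n, _PENALTY_LOGF)
    if abs(p.Ka - ke) < 1e-8 * ke:
        # ke -> Ka limit: log f = log(scale*ke) + log tau - ke*tau
        scale = MG_PER_L_TO_NG_PER_ML * p.F * sub.dose / p.V
        tauk = tau[ok]
        logf[ok] = math.log(scale * ke) + np.log(tauk) - ke * tauk
        dke = 1.0 / ke - tauk                      # d log f / d ke
        J[ok, 0] = -1.0 - ke * dke                 # eta_V (ke = CL/V)
        J[ok, 1] = ke * dke                        # eta_CL
        J[ok, 3] = 0.0                             # eta_Ka (flat at limit)
        J[ok, 4] = 1.0                             # eta_F
        dtau = 1.0 / tauk - ke
        J[ok, 2] = -p.Tlag * dtau                  # eta_Tlag
        return _sanitize(logf, J)

    amp = (MG_PER_L_TO_NG_PER_ML * p.F * sub.dose * p.Ka
           / (p.V * (p.Ka - ke)))
    tauk = tau[ok]
    E1 = np.exp(-ke * tauk)
    E2 = np.exp(-p.Ka * tauk)
    diff = E1 - E2
    # amp may be negative when Ka < ke; log|amp| + log|diff| is still the
    # log of the (positive) product
    logf[ok] = math.log(abs(amp)) + np.log(np.abs(diff))
    dlog_dke = 1.0 / (p.Ka - ke) - tauk * E1 / diff
    dlog_dKa = 1.0 / p.Ka - 1.0 / (p.Ka - ke) + tauk * E2 / diff
    dlog_dtau = (-ke * E1 + p.Ka * E2) / diff
    J[ok, 0] = -1.0 - ke * dlog_dke
    J[ok, 1] = ke * dlog_dke
    J[ok, 2] = -p.Tlag * dlog_dtau
    J[ok, 3] = p.Ka * dlog_dKa
    J[ok, 4] = 1.0
    return _sanitize(logf, J)


def subject_conditional_neg2ll(subject: SubjectRecord, theta: ThetaVector,
                               eta, sigma: SigmaValue | float
                               ) -> tuple[float, np.ndarray]:
    """Conditional -2 log-likelihood of one subject at fixed eta.

    Log-additive error: sum_j [ (log y_j - log f_j)^2/sigma^2
    + log(2 pi sigma^2) ].  Predicted concentrations of zero (oral
    observation at or before the lag time) contribute through a large
    finite penalty rather than an exception.  Returns the value and the
    log-residual vector.
    """
    if not isinstance(sigma, SigmaValue):
        sigma = SigmaValue((float(sigma),))
    sub = _prepare_single(subject)
    p = individual_params(theta, eta, subject.form_code)
    logf, _ = _logf_and_jac(sub, p)
    r = np.log(sub.y) - logf
    s2 = sigma.value ** 2
    val = float(np.sum(r * r / s2 + math.log(2 * math.pi * s2)))
    return val, r


def _prepare_single(subject: SubjectRecord) -> _SubjectData:
    return _SubjectData(
        subject_id=subject.subject_id,
        times=np.asarray(subject.times, dtype=float),
        y=np.asarray(subject.concs, dtype=float),
        dose=subject.dose,
        oral=subject.route == Route.ORAL,
        form_code=subject.form_code,
        record=subject,
    )


# ---------------------------------------------------------------------------
# FOCE marginal likelihood
# ---------------------------------------------------------------------------

class _Batch:
    """Padded per-subject arrays so the eta search vectorizes."""

    def __init__(self, subs: list[_SubjectData]):
        n = len(subs)
        t_max = max(len(s.times) for s in subs)
        self.t = np.ones((n, t_max))
        self.mask = np.zeros((n, t_max), dtype=bool)
        self.y = np.ones((n, t_max))
        for i, s in enumerate(subs):
            k = len(s.times)
            self.t[i, :k] = s.times
            self.y[i, :k] = s.y
            self.mask[i, :k] = True
        self.logy = np.log(self.y)
        self.dose = np.array([s.dose for s in subs])
        self.oral = np.array([s.oral for s in subs])
        self.code = np.array([s.form_code for s in subs], dtype=float)
        self.ids = [s.subject_id for s in subs]


def _batch_params(theta: ThetaVector, eta5: np.ndarray,
                  code: np.ndarray) -> np.ndarray:
    """(n_subjects, 5) individual parameter matrix, PARAM_ORDER columns."""
    tv = np.array([theta.tv(p) for p in PARAM_ORDER])
    dv = np.array([theta.d(p) or 0.0 for p in PARAM_ORDER])
    scale = 1.0 + dv[None, :] * code[:, None]
    with np.errstate(over="ignore"):  # wild line-search etas are sanitized
        return tv[None, :] * scale * np.exp(eta5)


def _batch_logf_jac(batch: _Batch, P: np.ndarray):
    """Batched log-predictions and eta-Jacobian.

    Returns ``logf`` (n, t) and ``J`` (n, t, 5); padded or penalized
    points carry a zero Jacobian row.
    """
    V, CL, Tlag, Ka, F = (P[:, i:i + 1] for i in range(5))
    t = batch.t
    dose = batch.dose[:, None]
    n, t_max = t.shape

    with np.errstate(all="ignore"):  # wild trial points are sanitized below
        ke = CL / V
        logf_iv = np.log(MG_PER_L_TO_NG_PER_ML * dose / V) - ke * t
        J_iv = np.zeros((n, t_max, 5))
        J_iv[:, :, 0] = -1.0 + ke * t
        J_iv[:, :, 1] = -ke * t

        tau = t - Tlag
        ok = tau > 0
        tauc = np.where(ok, tau, 1.0)
        E1 = np.exp(-ke * tauc)
        E2 = np.exp(-Ka * tauc)
        diff = E1 - E2
        amp = (MG_PER_L_TO_NG_PER_ML * F * dose * Ka / (V * (Ka - ke)))
        logf_reg = np.log(np.abs(amp)) + np.log(np.abs(diff))
        dke = 1.0 / (Ka - ke) - tauc * E1 / diff
        dka = 1.0 / Ka - 1.0 / (Ka - ke) + tauc * E2 / diff
        dtau = (-ke * E1 + Ka * E2) / diff
        # ke -> Ka limit branch
        scale0 = MG_PER_L_TO_NG_PER_ML * F * dose / V
        logf_deg = np.log(scale0 * ke) + np.log(tauc) - ke * tauc
        dke_deg = 1.0 / ke - tauc
        dtau_deg = 1.0 / tauc - ke

        deg = np.abs(Ka - ke) < 1e-8 * ke        # (n, 1)
        logf_or = np.where(deg, logf_deg, logf_reg)
        J_or = np.zeros((n, t_max, 5))
        J_or[:, :, 0] = np.where(deg, -1.0 - ke * dke_deg, -1.0 - ke * dke)
        J_or[:, :, 1] = np.where(deg, ke * dke_deg, ke * dke)
        J_or[:, :, 2] = np.where(deg, -Tlag * dtau_deg, -Tlag * dtau)
        J_or[:, :, 3] = np.where(deg, 0.0, Ka * dka)
        J_or[:, :, 4] = 1.0
    logf_or = np.where(ok, logf_or, _PENALTY_LOGF)
    J_or *= ok[:, :, None]

    oral = batch.oral[:, None]
    logf = np.where(oral, logf_or, logf_iv)
    J = np.where(oral[:, :, None], J_or, J_iv)

    bad = (~np.isfinite(logf)) | (logf < _PENALTY_LOGF) \
        | (~np.all(np.isfinite(J), axis=2)) | (~batch.mask)
    logf = np.where(bad & batch.mask, _PENALTY_LOGF,
                    np.where(batch.mask, logf, 0.0))
    J = np.where(bad[:, :, None], 0.0, J)
    return logf, J


def _batch_evaluate(batch: _Batch, theta: ThetaVector, E: np.ndarray,
                    free_idx, omega_inv: np.ndarray, sigma: SigmaValue,
                    error: ErrorModel):
    """Joint conditional objective and residual pieces at etas ``E``."""
    n = len(batch.ids)
    eta5 = np.zeros((n, 5))
    eta5[:, free_idx] = E
    P = _batch_params(theta, eta5, batch.code)
    logf, J = _batch_logf_jac(batch, P)
    if error.log_scale:
        r = batch.logy - logf
        Jr = J[:, :, free_idx]
        f_for_var = np.exp(logf)
    else:
        f = np.exp(logf)
        r = batch.y - f
        Jr = f[:, :, None] * J[:, :, free_idx]
        f_for_var = f
    var = error.variance(f_for_var, sigma)
    m = batch.mask
    S = np.sum((r * r / var + np.log(var)) * m, axis=1) \
        + np.sum(E * E * omega_inv, axis=1)
    return S, r, Jr, var


def _batch_eta_modes(batch: _Batch, theta: ThetaVector,
                     omega_inv: np.ndarray, free_idx, sigma: SigmaValue,
                     error: ErrorModel, eta0: np.ndarray | None = None,
                     max_iter: int = 60, gtol: float = 1e-6):
    """Conditional eta modes for all subjects by damped Gauss-Newton.

    All subjects iterate together; each stops once its gradient
    infinity-norm falls under ``gtol`` or its line search stalls.
    Returns (E, r, Jr, var) at the modes.
    """
    n = len(batch.ids)
    d = len(free_idx)
    E = np.zeros((n, d)) if eta0 is None else np.array(eta0, dtype=float)
    S_cur, r, Jr, var = _batch_evaluate(
        batch, theta, E, free_idx, omega_inv, sigma, error)
    if d == 0:
        return E, r, Jr, var
    active = np.ones(n, dtype=bool)
    eye = np.eye(d)
    for _ in range(max_iter):
        W = batch.mask / var
        g = -2.0 * np.einsum("stk,st->sk", Jr, W * r) + 2.0 * omega_inv * E
        active &= np.max(np.abs(g), axis=1) > gtol
        if not active.any():
            break
        H = 2.0 * (np.einsum("stj,st,stk->sjk", Jr, W, Jr)
                   + np.diag(omega_inv)[None, :, :])
        step = np.zeros_like(E)
        try:
            step[active] = -np.linalg.solve(
                H[active], g[active][:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step[active] = -np.linalg.solve(
                H[active] + 1e-8 * eye[None, :, :],
                g[active][:, :, None])[:, :, 0]
        # vectorized backtracking on the joint objective; accepted rows
        # are spliced in so no re-evaluation at E is needed
        alpha = np.where(active, 1.0, 0.0)
        need = active.copy()
        for _ls in range(10):
            if np.max(np.abs(step[need]) * alpha[need, None]) < 1e-10:
                break
            trial = E + (alpha * need)[:, None] * step
            S_t, r_t, Jr_t, var_t = _batch_evaluate(
                batch, theta, trial, free_idx, omega_inv, sigma, error)
            better = need & (S_t < S_cur - 1e-12)
            E = np.where(better[:, None], trial, E)
            S_cur = np.where(better, S_t, S_cur)
            r = np.where(better[:, None], r_t, r)
            Jr = np.where(better[:, None, None], Jr_t, Jr)
            var = np.where(better[:, None], var_t, var)
            need &= ~better
            if not need.any():
                break
            alpha = np.where(need, alpha * 0.5, alpha)
        active &= ~need  # subjects whose line search stalled are done
    return E, r, Jr, var


def foce_marginal_neg2ll(dataset: PKDataset, theta: ThetaVector,
                         omega: OmegaMatrix, sigma: SigmaValue | float,
                         error: ErrorModel | str = "log-additive",
                         eta_warm: dict[str, np.ndarray] | None = None,
                         ) -> tuple[float, dict[str, np.ndarray]]:
    """FOCE/Laplace approximate marginal -2 log-likelihood of the dataset.

    Per subject i, with conditional mode eta_hat and Gauss-Newton
    curvature A = J'WJ + Omega^-1,

        -2LL_i = sum_j [ r_j^2/v_j + log(2 pi v_j) ]
                 + eta_hat' Omega^-1 eta_hat + log|Omega| + log|A|,

    which collapses to the eta=0 conditional -2LL as Omega -> 0.
    Returns the total and the eta modes keyed by subject id.
    """
    if isinstance(error, str):
        error = ERROR_MODELS[error]()
    if not isinstance(sigma, SigmaValue):
        sigma = SigmaValue((float(sigma),))
    if isinstance(dataset, _Batch):
        batch = dataset
    else:
        subs = dataset if isinstance(dataset, list) else _prepare(dataset)
        batch = _Batch(subs)
    free_idx = [PARAM_ORDER.index(p) for p in omega.effects]
    w2 = omega.variances(floor=_OMEGA_FLOOR)
    omega_inv = 1.0 / w2
    logdet_omega = float(np.sum(np.log(w2)))

    eta0 = None
    if eta_warm is not None and all(i in eta_warm for i in batch.ids):
        eta0 = np.array([np.asarray(eta_warm[i])[free_idx]
                         for i in batch.ids])
    E, r, Jr, var = _batch_eta_modes(
        batch, theta, omega_inv, free_idx, sigma, error, eta0=eta0)

    m = batch.mask
    quad = np.sum((r * r / var + np.log(2 * math.pi * var)) * m, axis=1)
    A = (np.einsum("stj,st,stk->sjk", Jr, m / var, Jr)
         + np.diag(omega_inv)[None, :, :])
    sign, logdet_A = np.linalg.slogdet(A)
    if np.any(sign <= 0):  # numerically indefinite curvature; ridge it
        d = len(free_idx)
        A = A + 1e-10 * np.eye(d)[None, :, :]
        sign, logdet_A = np.linalg.slogdet(A)
    total = float(np.sum(quad + np.sum(E * E * omega_inv, axis=1)
                         + logdet_omega + logdet_A))
    eta_full = np.zeros((len(batch.ids), 5))
    eta_full[:, free_idx] = E
    modes = {i: eta_full[k] for k, i in enumerate(batch.ids)}
    return total, modes


def aic(neg2ll: float, n_params: int) -> float:
    """Akaike information criterion, -2LL + 2 * number of parameters."""
    return neg2ll + 2 * n_params


def eta_shrinkage(eta_modes: dict[str, np.ndarray],
                  omega: OmegaMatrix) -> dict[str, float]:
    """Percent eta-shrinkage 100*(1 - SD(eta_hat)/omega) per effect."""
    out = {}
    etas = np.array([eta_modes[k] for k in sorted(eta_modes)])
    for p in omega.effects:
        i = PARAM_ORDER.index(p)
        w = math.sqrt(max(omega.omega2[p], _OMEGA_FLOOR))
        sd = float(np.std(etas[:, i], ddof=1)) if len(etas) > 1 else 0.0
        out[p] = 100.0 * (1.0 - sd / w)
    return out


def iiv_percent(omega: OmegaMatrix) -> dict[str, float]:
    """Apparent inter-individual variability, 100*sqrt(omega^2) percent."""
    return {p: 100.0 * math.sqrt(omega.omega2[p]) for p in omega.effects}


# ---------------------------------------------------------------------------
# transformed parameter vector <-> model parameters
# ---------------------------------------------------------------------------

class _Parameterization:
    """Maps (theta, omega, sigma) to the unconstrained-ish fitting scale.

    Typical values and sigma are estimated on the log scale; covariate
    coefficients via d = exp(q) - 1 so that 1 + d > 0 holds for both
    covariate levels; omega^2 on the log scale with a small floor.
    """

    def __init__(self, spec: ModelSpec, tlag_upper: float):
        self.spec = spec
        self.error = ERROR_MODELS[spec.error]()
        self.tlag_upper = tlag_upper
        self.names: list[str] = [f"tv{p}" for p in PARAM_ORDER]
        self.names += [f"d{p}dFormulation" for p in spec.covariates]
        self.names += [f"omega2_{p}" for p in spec.iiv]
        self.names += (["sigma"] if self.error.n_sigma == 1
                       else ["sigma_add", "sigma_prop"])
        self.n = len(self.names)

    def bounds(self) -> list[tuple[float, float]]:
        b: list[tuple[float, float]] = []
        for p in PARAM_ORDER:
            if p == "Tlag":
                b.append((math.log(1e-6), math.log(self.tlag_upper)))
            else:
                b.append((math.log(1e-4), math.log(1e4)))
        b += [(-15.0, 8.0)] * len(self.spec.covariates)
        b += [(math.log(_OMEGA_FLOOR), math.log(25.0))] * len(self.spec.iiv)
        b += [(math.log(1e-4), math.log(1e2))] * self.error.n_sigma
        return b

    def pack(self, theta: ThetaVector, omega: OmegaMatrix,
             sigma: SigmaValue) -> np.ndarray:
        x = [math.log(max(theta.tv(p), 1e-6)) if p == "Tlag"
             else math.log(theta.tv(p)) for p in PARAM_ORDER]
        for p in self.spec.covariates:
            d = theta.d(p)
            d = 0.0 if d is None else d
            x.append(math.log(1.0 + d))
        for p in self.spec.iiv:
            x.append(math.log(max(omega.omega2.get(p, 0.0), _OMEGA_FLOOR)))
        x += [math.log(max(s, 1e-4)) for s in sigma.sigma]
        return np.array(x, dtype=float)

    def unpack(self, x) -> tuple[ThetaVector, OmegaMatrix, SigmaValue]:
        x = np.asarray(x, dtype=float)
        i = 0
        tv = {}
        for p in PARAM_ORDER:
            tv[f"tv{p}"] = math.exp(x[i])
            i += 1
        dd: dict[str, float | None] = {f"d{p}": None for p in PARAM_ORDER}
        for p in self.spec.covariates:
            dd[f"d{p}"] = math.exp(x[i]) - 1.0
            i += 1
        theta = ThetaVector(**tv, **dd)
        om = {}
        for p in self.spec.iiv:
            om[p] = math.exp(x[i])
            i += 1
        omega = OmegaMatrix(om)
        sigma = SigmaValue(tuple(math.exp(v) for v in x[i:]))
        return theta, omega, sigma

    def natural(self, x) -> dict[str, float]:
        """Natural-scale parameter values keyed by self.names."""
        theta, omega, sigma = self.unpack(x)
        out: dict[str, float] = {}
        for name in self.names:
            if name.startswith("tv"):
                out[name] = theta.tv(name[2:])
            elif name.startswith("d"):
                out[name] = theta.d(name[1:].split("dFormulation")[0])
            elif name.startswith("omega2_"):
                out[name] = omega.omega2[name.split("_", 1)[1]]
            elif name == "sigma" or name == "sigma_add":
                out[name] = sigma.sigma[0]
            else:
                out[name] = sigma.sigma[1]
        return out

    def jac_natural(self, x) -> np.ndarray:
        """d(natural)/d(transformed), diagonal (delta method).

        Log-scale entries differentiate as d e^x/dx = value; covariate
        coefficients as d(e^q - 1)/dq = 1 + d.
        """
        nat = self.natural(x)
        jac = np.empty(self.n)
        for j, name in enumerate(self.names):
            jac[j] = 1.0 + nat[name] if "Formulation" in name else nat[name]
        return jac


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates and fit statistics of one FOCE run."""

    theta: ThetaVector
    omega: OmegaMatrix
    sigma: SigmaValue
    neg2ll: float
    aic: float
    ofv: float                      # alias of neg2ll; both names are used
    n_params: int
    se: dict[str, float]
    rse_percent: dict[str, float]
    eta_by_subject: dict[str, np.ndarray]
    shrinkage_percent: dict[str, float]
    iiv_percent: dict[str, float]
    converged: bool
    spec: ModelSpec
    param_names: list[str] = field(default_factory=list)
    estimates: dict[str, float] = field(default_factory=dict)
    x_transformed: np.ndarray | None = None
    n_obs: int = 0
    message: str = ""


def _naive_level_estimates(subjects) -> dict[str, float]:
    """Moment-style V/CL/Ka/F guesses from one covariate level's subjects.

    V from the back-extrapolated IV intercept, CL from the IV
    log-linear slope, F from oral AUC against the IV-derived CL, Ka
    roughly as 1/Tmax.  Used only to seed the optimizer.
    """
    out: dict[str, float] = {}
    vs, cls = [], []
    for s in subjects:
        if s.route != Route.IV_BOLUS:
            continue
        t = np.asarray(s.times)
        c = np.asarray(s.concs)
        if c[1] < c[0]:
            slope0 = (math.log(c[1]) - math.log(c[0])) / (t[1] - t[0])
            c0 = math.exp(math.log(c[0]) - slope0 * t[0])
        else:
            c0 = float(c[0])
        v = MG_PER_L_TO_NG_PER_ML * s.dose / c0
        slope = (np.log(c[0]) - np.log(c[-1])) / (t[-1] - t[0])
        vs.append(v)
        cls.append(max(float(slope), 1e-3) * v)
    if vs:
        out["V"] = float(np.median(vs))
        out["CL"] = float(np.median(cls))
    fs, kas = [], []
    for s in subjects:
        if s.route != Route.ORAL:
            continue
        t = np.asarray(s.times)
        c = np.asarray(s.concs)
        auc = float(np.trapezoid(np.concatenate([[0.0], c]),
                                 np.concatenate([[0.0], t])))
        if "CL" in out:
            fs.append(auc * out["CL"]
                      / (MG_PER_L_TO_NG_PER_ML * s.dose))
        kas.append(1.0 / max(float(t[np.argmax(c)]), 0.05))
    if fs:
        out["F"] = float(np.clip(np.median(fs), 0.01, 5.0))
    if kas:
        out["Ka"] = float(np.clip(np.median(kas), 0.05, 10.0))
    return out


def _default_start(dataset: PKDataset, spec: ModelSpec) -> tuple[
        ThetaVector, OmegaMatrix, SigmaValue]:
    """Data-driven initial values from per-level moment estimates.

    Typical values come from the reference covariate level; covariate
    coefficients in the model start at the level-1/level-0 ratio minus
    one, others at zero.
    """
    by_code: dict[int, list] = {}
    for s in dataset.subjects:
        by_code.setdefault(s.form_code, []).append(s)
    lvl0 = _naive_level_estimates(by_code.get(0, []))
    lvl1 = _naive_level_estimates(by_code.get(1, []))
    defaults = {"V": 1.0, "CL": 1.0, "Ka": 1.0, "F": 0.3}
    base = {p: lvl0.get(p, lvl1.get(p, defaults[p])) for p in defaults}
    dd = {}
    for p in spec.covariates:
        if p in lvl0 and p in lvl1 and lvl0[p] > 0:
            dd[f"d{p}"] = float(np.clip(lvl1[p] / lvl0[p] - 1.0,
                                        -0.9999, 1e4))
        else:
            dd[f"d{p}"] = 0.0
    theta = ThetaVector(
        tvV=base["V"], tvCL=base["CL"], tvTlag=1e-3, tvKa=base["Ka"],
        tvF=base["F"], **dd)
    omega = OmegaMatrix({p: 0.05 for p in spec.iiv})
    sigma = SigmaValue(
        (0.5,) if ERROR_MODELS[spec.error]().n_sigma == 1 else (0.5, 0.3))
    return theta, omega, sigma


def _finite_diff_hessian(fun, x, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            xi = np.array(x)
            if i == j:
                xp, xm = np.array(x), np.array(x)
                xp[i] += h
                xm[i] -= h
                H[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / h ** 2
            else:
                xpp, xpm, xmp, xmm = (np.array(x) for _ in range(4))
                xpp[[i, j]] += h
                xpm[i] += h
                xpm[j] -= h
                xmp[i] -= h
                xmp[j] += h
                xmm[[i, j]] -= h
                H[i, j] = H[j, i] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * h ** 2)
    return H


class PopPKModel:
    """Population PK model bound to a dataset (statsmodels-style).

    Parameters
    ----------
    dataset : PKDataset
        Validated concentration-time data with the formulation covariate.
    covariates : sequence of str
        Structural parameters carrying the formulation covariate
        (subset of ``("V", "CL", "Tlag", "Ka", "F")``).
    iiv : sequence of str
        Parameters with an exponential inter-individual random effect.
    error : str
        Residual error model name; only ``"log-additive"`` is tuned.
    """

    def __init__(self, dataset: PKDataset,
                 covariates=("V", "CL", "Ka", "F"),
                 iiv=PARAM_ORDER,
                 error: str = "log-additive"):
        dataset.validate()
        self.dataset = dataset
        self.spec = ModelSpec(covariates=tuple(covariates),
                              iiv=tuple(iiv), error=error)
        self._subs = _prepare(dataset)
        self._batch = _Batch(self._subs)
        oral_first = [s.times[0] for s in self._subs if s.oral]
        self._tlag_upper = 0.5 * min(oral_first) if oral_first else 0.25
        self.param = _Parameterization(self.spec, self._tlag_upper)

    @classmethod
    def from_csv(cls, path, contrast, **kwargs) -> "PopPKModel":
        from .data import read_dataset
        return cls(read_dataset(path, contrast), **kwargs)

    # -- likelihood -------------------------------------------------------

    def neg2ll(self, x, eta_warm=None):
        theta, omega, sigma = self.param.unpack(x)
        val, modes = foce_marginal_neg2ll(
            self._batch, theta, omega, sigma,
            error=self.param.error, eta_warm=eta_warm)
        return val, modes

    # -- fitting ----------------------------------------------------------

    def fit(self, start: ThetaVector | None = None,
            omega_start: OmegaMatrix | None = None,
            sigma_start: SigmaValue | None = None,
            maxiter: int = 400, ftol: float = 1e-9, eps: float = 1e-5,
            n_starts: int = 1, seed: int | None = None,
            polish: bool = True,
            compute_se: bool = True) -> "PopPKResults":
        """Maximize the FOCE approximate marginal likelihood.

        The quasi-Newton outer search runs on the transformed scale
        with finite-difference step ``eps``; ``polish`` reruns it once
        from the optimum with fresh conditional modes, which shakes off
        warm-start hysteresis.  Multi-start (``n_starts > 1``) perturbs
        the initial vector with seeded jitter and keeps the best
        optimum.
        """
        th0, om0, sg0 = _default_start(self.dataset, self.spec)
        if start is not None:
            dd = {f"d{p}": (start.d(p) if start.d(p) is not None else 0.0)
                  for p in self.spec.covariates}
            dn = {f"d{p}": None for p in PARAM_ORDER
                  if p not in self.spec.covariates}
            th0 = replace(start, **dd, **dn)
        if omega_start is not None:
            om0 = OmegaMatrix({p: omega_start.omega2.get(p, 0.01)
                               for p in self.spec.iiv})
        else:
            om0 = OmegaMatrix({p: om0.omega2[p] for p in self.spec.iiv})
        if sigma_start is not None:
            sg0 = sigma_start

        x0 = self.param.pack(th0, om0, sg0)
        bounds = self.param.bounds()
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(n_starts - 1):
            starts.append(np.clip(x0 + rng.normal(0, 0.3, len(x0)),
                                  [b[0] for b in bounds],
                                  [b[1] for b in bounds]))

        def run_lbfgs(x_init):
            warm: dict[str, np.ndarray] = {}

            def objective(x):
                val, modes = self.neg2ll(x, eta_warm=warm)
                warm.update(modes)
                return val

            res = optimize.minimize(
                objective, x_init, method="L-BFGS-B", bounds=bounds,
                options=dict(maxiter=maxiter, ftol=ftol, maxcor=25,
                             eps=eps))
            return res, warm

        best = None
        for xs in starts:
            res, warm = run_lbfgs(xs)
            if best is None or res.fun < best[0].fun:
                best = (res, warm)
        if polish:
            res2, warm2 = run_lbfgs(best[0].x)
            if res2.fun < best[0].fun:
                best = (res2, warm2)
        res, warm = best

        xhat = res.x
        theta, omega, sigma = self.param.unpack(xhat)
        neg2, modes = self.neg2ll(xhat, eta_warm=warm)
        n_params = self.spec.n_params

        se: dict[str, float] = {}
        rse: dict[str, float] = {}
        if compute_se:
            warm_se = dict(modes)

            def fun_se(x):
                v, m = self.neg2ll(x, eta_warm=warm_se)
                return v

            H = _finite_diff_hessian(fun_se, xhat, h=1e-4)
            # covariance of the transformed estimates: 2 * H^-1 since the
            # objective is -2 log L
            try:
                cov_x = 2.0 * np.linalg.inv(H)
                var_x = np.clip(np.diag(cov_x), 0.0, None)
            except np.linalg.LinAlgError:
                var_x = np.full(len(xhat), np.nan)
            jac = self.param.jac_natural(xhat)
            se_nat = np.sqrt(var_x) * np.abs(jac)
            nat = self.param.natural(xhat)
            for j, name in enumerate(self.param.names):
                se[name] = float(se_nat[j])
                est = nat[name]
                rse[name] = (100.0 * se_nat[j] / abs(est)
                             if abs(est) > 1e-12 else float("nan"))

        fr = FitResult(
            theta=theta, omega=omega, sigma=sigma,
            neg2ll=float(neg2), aic=aic(float(neg2), n_params),
            ofv=float(neg2), n_params=n_params,
            se=se, rse_percent=rse,
            eta_by_subject=modes,
            shrinkage_percent=eta_shrinkage(modes, omega),
            iiv_percent=iiv_percent(omega),
            converged=bool(res.success),
            spec=self.spec,
            param_names=list(self.param.names),
            estimates=self.param.natural(xhat),
            x_transformed=xhat,
            n_obs=self.dataset.n_observations,
            message=str(res.message),
        )
        return PopPKResults(self, fr)


class PopPKResults:
    """Fitted population PK model: estimates, uncertainty, diagnostics."""

    def __init__(self, model: PopPKModel, fit: FitResult):
        self.model = model
        self.fit_result = fit

    # convenient passthroughs -------------------------------------------
    @property
    def theta(self) -> ThetaVector:
        return self.fit_result.theta

    @property
    def omega(self) -> OmegaMatrix:
        return self.fit_result.omega

    @property
    def sigma(self) -> SigmaValue:
        return self.fit_result.sigma

    @property
    def neg2ll(self) -> float:
        return self.fit_result.neg2ll

    @property
    def ofv(self) -> float:
        return self.fit_result.ofv

    @property
    def aic(self) -> float:
        return self.fit_result.aic

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def estimates(self) -> dict[str, float]:
        return self.fit_result.estimates

    def summary(self) -> str:
        """Parameter table: Estimate, SE, RSE%, Shrinkage%, IIV%."""
        from .pipeline import render_parameter_table
        return render_parameter_table(self.fit_result)

    def to_dict(self) -> dict:
        fr = self.fit_result
        return dict(
            estimates=fr.estimates,
            se=fr.se,
            rse_percent=fr.rse_percent,
            shrinkage_percent=fr.shrinkage_percent,
            iiv_percent=fr.iiv_percent,
            neg2ll=fr.neg2ll, aic=fr.aic, ofv=fr.ofv,
            n_params=fr.n_params, n_obs=fr.n_obs,
            converged=fr.converged,
            spec=dict(covariates=list(fr.spec.covariates),
                      iiv=list(fr.spec.iiv), error=fr.spec.error),
        )

    # diagnostics --------------------------------------------------------
    def gof(self):
        from .diagnostics import gof_table
        return gof_table(self, self.model.dataset)

    def vpc(self, n_sim: int = 1000, seed: int = 0, stratify: bool = False):
        from .diagnostics import vpc
        return vpc(self, self.model.dataset, n_sim=n_sim, seed=seed,
                   stratify=stratify)

    def bootstrap(self, n_rep: int = 1000, seed: int = 0, **kwargs):
        from .diagnostics import bootstrap
        return bootstrap(self, self.model.dataset, n_rep=n_rep, seed=seed,
                         **kwargs)

    def npde(self, n_sim: int = 1000, seed: int = 0):
        from .diagnostics import npde
        return npde(self, self.model.dataset, n_sim=n_sim, seed=seed)
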