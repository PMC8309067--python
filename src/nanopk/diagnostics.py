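"""Model evaluation: goodness-of-fit, VPC, bootstrap, and NPDE.

All diagnostics are pure functions of (fitted results, dataset, seed):
rerunning with the same seed reproduces the output exactly.  Monte
Carlo machinery works on the log-concentration scale throughout, which
matches the log-additive residual error model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import PKDataset
from .model import (OmegaMatrix, PARAM_ORDER, PopPKResults, SigmaValue,
                    ThetaVector, _logf_and_jac, _prepare, individual_params)

__all__ = [
    "GofTable",
    "VpcResult",
    "BootstrapResult",
    "NpdeResult",
    "gof_table",
    "vpc",
    "bootstrap",
    "npde",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class GofTable:
    """Observation-level PRED/IPRED/CWRES table."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def _omega_vector(omega: OmegaMatrix) -> np.ndarray:
    return np.array([omega.omega2.get(p, 0.0) for p in PARAM_ORDER])


def gof_table(fit: PopPKResults, dataset: PKDataset) -> GofTable:
    """PRED (eta=0), IPRED (eta_hat), and conditional weighted residuals.

    CWRES follow the FOCE linearization on the log scale: for subject i
    with Jacobian J_i = d log f / d eta at eta_hat,

        res_i  = log y_i - (log f_i(eta_hat) - J_i eta_hat)
        Cov_i  = J_i Omega J_i' + sigma^2 I
        cwres  = Cov_i^(-1/2) res_i    (symmetric matrix square root).

    A numerically singular Cov_i is ridged by 1e-10 with a warning.
    With Omega = 0 this collapses to (log y - log f)/sigma.
    """
    theta, omega, sigma = fit.theta, fit.omega, fit.sigma
    w2 = _omega_vector(omega)
    s2 = sigma.value ** 2
    rows = []
    for sub in _prepare(dataset):
        eta = fit.fit_result.eta_by_subject.get(sub.subject_id, np.zeros(5))
        p_pop = individual_params(theta, np.zeros(5), sub.form_code)
        p_ind = individual_params(theta, eta, sub.form_code)
        logf_pop, _ = _logf_and_jac(sub, p_pop)
        logf_ind, J = _logf_and_jac(sub, p_ind)
        res = np.log(sub.y) - (logf_ind - J @ eta)
        cov = J @ np.diag(w2) @ J.T + s2 * np.eye(len(sub.y))
        vals, vecs = np.linalg.eigh(cov)
        if vals.min() <= 0:
            log.warning("subject %s: singular CWRES covariance; "
                        "ridged by 1e-10", sub.subject_id)
            vals = vals + 1e-10
        inv_sqrt = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T
        cw = inv_sqrt @ res
        for j in range(len(sub.y)):
            rows.append(dict(
                subject_id=sub.subject_id, time=sub.times[j], dv=sub.y[j],
                pred=math.exp(logf_pop[j]), ipred=math.exp(logf_ind[j]),
                cwres=cw[j]))
    return GofTable(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# simulation helper shared by VPC and NPDE
# ---------------------------------------------------------------------------

def _simulate_log_obs(rng: np.random.Generator, theta: ThetaVector,
                      omega: OmegaMatrix, sigma: SigmaValue,
                      subs) -> list[np.ndarray]:
    """One replicate of log-scale observations on the original design."""
    sd_eta = np.sqrt(_omega_vector(omega))
    sig = sigma.value
    out = []
    for sub in subs:
        eta = rng.normal(0.0, 1.0, size=5) * sd_eta
        p = individual_params(theta, eta, sub.form_code)
        logf, _ = _logf_and_jac(sub, p)
        out.append(logf + rng.normal(0.0, sig, size=len(sub.times)))
    return out


# ---------------------------------------------------------------------------
# visual predictive check
# ---------------------------------------------------------------------------

@dataclass
class VpcResult:
    """Percentile bands per nominal time bin (optionally per stratum).

    ``bands`` columns: stratum, time, obs_p5/p50/p95, and for each
    simulated percentile its across-replicate median and 95% CI.
    ``coverage`` is the fraction of observations inside the simulated
    5th-95th band of their own bin.
    """

    bands: pd.DataFrame
    coverage: float
    n_sim: int


_PCTS = (5.0, 50.0, 95.0)


def vpc(fit: PopPKResults, dataset: PKDataset, n_sim: int = 1000,
        seed: int = 0, stratify: bool = False) -> VpcResult:
    """Visual predictive check binned on the nominal design times.

    ``n_sim`` replicate datasets are simulated at the estimates on the
    original design; per time bin the observed 5/50/95 percentiles are
    set against the across-replicate median and 95% CI of each
    simulated percentile.  Percentiles interpolate linearly between
    order statistics.  ``stratify`` splits by formulation.
    """
    if n_sim < 100:
        log.warning("vpc: n_sim=%d < 100 gives unstable confidence bands",
                    n_sim)
    rng = np.random.default_rng(seed)
    subs = _prepare(dataset)
    strata = (lambda s: s.record.formulation.value) if stratify \
        else (lambda s: "all")

    # replicate simulations, natural scale
    sims = []
    for _ in range(n_sim):
        rep = _simulate_log_obs(rng, fit.theta, fit.omega, fit.sigma, subs)
        sims.append([np.exp(v) for v in rep])

    rows = []
    n_inside = 0
    n_total = 0
    for stratum in sorted({strata(s) for s in subs}):
        members = [i for i, s in enumerate(subs) if strata(s) == stratum]
        times = sorted({t for i in members for t in subs[i].times})
        for t in times:
            idx = [(i, j) for i in members
                   for j, tj in enumerate(subs[i].times) if tj == t]
            obs = np.array([subs[i].y[j] for i, j in idx])
            sim_pct = np.array([
                np.percentile([rep[i][j] for i, j in idx], _PCTS)
                for rep in sims
            ])  # (n_sim, 3)
            med = np.median(sim_pct, axis=0)
            lo = np.percentile(sim_pct, 2.5, axis=0)
            hi = np.percentile(sim_pct, 97.5, axis=0)
            obs_pct = np.percentile(obs, _PCTS)
            band_lo, band_hi = med[0], med[2]
            n_inside += int(np.sum((obs >= band_lo) & (obs <= band_hi)))
            n_total += len(obs)
            row = dict(stratum=stratum, time=t, n_obs=len(obs))
            for k, pct in enumerate(("p5", "p50", "p95")):
                row[f"obs_{pct}"] = obs_pct[k]
                row[f"sim_{pct}_median"] = med[k]
                row[f"sim_{pct}_lo"] = lo[k]
                row[f"sim_{pct}_hi"] = hi[k]
            rows.append(row)
    return VpcResult(bands=pd.DataFrame(rows),
                     coverage=n_inside / n_total, n_sim=n_sim)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Percentile bootstrap of the parameter estimates.

    ``table`` columns: parameter, estimate, median, ci_lo, ci_hi
    (2.5th/97.5th percentiles over successful replicates).
    """

    table: pd.DataFrame
    n_success: int
    n_failed: int
    replicates: pd.DataFrame = field(repr=False, default=None)

    def estimate_within_ci(self, rtol: float = 1e-3,
                           atol: float = 1e-8) -> bool:
        """Whether every original estimate lies in its own 95% interval.

        Comparison carries a small tolerance: parameters pinned at a
        bound (floored variances, near-zero lag) give degenerate
        intervals whose sub-rtol misses reflect optimizer termination
        noise, not inference.
        """
        t = self.table
        slack = atol + rtol * t["estimate"].abs()
        return bool(np.all((t["estimate"] >= t["ci_lo"] - slack)
                           & (t["estimate"] <= t["ci_hi"] + slack)))


def bootstrap(fit: PopPKResults, dataset: PKDataset, n_rep: int = 1000,
              seed: int = 0, maxiter: int = 60, ftol: float = 1e-7,
              eps: float = 1e-4) -> BootstrapResult:
    """Nonparametric subject-level bootstrap, stratified by study arm.

    Subjects are resampled with replacement within each
    (formulation, route) arm, preserving per-arm n so every covariate
    level stays estimable; each replicate is refit warm-started at the
    original estimates.  Replicates whose refit raises are dropped and
    counted in ``n_failed``.
    """
    from .data import PKDataset as DS, SubjectRecord
    from .model import PopPKModel

    rng = np.random.default_rng(seed)
    arms = dataset.arms()
    est0 = fit.fit_result.estimates
    rows = []
    n_failed = 0
    for rep in range(n_rep):
        subjects = []
        k = 0
        for arm_subjects in arms.values():
            picks = rng.integers(0, len(arm_subjects), len(arm_subjects))
            for pick in picks:
                src = arm_subjects[pick]
                k += 1
                sid = f"B{k:03d}"
                subjects.append(SubjectRecord(
                    subject_id=sid, formulation=src.formulation,
                    form_code=src.form_code,
                    dose_events=[type(d)(sid, d.time, d.amount, d.route)
                                 for d in src.dose_events],
                    observations=[type(o)(sid, o.time, o.conc)
                                  for o in src.observations]))
        ds = DS(subjects=subjects, contrast=dataset.contrast)
        try:
            model = PopPKModel(ds, covariates=fit.model.spec.covariates,
                               iiv=fit.model.spec.iiv,
                               error=fit.model.spec.error)
            r = model.fit(start=fit.theta, omega_start=fit.omega,
                          sigma_start=fit.sigma, compute_se=False,
                          maxiter=maxiter, ftol=ftol, eps=eps,
                          polish=False)
            rows.append(dict(replicate=rep, **r.fit_result.estimates))
        except Exception as exc:  # noqa: BLE001 - count and continue
            log.warning("bootstrap replicate %d failed: %s", rep, exc)
            n_failed += 1
    reps = pd.DataFrame(rows)
    out_rows = []
    for name in fit.fit_result.param_names:
        vals = reps[name].to_numpy()
        out_rows.append(dict(
            parameter=name, estimate=est0[name],
            median=float(np.median(vals)),
            ci_lo=float(np.percentile(vals, 2.5)),
            ci_hi=float(np.percentile(vals, 97.5))))
    return BootstrapResult(table=pd.DataFrame(out_rows),
                           n_success=len(reps), n_failed=n_failed,
                           replicates=reps)


# ---------------------------------------------------------------------------
# normalized prediction distribution error
# ---------------------------------------------------------------------------

@dataclass
class NpdeResult:
    """Per-observation NPDE values plus the three global tests.

    Tests: Shapiro-Wilk normality, t-test for mean 0, and a two-sided
    chi-square variance test against 1 (the variance test named after
    Fisher in the pharmacometric evaluation convention).
    """

    table: pd.DataFrame
    shapiro_p: float
    t_test_p: float
    variance_p: float

    @property
    def values(self) -> np.ndarray:
        return self.table["npde"].to_numpy()

    @property
    def global_pass(self) -> bool:
        return bool(min(self.shapiro_p, self.t_test_p,
                        self.variance_p) > 0.05)


def npde(fit: PopPKResults, dataset: PKDataset, n_sim: int = 1000,
         seed: int = 0) -> NpdeResult:
    """Normalized prediction distribution errors on the log scale.

    Per subject, ``n_sim`` replicate observation vectors are simulated
    at the estimates; observed and simulated vectors are decorrelated
    with the simulated mean and the Cholesky factor of the simulated
    covariance; pd_ij is the fraction of decorrelated simulated values
    below the decorrelated observation, clamped to
    [1/(2 n_sim), 1 - 1/(2 n_sim)]; npde = Phi^-1(pd).
    """
    rng = np.random.default_rng(seed)
    subs = _prepare(dataset)
    sd_eta = np.sqrt(_omega_vector(fit.omega))
    sig = fit.sigma.value

    rows = []
    for sub in subs:
        n_obs = len(sub.times)
        if n_sim < n_obs:
            log.warning("subject %s: n_sim=%d < %d observations; simulated "
                        "covariance is rank-deficient", sub.subject_id,
                        n_sim, n_obs)
        sims = np.empty((n_sim, n_obs))
        for r in range(n_sim):
            eta = rng.normal(0.0, 1.0, size=5) * sd_eta
            p = individual_params(fit.theta, eta, sub.form_code)
            logf, _ = _logf_and_jac(sub, p)
            sims[r] = logf + rng.normal(0.0, sig, size=n_obs)
        mean = sims.mean(axis=0)
        cov = np.cov(sims, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov) + 1e-10 * np.eye(n_obs)
        L = np.linalg.cholesky(cov)
        dec_obs = np.linalg.solve(L, np.log(sub.y) - mean)
        dec_sims = np.linalg.solve(L, (sims - mean).T).T
        pd_ij = (dec_sims < dec_obs).mean(axis=0)
        eps = 1.0 / (2.0 * n_sim)
        pd_ij = np.clip(pd_ij, eps, 1.0 - eps)
        vals = stats.norm.ppf(pd_ij)
        for j in range(n_obs):
            rows.append(dict(subject_id=sub.subject_id, time=sub.times[j],
                             npde=vals[j]))
    table = pd.DataFrame(rows)
    v = table["npde"].to_numpy()
    shapiro_p = float(stats.shapiro(v).pvalue)
    t_p = float(stats.ttest_1samp(v, 0.0).pvalue)
    n = len(v)
    chi2_stat = (n - 1) * np.var(v, ddof=1)
    variance_p = float(2 * min(stats.chi2.cdf(chi2_stat, n - 1),
                               stats.chi2.sf(chi2_stat, n - 1)))
    return NpdeResult(table=table, shapiro_p=shapiro_p, t_test_p=t_p,
                      variance_p=variance_p)
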