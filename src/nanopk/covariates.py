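"""Stepwise formulation-covariate selection by objective-function change.

Forward addition / backward elimination over formulation-on-parameter
effects, with inclusion judged by the drop in the objective function
value (OFV, the minimized -2 log-likelihood) against chi-square(1)
critical values: 3.84 at p < 0.05 for forward addition, 6.63 at
p < 0.01 for backward elimination.  The search is greedy
largest-drop-first; ties break toward fewer parameters, then
alphabetical parameter name.  Every model tried is recorded in a
ledger of :class:`CovariateStep` rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .data import PKDataset
from .model import ModelSpec, PopPKModel, PopPKResults, ThetaVector

__all__ = [
    "CovariateStep",
    "StepwiseResult",
    "chi2_threshold",
    "forward_addition",
    "backward_elimination",
    "stepwise",
    "FORWARD_ALPHA",
    "BACKWARD_ALPHA",
]

log = logging.getLogger(__name__)

FORWARD_ALPHA = 0.05    # OFV drop > 3.84 to enter
BACKWARD_ALPHA = 0.01   # OFV rise > 6.63 on removal to stay


def chi2_threshold(alpha: float, df: int = 1) -> float:
    """Chi-square critical OFV change, rounded to 2 decimals for reporting."""
    return round(float(stats.chi2.ppf(1.0 - alpha, df)), 2)


@dataclass
class CovariateStep:
    """One row of the search ledger."""

    model_label: str
    description: str
    ofv: float
    delta_ofv: float | None
    comparator_label: str | None
    n_params: int
    accepted: bool
    covariates: tuple[str, ...] = ()


@dataclass
class StepwiseResult:
    """Final covariate set plus the full ledger of models tried."""

    final_covariates: tuple[str, ...]
    final_fit: PopPKResults | None
    ledger: list[CovariateStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            dict(Model=s.model_label, Description=s.description,
                 OFV=s.ofv,
                 dOFV=(float("nan") if s.delta_ofv is None else s.delta_ofv),
                 Compared_with=s.comparator_label or "-",
                 n_Parameter=s.n_params, Accepted=s.accepted)
            for s in self.ledger
        ])


def _describe(covs: tuple[str, ...]) -> str:
    if not covs:
        return "Base model"
    return "Formulation on " + " & ".join(covs)


def _fit_spec(dataset: PKDataset, base: ModelSpec,
              covariates: tuple[str, ...],
              warm: PopPKResults | None,
              fit_kwargs: dict) -> PopPKResults:
    model = PopPKModel(dataset, covariates=covariates, iiv=base.iiv,
                       error=base.error)
    start = None
    omega_start = sigma_start = None
    if warm is not None:
        # warm-start from the incumbent's estimates; new coefficients at 0
        t = warm.theta
        start = ThetaVector(
            tvV=t.tvV, tvCL=t.tvCL, tvTlag=t.tvTlag, tvKa=t.tvKa, tvF=t.tvF,
            **{f"d{p}": (t.d(p) if t.d(p) is not None else 0.0)
               for p in covariates})
        omega_start = warm.omega
        sigma_start = warm.sigma
    return model.fit(start=start, omega_start=omega_start,
                     sigma_start=sigma_start, compute_se=False, **fit_kwargs)


def forward_addition(dataset: PKDataset, base_spec: ModelSpec,
                     candidates, fit_kwargs: dict | None = None,
                     ledger: list[CovariateStep] | None = None,
                     base_fit: PopPKResults | None = None,
                     ) -> tuple[tuple[str, ...], PopPKResults,
                                list[CovariateStep]]:
    """Greedy forward covariate addition at the p < 0.05 threshold.

    At each round every remaining candidate is added to the incumbent
    and refit (warm-started); the candidate with the largest OFV drop
    enters if the drop exceeds chi2(1, 0.05) = 3.84.  A failing
    candidate fit is skipped with a warning.  Returns the included
    set, the incumbent fit, and the ledger.
    """
    fit_kwargs = fit_kwargs or {}
    ledger = ledger if ledger is not None else []
    threshold = chi2_threshold(FORWARD_ALPHA)
    candidates = sorted(set(candidates))

    if base_fit is None:
        base_fit = _fit_spec(dataset, base_spec, base_spec.covariates,
                             None, fit_kwargs)
    included = tuple(base_spec.covariates)
    incumbent = base_fit
    label = "base"
    ledger.append(CovariateStep(
        model_label=label, description=_describe(included),
        ofv=incumbent.ofv, delta_ofv=None, comparator_label=None,
        n_params=incumbent.fit_result.n_params, accepted=True,
        covariates=included))

    remaining = [c for c in candidates if c not in included]
    step_no = 0
    while remaining:
        step_no += 1
        trials = []
        for c in remaining:
            covs = tuple(sorted(included + (c,)))
            try:
                fit = _fit_spec(dataset, base_spec, covs, incumbent,
                                fit_kwargs)
            except Exception as exc:  # noqa: BLE001 - search must go on
                log.warning("forward addition: candidate %s failed (%s); "
                            "skipped", c, exc)
                continue
            drop = incumbent.ofv - fit.ofv
            trials.append((c, covs, fit, drop))
            ledger.append(CovariateStep(
                model_label=f"fwd{step_no}-{c}",
                description=_describe(covs),
                ofv=fit.ofv, delta_ofv=fit.ofv - incumbent.ofv,
                comparator_label=label,
                n_params=fit.fit_result.n_params,
                accepted=False, covariates=covs))
        # largest drop first; ties -> fewer params then alphabetical name
        qualifying = [t for t in trials if t[3] > threshold]
        if not qualifying:
            break
        qualifying.sort(key=lambda t: (-t[3], len(t[1]), t[0]))
        c, covs, fit, drop = qualifying[0]
        for s in ledger:
            if s.model_label == f"fwd{step_no}-{c}":
                s.accepted = True
        included, incumbent, label = covs, fit, f"fwd{step_no}-{c}"
        remaining = [x for x in remaining if x != c]
    return included, incumbent, ledger


def backward_elimination(dataset: PKDataset, full_spec: ModelSpec,
                         fit_kwargs: dict | None = None,
                         ledger: list[CovariateStep] | None = None,
                         full_fit: PopPKResults | None = None,
                         ) -> tuple[tuple[str, ...], PopPKResults,
                                    list[CovariateStep]]:
    """Backward elimination at the stricter p < 0.01 threshold.

    Each included effect is removed in turn; an effect whose removal
    raises the OFV by more than chi2(1, 0.01) = 6.63 is retained.  The
    non-significant effect with the smallest OFV rise leaves first;
    the loop refits until stable.
    """
    fit_kwargs = fit_kwargs or {}
    ledger = ledger if ledger is not None else []
    threshold = chi2_threshold(BACKWARD_ALPHA)

    included = tuple(sorted(full_spec.covariates))
    if full_fit is None:
        full_fit = _fit_spec(dataset, full_spec, included, None, fit_kwargs)
    incumbent = full_fit
    label = "full"
    step_no = 0
    while included:
        step_no += 1
        trials = []
        for c in included:
            covs = tuple(x for x in included if x != c)
            try:
                fit = _fit_spec(dataset, full_spec, covs, incumbent,
                                fit_kwargs)
            except Exception as exc:  # noqa: BLE001
                log.warning("backward elimination: removal of %s failed "
                            "(%s); effect retained", c, exc)
                continue
            rise = fit.ofv - incumbent.ofv
            trials.append((c, covs, fit, rise))
            ledger.append(CovariateStep(
                model_label=f"bwd{step_no}-{c}",
                description=f"Remove formulation on {c}",
                ofv=fit.ofv, delta_ofv=rise, comparator_label=label,
                n_params=fit.fit_result.n_params,
                accepted=False, covariates=covs))
        removable = [t for t in trials if t[3] <= threshold]
        if not removable:
            break
        removable.sort(key=lambda t: (t[3], t[0]))
        c, covs, fit, rise = removable[0]
        for s in ledger:
            if s.model_label == f"bwd{step_no}-{c}":
                s.accepted = True
        included, incumbent, label = covs, fit, f"bwd{step_no}-{c}"
    return included, incumbent, ledger


def stepwise(dataset: PKDataset, base_spec: ModelSpec, candidates,
             fit_kwargs: dict | None = None) -> StepwiseResult:
    """Forward addition then backward elimination; full ledger kept."""
    if dataset.n_subjects < 2:
        raise ValueError("stepwise covariate search needs >= 2 subjects")
    ledger: list[CovariateStep] = []
    included, incumbent, ledger = forward_addition(
        dataset, base_spec, candidates, fit_kwargs, ledger)
    if included:
        full_spec = ModelSpec(covariates=included, iiv=base_spec.iiv,
                              error=base_spec.error)
        included, incumbent, ledger = backward_elimination(
            dataset, full_spec, fit_kwargs, ledger, full_fit=incumbent)
    return StepwiseResult(final_covariates=included, final_fit=incumbent,
                          ledger=ledger)
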