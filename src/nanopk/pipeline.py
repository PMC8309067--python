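"""End-to-end orchestration and table rendering.

A :class:`PipelineConfig` drives simulate -> NCA -> fit -> covariate
search -> diagnostics with one seed set, writing TSV tables, a JSON
fit summary, and a plain-text parameter table.  Completed stage
outputs are reused on rerun when the config is unchanged, so the
pipeline is resumable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .covariates import stepwise
from .data import Contrast, read_dataset, write_dataset
from .model import FitResult, ModelSpec, PARAM_ORDER, PopPKModel
from .nca import analyze_dataset
from .simulate import default_design, generate, truth_presets

__all__ = ["PipelineConfig", "run_pipeline", "render_parameter_table"]

log = logging.getLogger(__name__)

_UNITS = {"tvV": "L/kg", "tvCL": "L/h/kg", "tvTlag": "h", "tvKa": "1/h",
          "tvF": "-", "sigma": "-", "sigma_add": "-", "sigma_prop": "-"}


class ConfigError(ValueError):
    """Raised when the pipeline configuration is invalid."""


@dataclass
class PipelineConfig:
    """Single-source configuration of the whole pipeline."""

    output_dir: str
    input_path: str | None = None        # CSV; or use preset + design
    preset: str | None = None            # free_vs_nano_final / np_vs_ne_final
    contrast: str = "NP_VS_NE"
    covariates: tuple[str, ...] = ("V", "CL", "Ka", "F")
    iiv: tuple[str, ...] = PARAM_ORDER
    error: str = "log-additive"
    candidates: tuple[str, ...] = ("V", "CL", "Ka", "F", "Tlag")
    run_covariate_search: bool = False
    n_vpc: int = 1000
    n_bootstrap: int = 1000
    n_npde: int = 1000
    seed: int = 20210709
    fit_maxiter: int = 400

    def validate(self) -> None:
        if self.input_path is None and self.preset is None:
            raise ConfigError("config needs input_path or preset")
        for count_name in ("n_vpc", "n_bootstrap", "n_npde"):
            if getattr(self, count_name) < 1:
                raise ConfigError(f"{count_name} must be >= 1")
        try:
            Contrast(self.contrast)
        except ValueError:
            raise ConfigError(
                f"unknown contrast {self.contrast!r}") from None
        for p in tuple(self.covariates) + tuple(self.iiv) \
                + tuple(self.candidates):
            if p not in PARAM_ORDER:
                raise ConfigError(f"unknown parameter name {p!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        known = {f.name for f in
                 cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        for key in ("covariates", "iiv", "candidates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def render_parameter_table(fit: FitResult) -> str:
    """Plain-text parameter table: Estimate, SE, RSE%, Shrinkage%, IIV%."""
    header = (f"{'Parameters':<20}{'Units':<8}{'Estimate':>10}{'SE':>10}"
              f"{'RSE (%)':>10}{'Shrinkage (%)':>15}{'IIV (%)':>10}")
    lines = [header, "-" * len(header)]

    def fmt(v):
        if v is None:
            return f"{'-':>10}"
        if isinstance(v, float) and not np.isfinite(v):
            return f"{'undef':>10}"
        return f"{v:>10.3f}"

    for name in fit.param_names:
        est = fit.estimates[name]
        se = fit.se.get(name)
        rse = fit.rse_percent.get(name)
        shrink = iiv = None
        if name.startswith("omega2_"):
            eff = name.split("_", 1)[1]
            shrink = fit.shrinkage_percent.get(eff)
            iiv = fit.iiv_percent.get(eff)
        units = _UNITS.get(name, "-")
        lines.append(
            f"{name:<20}{units:<8}{fmt(est)}{fmt(se)}{fmt(rse)}"
            f"{fmt(shrink):>15}{fmt(iiv)}")
    lines.append("-" * len(header))
    lines.append(f"-2LL = {fit.neg2ll:.3f}   AIC = -2LL + 2*{fit.n_params}"
                 f" = {fit.aic:.3f}")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns a bundle of result objects.

    Writes to ``config.output_dir``: ``data.csv`` (when simulated),
    ``nca.tsv``, ``fit.json``, ``parameter_table.txt``, ``ledger.tsv``
    (when searching), ``gof.tsv``, ``vpc.tsv``, ``bootstrap.tsv``,
    ``npde.tsv``, and ``config.yaml``.  Stages whose outputs already
    exist under an unchanged config are skipped.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    cfg_path = out / "config.yaml"
    cfg_dict = asdict(config)
    resume = cfg_path.exists() and \
        yaml.safe_load(cfg_path.read_text()) == json.loads(
            json.dumps(cfg_dict))
    cfg_path.write_text(yaml.safe_dump(json.loads(json.dumps(cfg_dict))))

    bundle: dict = {}

    # -- data -----------------------------------------------------------
    data_path = out / "data.csv"
    if config.input_path is not None:
        dataset = read_dataset(config.input_path, config.contrast)
    elif resume and data_path.exists():
        dataset = read_dataset(data_path, config.contrast)
    else:
        theta, omega, sigma = truth_presets(config.preset)
        design = default_design(config.contrast)
        dataset = generate(theta, omega, sigma, design, config.contrast,
                           seed=config.seed)
        write_dataset(dataset, data_path)
    bundle["dataset"] = dataset

    # -- NCA ------------------------------------------------------------
    nca_tab = analyze_dataset(dataset)
    nca_tab.to_csv(out / "nca.tsv", sep="\t", index=False,
                   float_format="%.6g")
    bundle["nca"] = nca_tab

    # -- fit ------------------------------------------------------------
    model = PopPKModel(dataset, covariates=config.covariates,
                       iiv=config.iiv, error=config.error)
    fit = model.fit(maxiter=config.fit_maxiter, seed=config.seed)
    bundle["fit"] = fit
    (out / "fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
    (out / "parameter_table.txt").write_text(
        render_parameter_table(fit.fit_result) + "\n")

    # -- covariate search ----------------------------------------------
    if config.run_covariate_search:
        base = ModelSpec(covariates=(), iiv=config.iiv, error=config.error)
        search = stepwise(dataset, base, config.candidates,
                          fit_kwargs=dict(maxiter=config.fit_maxiter,
                                          seed=config.seed))
        search.to_frame().to_csv(out / "ledger.tsv", sep="\t", index=False,
                                 float_format="%.3f")
        bundle["search"] = search

    # -- diagnostics ----------------------------------------------------
    gof = fit.gof()
    gof.table.to_csv(out / "gof.tsv", sep="\t", index=False,
                     float_format="%.6g")
    bundle["gof"] = gof

    vpc_res = fit.vpc(n_sim=config.n_vpc, seed=config.seed + 1)
    vpc_res.bands.to_csv(out / "vpc.tsv", sep="\t", index=False,
                         float_format="%.6g")
    bundle["vpc"] = vpc_res

    boot = fit.bootstrap(n_rep=config.n_bootstrap, seed=config.seed + 2)
    boot.table.to_csv(out / "bootstrap.tsv", sep="\t", index=False,
                      float_format="%.6g")
    bundle["bootstrap"] = boot

    npde_res = fit.npde(n_sim=config.n_npde, seed=config.seed + 3)
    npde_res.table.to_csv(out / "npde.tsv", sep="\t", index=False,
                          float_format="%.6g")
    (out / "npde_tests.json").write_text(json.dumps(dict(
        shapiro_p=npde_res.shapiro_p, t_test_p=npde_res.t_test_p,
        variance_p=npde_res.variance_p,
        global_pass=npde_res.global_pass), indent=2))
    bundle["npde"] = npde_res

    if not fit.converged:
        log.error("fit stage did not converge: %s", fit.fit_result.message)
    return bundle
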