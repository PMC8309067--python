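"""Shared fixtures: all datasets are generated in-process, never stored."""

from __future__ import annotations

import numpy as np
import pytest

from nanopk.data import (Contrast, DoseEvent, Formulation, ObservationRow,
                         Route, SubjectRecord)
from nanopk.model import PopPKModel
from nanopk.simulate import default_design, generate, truth_presets

#: one seed for every deterministic simulation experiment in the suite
SUITE_SEED = 1


def make_iv_subject(subject_id="R1", dose=5.0, v=18.832, cl=9.167,
                    times=(0.25, 0.5, 1.0, 2.0, 4.0, 8.0),
                    formulation=Formulation.NANOPARTICLE, form_code=0):
    """Noiseless mono-exponential IV subject from the structural model."""
    ke = cl / v
    c0 = 1000.0 * dose / v
    obs = [ObservationRow(subject_id, t, c0 * np.exp(-ke * t))
           for t in times]
    return SubjectRecord(
        subject_id=subject_id, formulation=formulation, form_code=form_code,
        dose_events=[DoseEvent(subject_id, 0.0, dose, Route.IV_BOLUS)],
        observations=obs)


@pytest.fixture(scope="session")
def np_vs_ne_truth():
    return truth_presets("np_vs_ne_final")


@pytest.fixture(scope="session")
def sim_dataset(np_vs_ne_truth):
    """One NP-vs-NE study simulated from the published final estimates."""
    theta, omega, sigma = np_vs_ne_truth
    return generate(theta, omega, sigma, default_design(Contrast.NP_VS_NE),
                    Contrast.NP_VS_NE, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def fit_final(sim_dataset):
    """Full final-model FOCE fit of the simulated study (slow, shared)."""
    model = PopPKModel(sim_dataset)
    return model.fit(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def fit_final_reduced(sim_dataset):
    """Reduced-IIV fit (random effects on CL and F only) for diagnostics.

    The three remaining variances are ~0 in the generating truth, so
    dropping their random effects changes nothing material while
    cutting the refit cost of bootstrap-style diagnostics.
    """
    model = PopPKModel(sim_dataset, iiv=("CL", "F"))
    return model.fit(seed=SUITE_SEED)


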