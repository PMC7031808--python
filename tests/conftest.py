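"""Shared fixtures: synthetic studies and (expensive) ensemble fits.

The four-contrast study fixtures reproduce the experimental design: one
SAXS curve plus SANS at 100/75/50% D2O, 1% relative Gaussian noise, fitted
for q > 0.05 1/A with a 40-run genetic-algorithm ensemble.  Ensemble
fixtures are session-scoped because several tests interrogate the same run
distributions.
"""

from __future__ import annotations

import numpy as np
import pytest

from sdpfit.composition import default_peptides
from sdpfit.fitting import GAConfig, JointSDPModel
from sdpfit.simulate import simulate_study, system_recipe

#: GA configuration used for all study-condition ensembles in the suite.
STUDY_GA = GAConfig(generations=200, mutation_decay=0.98)

#: Seeds for the synthetic studies and the fitting ensembles.
STUDY_SEED = 11
ENSEMBLE_SEED = 5
STUDY_NOISE = 0.01
N_RUNS = 40


def make_study_model(system: str, noise_rel: float = STUDY_NOISE,
                     seed: int = STUDY_SEED) -> tuple[JointSDPModel, dict]:
    """Synthetic four-contrast study bound to a JointSDPModel, plus truth."""
    rec = system_recipe(system, noise_rel=noise_rel, seed=seed)
    library = default_peptides()
    model = JointSDPModel(
        simulate_study(rec),
        peptides=[library[n] for n in rec.peptides],
        PL_ratio=rec.PL_ratio,
    )
    return model, rec.params


def run_study_ensemble(system: str):
    model, truth = make_study_model(system)
    result = model.fit(n_runs=N_RUNS, seed=ENSEMBLE_SEED, ga_config=STUDY_GA)
    return result, truth


@pytest.fixture(scope="session")
def pure_ensemble():
    """40-run ensemble fit of the peptide-free POPE/POPG study."""
    return run_study_ensemble("pure")


@pytest.fixture(scope="session")
def pgla_ensemble():
    return run_study_ensemble("L18W-PGLa")


@pytest.fixture(scope="session")
def mg2a_ensemble():
    return run_study_ensemble("MG2a")


@pytest.fixture(scope="session")
def mixture_ensemble():
    return run_study_ensemble("mixture")


@pytest.fixture()
def pure_model():
    """Noise-free truth SDPModel of the pure bilayer."""
    from sdpfit.simulate import build_truth_model

    return build_truth_model(system_recipe("pure"))


@pytest.fixture()
def pgla_model():
    from sdpfit.simulate import build_truth_model

    return build_truth_model(system_recipe("L18W-PGLa"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
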