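import numpy as np
import pytest

from intmod.restraints import NuisanceParams, PosteriorScorer
from intmod.sampling import ModelState
from intmod.synthetic_data import (
    ToyAssemblySpec,
    make_toy_assembly,
    simulate_crosslinks,
    simulate_density,
)

TOY_SEED = 1


@pytest.fixture(scope="session")
def toy():
    """One deterministic toy assembly shared across the suite: ground
    truth, multi-scale model, simulated cross-links (5% noise), and a
    simulated density map."""
    rng = np.random.default_rng(TOY_SEED)
    truth, model = make_toy_assembly(rng=rng)
    xlset = simulate_crosslinks(truth, model, n_true=50, noise_fraction=0.05, rng=rng)
    gmm, vmap = simulate_density(truth, seed=0)
    return {
        "truth": truth,
        "model": model,
        "xlset": xlset,
        "data_gmm": gmm,
        "data_map": vmap,
    }


@pytest.fixture(scope="session")
def toy_scorer(toy):
    return PosteriorScorer(toy["model"], toy["xlset"], em_data=toy["data_gmm"])


@pytest.fixture(scope="session")
def truth_state(toy):
    return ModelState.reference(toy["model"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
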