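import numpy as np
import pytest

from rhldscan import FilterConfig, build_matrix, prepare_variants
from rhldscan import simulate as sim


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic cohort at the default study conditions."""
    return sim.generate(sim.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrices(default_sim):
    cfg = FilterConfig()
    filtered = prepare_variants(default_sim.variants, default_sim.subjects, cfg)
    return {
        model: build_matrix(default_sim.subjects, filtered, model, cfg)
        for model in ("dominant", "recessive")
    }


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down cohort shared by replicate-heavy simulation tests."""
    cfg = sim.null_config()
    rng = np.random.default_rng(42)
    return cfg, sim.generate_cohort(cfg, rng)
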