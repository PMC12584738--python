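import numpy as np
import pytest
from hypothesis import settings

from ervatlas.synthetic_genome import build_demo, build_pair_demo

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

DEMO_SEED = 20260901


@pytest.fixture(scope="session")
def demo():
    """Bundled single-genome demo: >=20 planted elements, ages <= 10 Myr."""
    sim, templates = build_demo(seed=DEMO_SEED)
    return sim, sim.as_contigset(), templates


@pytest.fixture(scope="session")
def pair_demo():
    """Bundled two-species demo (speciation 8 Myr)."""
    return build_pair_demo(DEMO_SEED)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(DEMO_SEED)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    from ervatlas.config import RunConfig
    from ervatlas.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    config = RunConfig(seed=DEMO_SEED, out_dir=str(out))
    result = run_pipeline(config)
    return config, out, result
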