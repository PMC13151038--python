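import numpy as np
import pytest

from tesland import fixtures as fx
from tesland.optimizer import run_scenario_suite


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Small synthetic landscape bundle, written to and read back from disk."""
    outdir = tmp_path_factory.mktemp("small-bundle")
    fx.generate_landscape(fx.preset_spec("small", seed=1), outdir)
    return fx.load_bundle(outdir)


@pytest.fixture(scope="session")
def small_suite(small_bundle):
    """The five design cases solved on the small landscape (shared run)."""
    return run_scenario_suite(
        small_bundle.problem,
        annual_luc_budget=small_bundle.annual_luc_budget,
        horizon=small_bundle.horizon,
        mip_gap=1e-3,
        n_draws=1000,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """2x2 grid, two plantable receptors, 3-year horizon: enumerable."""
    outdir = tmp_path_factory.mktemp("tiny-bundle")
    return fx.tiny_instance(seed=3, outdir=outdir)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
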