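import pytest

from lncprobe.pipeline import run_all
from lncprobe.simulate import SimulationConfig, simulate_universe, worked_toy


@pytest.fixture(scope="session")
def default_universe(tmp_path_factory):
    """The default study-condition universe: 560 lncRNAs, 12 datasets, 3 platforms."""
    return simulate_universe(
        SimulationConfig(seed=0), tmp_path_factory.mktemp("sim_default")
    )


@pytest.fixture(scope="session")
def default_result(default_universe):
    return run_all(default_universe.manifest_path)


SMALL_CLASSES = {
    "exonic_sense": 4, "intronic_sense": 4, "antisense": 20,
    "bidirectional": 20, "intergenic": 20,
}


@pytest.fixture(scope="session")
def small_universe(tmp_path_factory):
    cfg = SimulationConfig(
        seed=7, n_per_class=dict(SMALL_CLASSES), n_up=5, n_down=4,
        n_decoy_blocks=2, n_bound_all_four=3,
    )
    return simulate_universe(cfg, tmp_path_factory.mktemp("sim_small"))


@pytest.fixture(scope="session")
def small_result(small_universe):
    return run_all(small_universe.manifest_path)


@pytest.fixture()
def toy():
    return worked_toy()
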