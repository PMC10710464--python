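import warnings

import numpy as np
import pytest

import polyhic as ph
from polyhic import simulate as sim

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_binning():
    return ph.GenomeBinning({"chr1": 10_000_000, "chr2": 8_000_000}, 25_000)


@pytest.fixture(scope="session")
def small_truth(small_binning):
    return sim.build_truth(small_binning, n_tads=16, n_ctcf_loops=4,
                           n_polycomb_loops=4, n_ultralong=1, n_genes=30,
                           seed=3)


@pytest.fixture(scope="session")
def small_params():
    return sim.SimulationParams(seed=3, depth=8e5)


@pytest.fixture(scope="session")
def small_matrices(small_truth, small_params):
    """Balanced WT/KO matrices on the small two-chromosome genome."""
    out = {}
    for cond in ("WT", "KO"):
        cm = sim.simulate_contact_matrix(small_truth, small_params, cond)
        ph.ice_balance(cm)
        out[cond] = cm
    return out


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory, small_truth, small_params):
    out = tmp_path_factory.mktemp("fixture")
    sim.write_fixture(out, small_truth, small_params)
    return out


@pytest.fixture(scope="session")
def accept_bundle():
    """Full default-scale pipeline bundle (the study conditions)."""
    from polyhic.pipeline import PipelineConfig, run_comparison
    return run_comparison(PipelineConfig(seed=0))
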