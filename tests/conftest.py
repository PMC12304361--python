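import numpy as np
import pytest

import sctagdiff as st

from _pilot_constants import SCENARIO_SEED


def run_testing_branch(sim):
    """Simulated data -> per-condition scaled matrices (testing branch)."""
    peaks = st.filter_peaks(sim.peaks)
    ws = st.make_windows(
        peaks,
        flank=sim.config.flank,
        bin_width=sim.config.bin_width,
        chrom_sizes=sim.chrom_sizes,
    )
    mats = st.build_matrix(sim.all_fragments(), ws, sim.design)
    a, b = sim.config.conditions
    return st.normalize_total(mats[a]), st.normalize_total(mats[b])


@pytest.fixture(scope="session")
def recovery_sim():
    """The default recovery scenario at its frozen seed."""
    return st.simulate_experiment(st.SimConfig(seed=SCENARIO_SEED))


@pytest.fixture(scope="session")
def recovery_matrices(recovery_sim):
    return run_testing_branch(recovery_sim)


@pytest.fixture(scope="session")
def recovery_results(recovery_matrices):
    return st.run_differential(*recovery_matrices)


@pytest.fixture(scope="session")
def small_sim():
    """A light two-state dataset for structural tests."""
    cfg = st.SimConfig(
        seed=42,
        n_peaks=40,
        frac_diff=0.25,
        effect_log2fc=2.5,
        cells_per_condition=30,
        mean_peak_reads=2.0,
        background_rate=10.0,
    )
    return st.simulate_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
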