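import numpy as np
import pytest
from hypothesis import settings

settings.register_profile(
    "deterministic", derandomize=True, deadline=None, database=None
)
settings.load_profile("deterministic")

from mars.evaluation import collect_scored_spectra
from mars.pipeline import score_run
from mars.scoring import TableMProvider, TableRTPredictor
from mars.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def mixed_dataset():
    """Small mixed-signal simulated run shared across tests."""
    return simulate_dataset(SimulationConfig.mixed(seed=7, n_spectra=400))


def scored_spectra_of(dataset):
    """Score a simulated run and return evaluation-ready containers."""
    run = score_run(
        dataset.sets,
        {dataset.typing.sample_id: dataset.typing},
        TableMProvider(dataset.m_table),
        TableRTPredictor(dataset.rt_table),
    )
    truth = {
        e.spectrum_id: e.true_peptide for e in dataset.ground_truth if e.recoverable
    }
    return collect_scored_spectra(run.rescored, truth)


@pytest.fixture(scope="session")
def mixed_scored(mixed_dataset):
    return scored_spectra_of(mixed_dataset)
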