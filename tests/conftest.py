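import numpy as np
import pandas as pd
import pytest

from eddyomics import AbundanceTable, ErccCalibrationModel, SampleMetadata
from eddyomics.simulate import diel_ids, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic two-eddy dataset, shared across tests."""
    return simulate_dataset(1)


@pytest.fixture(scope="session")
def diel_meta(dataset):
    return dataset.meta.subset(diel_ids(dataset.meta))


@pytest.fixture(scope="session")
def depth_meta(dataset):
    return dataset.meta.subset(dataset.ecotype_rpb.samples)


@pytest.fixture(scope="session")
def per_ml(dataset, diel_meta):
    """Spike-calibrated absolute transcript table for the shared dataset."""
    cal = ErccCalibrationModel(dataset.spike_counts, dataset.ercc_reference).fit()
    return cal.normalize(dataset.transcript_counts, diel_meta)


@pytest.fixture
def small_meta():
    """Four-sample two-eddy metadata with depths around a 100 m DCM."""
    return SampleMetadata(
        pd.DataFrame(
            dict(
                sample_id=["C1", "C2", "A1", "A2"],
                eddy=["cyclone", "cyclone", "anticyclone", "anticyclone"],
                depth_m=[90.0, 100.0, 90.0, 100.0],
                dcm_depth_m=[100.0, 100.0, 100.0, 100.0],
                volume_ml=[1000.0, 1500.0, 1200.0, 1800.0],
            )
        )
    )


def random_table(rng: np.random.Generator, n_features: int = 8, n_samples: int = 5,
                 kind: str = "asv_count") -> AbundanceTable:
    vals = rng.uniform(0.1, 100.0, size=(n_features, n_samples))
    return AbundanceTable(
        pd.DataFrame(
            vals,
            index=[f"f{i}" for i in range(n_features)],
            columns=[f"s{j}" for j in range(n_samples)],
        ),
        kind,
    )
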