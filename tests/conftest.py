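import numpy as np
import pandas as pd
import pytest

from exocue.core_model import PipelineConfig


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig(rng_seed=7)


@pytest.fixture
def toy_tables():
    """3 features x 4 samples (1 blank, 1 control, 2 treatment), 2 subnetworks."""
    samples = pd.DataFrame(
        {
            "role": ["blank", "control", "treatment", "treatment"],
            "group_label": ["blank", "seawater", "cca", "cca"],
            "replicate": [1, 1, 1, 2],
        },
        index=pd.Index(["B1", "C1", "T1", "T2"], name="sample_id"),
    )
    features = pd.DataFrame(
        {
            "mz": [200.1, 350.5, 720.9],
            "rt": [65.0, 120.0, 340.0],
            "subnetwork_id": ["SN1", "SN1", "SN2"],
        },
        index=pd.Index(["F1", "F2", "F3"], name="feature_id"),
    )
    matrix = pd.DataFrame(
        [
            [0.0, 1e5, 2e5, 3e5],
            [0.0, 5e4, 8e4, 6e4],
            [1e3, 0.0, 9e5, 7e5],
        ],
        index=features.index,
        columns=samples.index,
    )
    return matrix, features, samples


def random_dataset(rng, n_features=30, n_blanks=2, n_samples=8, n_subnetworks=6):
    """A small random dataset exercising zeros, blanks and subnetworks."""
    sample_ids = [f"B{i}" for i in range(n_blanks)] + [
        f"S{i}" for i in range(n_samples)
    ]
    samples = pd.DataFrame(
        {
            "role": ["blank"] * n_blanks
            + ["control"] * (n_samples // 2)
            + ["treatment"] * (n_samples - n_samples // 2),
            "group_label": "",
            "replicate": 1,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values = 10 ** rng.normal(4.2, 1.2, size=(n_features, len(sample_ids)))
    values[rng.random(values.shape) < 0.35] = 0.0
    # blanks are mostly clean: only occasional carry-over contamination
    values[:, :n_blanks] *= rng.random((n_features, n_blanks)) < 0.15
    features = pd.DataFrame(
        {
            "mz": rng.uniform(150, 1500, n_features),
            "rt": rng.uniform(30, 700, n_features),
            "subnetwork_id": [
                f"SN{rng.integers(n_subnetworks)}" for _ in range(n_features)
            ],
        },
        index=pd.Index([f"F{i}" for i in range(n_features)], name="feature_id"),
    )
    matrix = pd.DataFrame(values, index=features.index, columns=samples.index)
    return matrix, features, samples


def as_rows(matrix: pd.DataFrame) -> dict:
    """Intensity matrix as the plain nested dict the oracles consume."""
    return {
        str(fid): {str(c): float(matrix.at[fid, c]) for c in matrix.columns}
        for fid in matrix.index
    }
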