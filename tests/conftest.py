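import numpy as np
import pandas as pd
import pytest

from ebmeta import (
    EBMTrainConfig,
    PipelineConfig,
    ProfileDataset,
    ProfileMatrix,
    functional_mode_config,
    generate_dataset,
)


@pytest.fixture(scope="session")
def fast_config() -> PipelineConfig:
    """Pipeline config with a quickly converging booster for test-scale fits."""
    return PipelineConfig(ebm=EBMTrainConfig(learning_rate=0.1, n_epochs=150))


@pytest.fixture(scope="session")
def small_dataset():
    """4 projects x 40 samples, 120 features, 12 planted: fast end-to-end data."""
    config = functional_mode_config(
        seed=20240,
        n_projects=4,
        samples_per_condition={"healthy": 12, "crc": 12, "adenoma": 8, "small_adenoma": 8},
        n_features=120,
        n_signal=12,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def binary_small(small_dataset):
    dataset, _ = small_dataset
    mask = dataset.metadata["condition"].isin(["healthy", "crc"])
    return dataset.subset(list(dataset.metadata.index[mask]))


def make_dataset(values, sample_ids, feature_ids, conditions, project="p1",
                 namespace="kegg", comorbidity=None):
    """Assemble a ProfileDataset from raw pieces (test helper)."""
    data = pd.DataFrame(np.asarray(values, dtype=float),
                        index=sample_ids, columns=feature_ids)
    comorbidity = comorbidity or [False] * len(sample_ids)
    projects = [project] * len(sample_ids) if isinstance(project, str) else project
    meta = pd.DataFrame(
        {"project_id": projects, "condition": conditions, "comorbidity": comorbidity},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ProfileDataset(ProfileMatrix(data, namespace), meta)
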