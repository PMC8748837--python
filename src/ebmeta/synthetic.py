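"""Seeded generator of multi-project abundance datasets.

The generator emulates the statistical structure of multi-cohort gut-metagenome
case/control profiles: several projects with project-specific batch offsets,
zero-inflated and heavily skewed abundances, one low-depth project (more
dropout, globally attenuated values), and a minority of *signal* features whose
abundance carries the condition.  In ``functional`` mode the planted effects
are ordered along disease progression (healthy < small adenoma < adenoma <
CRC); in ``taxonomic`` mode only CRC samples deviate, so pre-malignant
conditions are indistinguishable from healthy — mirroring the contrast between
functional and taxonomic profiles.

The model for the abundance of feature j in sample i is

    a_ij = B_ij * exp(mu_j + b_{p(i),j} + log e_{c(i),j} + eps_ij)

with mu_j ~ N(0, base_log_mean_sd) a feature baseline shared by all projects,
b_{p,j} ~ N(0, batch_sd) a per-project batch offset, e_{c,j} the condition
multiplier (1 for null features), eps_ij ~ N(0, noise_sd) sampling noise and
B_ij ~ Bernoulli(1 - zero_inflation) a dropout mask.  The low-depth project is
additionally scaled by ``depth_factor`` and gets its own (higher) dropout rate.
Condition effects are applied to a single nested signal set, so the adenoma
signature is a weakened CRC signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .data import ProfileDataset, ProfileMatrix

#: Ordered condition multipliers: a graded change in functional activity along
#: the healthy -> small adenoma -> adenoma -> CRC progression, one doubling
#: per stage.  The CRC multiplier mirrors the near-order-of-magnitude
#: enrichment reported for established CRC microbiome biomarkers;
#: pre-malignant stages carry attenuated versions of the same shift.
FUNCTIONAL_EFFECTS = {
    "healthy": 1.0,
    "small_adenoma": 2.0,
    "adenoma": 4.0,
    "crc": 8.0,
}

#: CRC-only multipliers: taxon abundances shift only near the cancer state.
TAXONOMIC_EFFECTS = {
    "healthy": 1.0,
    "small_adenoma": 1.0,
    "adenoma": 1.0,
    "crc": 8.0,
}

DEFAULT_SAMPLES_PER_CONDITION = {
    "healthy": 25,
    "crc": 25,
    "adenoma": 5,
    "small_adenoma": 5,
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic multi-project generator.

    All noise scales are on the natural-log abundance scale.
    """

    seed: int
    n_projects: int = 7
    samples_per_condition: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLES_PER_CONDITION)
    )
    n_features: int = 500
    n_signal: int = 30
    effect_profile: dict[str, float] = field(
        default_factory=lambda: dict(FUNCTIONAL_EFFECTS)
    )
    base_log_mean_sd: float = 1.0
    batch_sd: float = 0.3
    zero_inflation: float = 0.3
    noise_sd: float = 1.0
    low_depth_project: Optional[int] = 0
    depth_factor: float = 0.5
    low_depth_zero_inflation: float = 0.55
    namespace: str = "kegg"

    def __post_init__(self) -> None:
        if self.n_signal > self.n_features:
            raise ValueError("n_signal cannot exceed n_features")
        for name, p in (
            ("zero_inflation", self.zero_inflation),
            ("low_depth_zero_inflation", self.low_depth_zero_inflation),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if not 0.0 < self.depth_factor <= 1.0:
            raise ValueError("depth_factor must lie in (0, 1]")
        if any(n < 0 for n in self.samples_per_condition.values()):
            raise ValueError("sample counts must be nonnegative")
        if self.low_depth_project is not None and not (
            0 <= self.low_depth_project < self.n_projects
        ):
            raise ValueError("low_depth_project index out of range")
        missing = set(self.samples_per_condition) - set(self.effect_profile)
        if missing:
            raise ValueError(
                f"effect_profile missing conditions present in "
                f"samples_per_condition: {sorted(missing)}"
            )


@dataclass
class PlantedTruth:
    """Ground truth of a generated dataset: which features carry signal."""

    signal_feature_ids: list[str]
    effect_profile: dict[str, float]


def functional_mode_config(seed: int, **overrides) -> GeneratorConfig:
    """Default configuration with ordered (progression-graded) planted effects."""
    return replace(
        GeneratorConfig(seed=seed, effect_profile=dict(FUNCTIONAL_EFFECTS)),
        **overrides,
    )


def taxonomic_mode_config(seed: int, **overrides) -> GeneratorConfig:
    """Default configuration with CRC-only planted effects (2-bin namespace)."""
    return replace(
        GeneratorConfig(
            seed=seed,
            effect_profile=dict(TAXONOMIC_EFFECTS),
            namespace="taxonomic",
        ),
        **overrides,
    )


def generate_dataset(config: GeneratorConfig) -> tuple[ProfileDataset, PlantedTruth]:
    """Draw one multi-project dataset; bitwise-reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    d = config.n_features
    feature_ids = [f"F{j:05d}" for j in range(d)]

    signal_idx = rng.choice(d, size=config.n_signal, replace=False)
    signal_idx.sort()
    signal_set = np.zeros(d, dtype=bool)
    signal_set[signal_idx] = True

    mu = rng.normal(0.0, config.base_log_mean_sd, size=d)

    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    for p in range(config.n_projects):
        pid = f"project_{p + 1}"
        batch = rng.normal(0.0, config.batch_sd, size=d)
        low_depth = config.low_depth_project is not None and p == config.low_depth_project
        zi = config.low_depth_zero_inflation if low_depth else config.zero_inflation
        depth = config.depth_factor if low_depth else 1.0
        for condition, n in config.samples_per_condition.items():
            effect = np.ones(d)
            effect[signal_set] = config.effect_profile[condition]
            for k in range(n):
                eps = rng.normal(0.0, config.noise_sd, size=d)
                mask = rng.random(d) >= zi
                values = depth * mask * np.exp(mu + batch + np.log(effect) + eps)
                sid = f"{pid}_{condition}_{k + 1:03d}"
                rows.append(values)
                sample_ids.append(sid)
                meta_rows.append(
                    {"project_id": pid, "condition": condition, "comorbidity": False}
                )

    data = pd.DataFrame(
        np.asarray(rows), index=pd.Index(sample_ids, name="sample_id"), columns=feature_ids
    )
    metadata = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    dataset = ProfileDataset(ProfileMatrix(data, config.namespace), metadata)
    truth = PlantedTruth(
        signal_feature_ids=[feature_ids[j] for j in signal_idx],
        effect_profile=dict(config.effect_profile),
    )
    return dataset, truth
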