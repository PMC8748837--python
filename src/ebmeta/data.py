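"""Core data containers and readers for abundance profiles and sample metadata.

A *profile* is a nonnegative sample x feature abundance matrix in one of three
feature namespaces: ``taxonomic`` (strain/taxon relative abundances), ``kegg``
(KEGG ortholog functional abundances) or ``eggnog`` (eggNOG orthologous-group
abundances).  Samples carry a project identifier (the study they come from) and
a condition label from a closed vocabulary.

On disk, profiles follow the common metagenomic count-table layout: features as
rows, samples as columns, tab-separated, first column holding feature ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NAMESPACES = ("taxonomic", "kegg", "eggnog")

#: Closed condition vocabulary. ``crc`` is the positive class throughout.
CONDITIONS = ("healthy", "crc", "adenoma", "small_adenoma", "other")

METADATA_COLUMNS = ("project_id", "condition", "comorbidity")


class ProfileError(ValueError):
    """Raised for malformed profile matrices or metadata."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ProfileError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ProfileMatrix:
    """Sample x feature nonnegative abundance matrix.

    Parameters
    ----------
    data
        DataFrame with samples as the index and features as the columns.
    namespace
        One of :data:`NAMESPACES`.
    """

    data: pd.DataFrame
    namespace: str

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ProfileError(
                f"unknown namespace {self.namespace!r}; expected one of {NAMESPACES}"
            )
        _check_unique(list(self.data.index), "sample")
        _check_unique(list(self.data.columns), "feature")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ProfileError(
                f"non-finite abundance at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ProfileError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotation record."""

    sample_id: str
    project_id: str
    condition: str
    comorbidity: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ProfileError(
                f"unknown condition {self.condition!r} for sample "
                f"{self.sample_id!r}; expected one of {CONDITIONS}"
            )


def metadata_frame(records: Iterable[SampleMetadata]) -> pd.DataFrame:
    """Assemble metadata records into the canonical indexed DataFrame."""
    rows = list(records)
    _check_unique([r.sample_id for r in rows], "sample")
    frame = pd.DataFrame(
        {
            "project_id": [r.project_id for r in rows],
            "condition": [r.condition for r in rows],
            "comorbidity": [bool(r.comorbidity) for r in rows],
        },
        index=pd.Index([r.sample_id for r in rows], name="sample_id"),
    )
    return frame


@dataclass
class ProfileDataset:
    """A profile matrix together with aligned per-sample metadata.

    Every matrix sample must have exactly one metadata record and vice versa;
    metadata rows are reordered to the matrix sample order on construction.
    """

    matrix: ProfileMatrix
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        meta = self.metadata
        missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
        if missing:
            raise ProfileError(f"metadata missing columns: {missing}")
        _check_unique(list(meta.index), "metadata sample")
        mat_ids = set(self.matrix.sample_ids)
        meta_ids = set(meta.index)
        if mat_ids != meta_ids:
            only_mat = sorted(mat_ids - meta_ids)[:3]
            only_meta = sorted(meta_ids - mat_ids)[:3]
            raise ProfileError(
                "matrix and metadata sample ids disagree "
                f"(matrix-only: {only_mat}, metadata-only: {only_meta})"
            )
        bad = meta.loc[~meta["condition"].isin(CONDITIONS)]
        if len(bad):
            raise ProfileError(
                f"unknown condition {bad['condition'].iloc[0]!r} for sample "
                f"{bad.index[0]!r}"
            )
        # align metadata to matrix order
        self.metadata = meta.loc[self.matrix.sample_ids].copy()
        self.metadata["comorbidity"] = self.metadata["comorbidity"].astype(bool)

    # -- convenience accessors -------------------------------------------------

    @property
    def namespace(self) -> str:
        return self.matrix.namespace

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.sample_ids

    @property
    def feature_ids(self) -> list[str]:
        return self.matrix.feature_ids

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples

    def conditions(self) -> pd.Series:
        return self.metadata["condition"]

    def project_ids(self) -> list[str]:
        """Distinct project ids in first-appearance order."""
        return list(dict.fromkeys(self.metadata["project_id"]))

    def subset(self, sample_ids: Sequence[str]) -> "ProfileDataset":
        """Row-subset (and reorder) by sample id."""
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.matrix.data.index]
        if missing:
            raise ProfileError(f"unknown sample ids: {missing[:3]}")
        return ProfileDataset(
            ProfileMatrix(self.matrix.data.loc[ids], self.namespace),
            self.metadata.loc[ids],
        )

    def by_project(self) -> dict[str, "ProfileDataset"]:
        """Split into one dataset per project, preserving project order."""
        out = {}
        for pid in self.project_ids():
            ids = self.metadata.index[self.metadata["project_id"] == pid]
            out[pid] = self.subset(list(ids))
        return out

    def binary_labels(self) -> pd.Series:
        """0/1 labels (crc = 1) for the healthy/crc samples; errors otherwise."""
        cond = self.metadata["condition"]
        bad = cond[~cond.isin(["healthy", "crc"])]
        if len(bad):
            raise ProfileError(
                f"non healthy/crc condition {bad.iloc[0]!r} in a binary task "
                f"(sample {bad.index[0]!r})"
            )
        return (cond == "crc").astype(int)


# -- TSV readers / writers ----------------------------------------------------


def read_profile_tsv(path: str | Path, namespace: str) -> ProfileMatrix:
    """Read a feature x sample abundance TSV into a :class:`ProfileMatrix`.

    The first column holds feature ids, the header row sample ids; the body is
    numeric.  Duplicate ids and negative values raise :class:`ProfileError`.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise ProfileError(f"{path}: empty file")
    sample_ids = header.split("\t")[1:]
    if not sample_ids:
        raise ProfileError(f"{path}: no samples")
    _check_unique(sample_ids, "sample")
    body = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if body.shape[0] == 0:
        raise ProfileError(f"{path}: no samples (empty body)")
    _check_unique(list(body.index), "feature")
    try:
        numeric = body.astype(float)
    except ValueError as exc:
        raise ProfileError(f"{path}: non-numeric cell ({exc})") from exc
    numeric.columns = sample_ids
    return ProfileMatrix(numeric.T, namespace)


def write_profile_tsv(matrix: ProfileMatrix, path: str | Path) -> None:
    """Write a profile as a feature x sample TSV (inverse of the reader)."""
    out = matrix.data.T
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read a metadata TSV (sample_id, project_id, condition, comorbidity)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "project_id": str})
    missing = [c for c in ("sample_id",) + METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise ProfileError(f"{path}: metadata missing columns {missing}")
    frame = frame.set_index("sample_id")
    frame["comorbidity"] = frame["comorbidity"].astype(bool)
    return frame


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def load_dataset(
    profile_path: str | Path, metadata_path: str | Path, namespace: str
) -> ProfileDataset:
    """Load a profile TSV + metadata TSV pair into a dataset."""
    return ProfileDataset(
        read_profile_tsv(profile_path, namespace), read_metadata_tsv(metadata_path)
    )


def save_dataset(
    dataset: ProfileDataset, profile_path: str | Path, metadata_path: str | Path
) -> None:
    write_profile_tsv(dataset.matrix, profile_path)
    write_metadata_tsv(dataset.metadata, metadata_path)


# -- concatenation -------------------------------------------------------------


def concat_datasets(datasets: Sequence[ProfileDataset]) -> ProfileDataset:
    """Sample-wise concatenation over the union of feature ids.

    Features absent from a dataset are filled with 0 (profiles are built on a
    shared catalog, so absence means not observed).  Duplicate sample ids or
    mixed namespaces raise :class:`ProfileError`.
    """
    datasets = list(datasets)
    if not datasets:
        raise ProfileError("nothing to concatenate")
    namespaces = {d.namespace for d in datasets}
    if len(namespaces) > 1:
        raise ProfileError(f"mixed namespaces: {sorted(namespaces)}")
    all_ids: list[str] = []
    for d in datasets:
        all_ids.extend(d.sample_ids)
    _check_unique(all_ids, "sample")
    data = pd.concat([d.matrix.data for d in datasets], axis=0).fillna(0.0)
    meta = pd.concat([d.metadata for d in datasets], axis=0)
    return ProfileDataset(ProfileMatrix(data, datasets[0].namespace), meta)
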