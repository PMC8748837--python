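"""Validation designs: repeated CV, cross-dataset prediction, LOPO and o-LOPO.

Three data-splitting scenarios probe the healthy-vs-CRC classifier:

* ``repeated_cv`` — 20-times repeated stratified tenfold cross-validation
  inside one project (intra-project performance);
* ``cross_dataset_matrix`` — train on one project, test on every other
  (how well a single-study signature transfers);
* ``lopo`` / ``olopo`` — leave-one-project-out: predict each study with a model
  trained on the union of the remaining ones.  Plain LOPO refits the feature
  selection inside each training union; o-LOPO fixes the feature set to an
  externally computed mask (e.g. the consensus-signature support), an
  intentional, documented information leak that makes the design comparable to
  reference meta-analysis methodologies.

All scores are AUROC: the probability that a random positive outranks a random
negative, ties counted 1/2.  Cells where the test set lacks one of the two
classes are undefined and reported as NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data import ProfileDataset
from .preprocess import (
    EmptySignatureError,
    FittedPipeline,
    PipelineConfig,
    fit_pipeline,
    predict_proba,
)
from .reports import CrossPredictionMatrix, PerformanceResult


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; NaN when only one class is present."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(labels) != len(scores):
        raise ValueError("scores and labels length mismatch")
    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(roc_auc_score(labels, scores))


@dataclass
class SplitPlan:
    """A list of (train ids, test ids) pairs under a named splitting schema."""

    splits: list[tuple[list[str], list[str]]]
    schema: str
    seed: int

    def __post_init__(self) -> None:
        for train, test in self.splits:
            if set(train) & set(test):
                raise ValueError("train and test overlap within a split")

    def __len__(self) -> int:
        return len(self.splits)


def cv_split_plan(
    dataset: ProfileDataset, k: int = 10, repeats: int = 20, seed: int = 0
) -> SplitPlan:
    """Repeated stratified k-fold plan on a binary-labeled dataset.

    If the minority class has fewer than ``k`` members, k is reduced (with a
    warning) so every fold keeps both classes.
    """
    y = dataset.binary_labels()
    ids = np.asarray(dataset.sample_ids)
    min_class = int(y.value_counts().min())
    if min_class < 2:
        raise ValueError("need at least 2 samples of each class for CV")
    if min_class < k:
        warnings.warn(
            f"reducing k from {k} to {min_class}: smallest class has "
            f"{min_class} samples",
            stacklevel=2,
        )
        k = min_class
    splits = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        for train_idx, test_idx in skf.split(ids, y.to_numpy()):
            splits.append((list(ids[train_idx]), list(ids[test_idx])))
    return SplitPlan(splits=splits, schema="repeated_cv", seed=seed)


def evaluate_splits(
    dataset: ProfileDataset,
    plan: SplitPlan,
    config: Optional[PipelineConfig] = None,
) -> PerformanceResult:
    """Fit on each split's training ids, score its test ids, summarize AUROCs."""
    config = config or PipelineConfig()
    aurocs = []
    for train_ids, test_ids in plan.splits:
        try:
            pipe = fit_pipeline(dataset.subset(train_ids), config)
        except EmptySignatureError:
            # nothing survived the screening in this split: score undefined
            aurocs.append(float("nan"))
            continue
        test = dataset.subset(test_ids)
        probs = predict_proba(pipe, test)
        aurocs.append(auroc(probs.to_numpy(), test.binary_labels().to_numpy()))
    arr = np.asarray(aurocs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN folds
        return PerformanceResult(
            aurocs=list(arr),
            mean=float(np.nanmean(arr)),
            q25=float(np.nanquantile(arr, 0.25)),
            q75=float(np.nanquantile(arr, 0.75)),
            schema=plan.schema,
        )


def repeated_cv(
    dataset: ProfileDataset,
    config: Optional[PipelineConfig] = None,
    k: int = 10,
    repeats: int = 20,
    seed: int = 0,
) -> PerformanceResult:
    """Repeated stratified k-fold CV with selection/binning refit per fold."""
    plan = cv_split_plan(dataset, k=k, repeats=repeats, seed=seed)
    return evaluate_splits(dataset, plan, config)


def _binary_subset(dataset: ProfileDataset) -> ProfileDataset:
    mask = dataset.metadata["condition"].isin(["healthy", "crc"])
    return dataset.subset(list(dataset.metadata.index[mask]))


def _score_on(pipe: FittedPipeline, target: ProfileDataset) -> float:
    probs = predict_proba(pipe, target)
    labels = (target.metadata["condition"] == "crc").astype(int)
    return auroc(probs.to_numpy(), labels.to_numpy())


@dataclass
class LopoResult:
    """Per-held-out-project AUROC plus the relevance vector of each run."""

    aurocs: dict[str, float]
    relevances: pd.DataFrame  # rows = held-out project, columns = all features

    def mean_auroc(self) -> float:
        return float(np.nanmean(list(self.aurocs.values())))


def lopo(
    dataset: ProfileDataset,
    config: Optional[PipelineConfig] = None,
    external_mask: Optional[Sequence[str]] = None,
) -> LopoResult:
    """Leave-one-project-out validation over a multi-project dataset.

    For each project: fit the full pipeline (selection refit inside the
    training union unless ``external_mask`` fixes it), score the held-out
    project, and record the run's global-relevance vector over the full
    feature space (zero for unselected features) for signature building.
    """
    config = config or PipelineConfig()
    if external_mask is not None:
        config = config.with_mask(external_mask)
    projects = dataset.by_project()
    if len(projects) < 2:
        raise ValueError("LOPO needs at least 2 projects")
    binary = {pid: _binary_subset(ds) for pid, ds in projects.items()}
    aurocs: dict[str, float] = {}
    rel_rows = {}
    for held_out in projects:
        train_ids: list[str] = []
        for pid, ds in binary.items():
            if pid != held_out:
                train_ids.extend(ds.sample_ids)
        try:
            pipe = fit_pipeline(dataset.subset(train_ids), config)
        except EmptySignatureError:
            warnings.warn(
                f"LOPO run holding out {held_out!r}: empty selection on the "
                "training union; run undefined",
                stacklevel=2,
            )
            aurocs[held_out] = float("nan")
            rel_rows[held_out] = pd.Series(0.0, index=pd.Index(dataset.feature_ids))
            continue
        aurocs[held_out] = _score_on(pipe, binary[held_out])
        rel_rows[held_out] = pipe.relevance_vector()
    relevances = pd.DataFrame(rel_rows).T
    relevances = relevances[dataset.feature_ids]
    return LopoResult(aurocs=aurocs, relevances=relevances)


def olopo(
    dataset: ProfileDataset,
    external_mask: Sequence[str],
    config: Optional[PipelineConfig] = None,
) -> LopoResult:
    """LOPO with the feature set fixed to an out-of-training mask.

    The mask is typically the consensus-signature support computed on the
    pooled data; fixing it before the LOPO loop is a deliberate information
    leak mirroring reference meta-analysis pipelines.
    """
    if external_mask is None or len(list(external_mask)) == 0:
        raise ValueError("o-LOPO requires a non-empty external feature mask")
    return lopo(dataset, config, external_mask=list(external_mask))


def cross_dataset_matrix(
    dataset: ProfileDataset,
    config: Optional[PipelineConfig] = None,
    cv_repeats: int = 20,
    cv_k: int = 10,
    seed: int = 0,
    include_lopo: bool = True,
    olopo_mask: Optional[Sequence[str]] = None,
) -> CrossPredictionMatrix:
    """Project x project AUROC matrix.

    Off-diagonal cell (r, c): train on project r, test on project c.  Diagonal:
    mean of repeated stratified CV within the project.  When requested, two
    aggregate rows are appended: LOPO (train on all other projects) and oLOPO
    (same, with the feature set fixed to ``olopo_mask``).
    """
    config = config or PipelineConfig()
    projects = dataset.by_project()
    if len(projects) < 2:
        raise ValueError("cross-dataset analysis needs at least 2 projects")
    pids = list(projects)
    binary = {pid: _binary_subset(ds) for pid, ds in projects.items()}
    table = pd.DataFrame(np.nan, index=list(pids), columns=list(pids))
    for r in pids:
        try:
            pipe = fit_pipeline(binary[r], config)
        except ValueError:
            pipe = None  # single class or empty selection: row undefined
        if pipe is not None:
            for c in pids:
                if c != r:
                    table.loc[r, c] = _score_on(pipe, binary[c])
        try:
            table.loc[r, r] = repeated_cv(
                binary[r], config, k=cv_k, repeats=cv_repeats, seed=seed
            ).mean
        except ValueError:
            pass
    if include_lopo:
        lopo_res = lopo(dataset, config)
        table.loc["LOPO"] = pd.Series(lopo_res.aurocs)
        if olopo_mask is not None:
            olopo_res = olopo(dataset, olopo_mask, config)
            table.loc["oLOPO"] = pd.Series(olopo_res.aurocs)
        else:
            table.loc["oLOPO"] = np.nan
    return CrossPredictionMatrix(table=table)
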