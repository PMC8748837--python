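"""Deterministic front end of the classification pipeline.

Order of operations: log(1 + x) transform, ANOVA F-test univariate screening
with Benjamini-Hochberg FDR control (alpha = 0.05), per-feature equal-frequency
discretization (2 bins for taxonomic profiles, 20 for functional ones), and
finally the explainable boosting machine.  All statistics — selection mask,
bin edges, model — are learned on the training rows only; the one sanctioned
exception is an explicitly supplied external feature mask (the out-of-training
selection used by the o-LOPO design), which replaces the internal screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from statsmodels.stats.multitest import multipletests

from . import ebm as _ebm
from .data import ProfileDataset
from .ebm import EBMModel, EBMTrainConfig


class EmptySignatureError(ValueError):
    """No feature survived the FDR screening."""


def log_transform(X: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Elementwise log(1 + x); mitigates the skew toward large abundances."""
    values = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if values.size and values.min() < 0:
        raise ValueError("log transform requires nonnegative abundances")
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(np.log1p(values), index=X.index, columns=X.columns)
    return np.log1p(values)


@dataclass
class SelectionResult:
    """Univariate screening outcome: mask is q <= alpha, per feature."""

    mask: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    alpha: float = 0.05

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def anova_fdr_select(
    X: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> SelectionResult:
    """One-way ANOVA F screening with Benjamini-Hochberg FDR control.

    Constant features are assigned p = 1 (no evidence).  Requires at least two
    samples in each class so the within-group variance is estimable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {len(classes)}")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples for the F-test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features trip a RuntimeWarning
        _, p = f_classif(X, y)
    p = np.where(np.isfinite(p), p, 1.0)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return SelectionResult(mask=reject, p_values=p, q_values=q, alpha=alpha)


@dataclass
class Discretizer:
    """Per-feature equal-frequency binning fitted on training values.

    ``edges[j]`` holds the strictly increasing interior cut points of feature
    j; a value v falls into bin ``searchsorted(edges, v, side="right")``, so
    out-of-range test values are clamped into the first or last bin.  Tied
    quantiles collapse, so the realized bin count can be below ``n_bins``.
    """

    edges: list[np.ndarray]
    n_bins: int

    @property
    def n_features(self) -> int:
        return len(self.edges)

    def realized_bins(self, j: int) -> int:
        return len(self.edges[j]) + 1


def fit_discretizer(X: np.ndarray, n_bins: int) -> Discretizer:
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    X = np.asarray(X, dtype=float)
    qs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    edges = []
    for j in range(X.shape[1]):
        cuts = np.unique(np.quantile(X[:, j], qs))
        # a cut at the column maximum would leave the top bin empty (values
        # fall into bins by searchsorted side="right"); for a constant column
        # this drops every cut, collapsing to a single bin.  A cut equal to
        # the minimum is kept: it isolates the minimum (e.g. the zero mass of
        # sparse profiles) in the first bin.
        cuts = cuts[cuts < X[:, j].max()]
        edges.append(cuts)
    return Discretizer(edges=edges, n_bins=n_bins)


def apply_discretizer(disc: Discretizer, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != disc.n_features:
        raise ValueError(
            f"expected {disc.n_features} features, got {X.shape[1]}"
        )
    out = np.empty(X.shape, dtype=np.intp)
    for j in range(X.shape[1]):
        out[:, j] = np.searchsorted(disc.edges[j], X[:, j], side="right")
    return out


def default_n_bins(namespace: str) -> int:
    """2 bins for taxonomic profiles, 20 for functional (kegg/eggnog) ones."""
    return 2 if namespace == "taxonomic" else 20


@dataclass
class PipelineConfig:
    """Configuration of the full log -> select -> discretize -> EBM pipeline.

    ``n_bins=None`` resolves from the dataset namespace (2 taxonomic / 20
    functional).  ``select=False`` bypasses the FDR screening (all features
    kept); ``external_mask`` fixes the feature set to an externally computed
    selection, replacing the internal screening (o-LOPO mode).
    """

    alpha: float = 0.05
    n_bins: Optional[int] = None
    select: bool = True
    external_mask: Optional[list[str]] = None
    ebm: EBMTrainConfig = field(default_factory=EBMTrainConfig)

    def with_mask(self, feature_ids: Sequence[str]) -> "PipelineConfig":
        return replace(self, external_mask=list(feature_ids))


@dataclass
class FittedPipeline:
    """Frozen state of a fitted pipeline; applies to any compatible dataset."""

    feature_ids: list[str]  # full input feature space, in training order
    selected_ids: list[str]
    selection: Optional[SelectionResult]
    discretizer: Discretizer
    model: EBMModel
    config: PipelineConfig

    def relevance_vector(self) -> pd.Series:
        """EBM global relevance over the *full* feature space (0 if unselected)."""
        vec = pd.Series(0.0, index=pd.Index(self.feature_ids))
        vec.loc[self.selected_ids] = self.model.relevance
        return vec


def _frame(X, feature_ids=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    cols = feature_ids if feature_ids is not None else [f"f{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=cols)


def fit_pipeline_xy(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    config: Optional[PipelineConfig] = None,
    n_bins: Optional[int] = None,
) -> FittedPipeline:
    """Fit the pipeline on a feature table and binary labels (crc = 1)."""
    config = config or PipelineConfig()
    frame = _frame(X)
    y = np.asarray(y)
    n_bins = n_bins if n_bins is not None else (config.n_bins or 20)

    logged = log_transform(frame)
    selection: Optional[SelectionResult] = None
    if config.external_mask is not None:
        if not config.external_mask:
            raise EmptySignatureError("external feature mask is empty")
        missing = [f for f in config.external_mask if f not in frame.columns]
        if missing:
            raise ValueError(f"external mask features absent from data: {missing[:3]}")
        selected_ids = list(config.external_mask)
    elif config.select:
        selection = anova_fdr_select(logged.to_numpy(), y, alpha=config.alpha)
        if selection.n_selected == 0:
            raise EmptySignatureError(
                "empty signature: no feature passed the FDR screening "
                f"(alpha={config.alpha}); pass select=False to bypass"
            )
        selected_ids = list(frame.columns[selection.mask])
    else:
        selected_ids = list(frame.columns)

    sub = logged[selected_ids].to_numpy()
    disc = fit_discretizer(sub, n_bins)
    binned = apply_discretizer(disc, sub)
    model = _ebm.fit_ebm(binned, y, config.ebm, feature_ids=selected_ids)
    return FittedPipeline(
        feature_ids=list(frame.columns),
        selected_ids=selected_ids,
        selection=selection,
        discretizer=disc,
        model=model,
        config=config,
    )


def fit_pipeline(
    train: ProfileDataset, config: Optional[PipelineConfig] = None
) -> FittedPipeline:
    """Fit on a healthy/crc dataset; labels derive from the condition column."""
    config = config or PipelineConfig()
    y = train.binary_labels().to_numpy()
    n_bins = config.n_bins or default_n_bins(train.namespace)
    return fit_pipeline_xy(train.matrix.data, y, config, n_bins=n_bins)


def predict_proba_xy(
    pipeline: FittedPipeline, X: pd.DataFrame | np.ndarray
) -> np.ndarray:
    frame = _frame(X, pipeline.feature_ids)
    missing = [f for f in pipeline.selected_ids if f not in frame.columns]
    if missing:
        raise ValueError(f"prediction data lacks trained features: {missing[:3]}")
    logged = log_transform(frame[pipeline.selected_ids]).to_numpy()
    binned = apply_discretizer(pipeline.discretizer, logged)
    return _ebm.predict_proba(pipeline.model, binned)


def predict_proba(pipeline: FittedPipeline, dataset: ProfileDataset) -> pd.Series:
    """P(CRC) per sample, indexed by sample id."""
    probs = predict_proba_xy(pipeline, dataset.matrix.data)
    return pd.Series(probs, index=dataset.matrix.data.index)
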