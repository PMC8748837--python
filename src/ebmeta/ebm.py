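"""A minimal explainable boosting machine for pre-binned features.

The model is a generalized additive model on the logit link,

    logit P(y = 1 | x) = beta0 + sum_j f_j(x_j),

where each shape function f_j ("graph") maps the discrete bin of feature j to
an additive log-odds contribution.  Training is cyclic gradient boosting: in
every epoch the features are visited round-robin, and for each one a depth-1
learner on its bins is fitted to the current logistic-loss residuals and added
into that feature's graph with a small learning rate.  Because features arrive
already binned, the depth-1 learner is simply the per-bin Newton step
sum(y - p) / sum(p (1 - p)) — the standard leaf value of gradient-boosted
trees under the logistic loss.  The small learning rate combined with the
round-robin schedule spreads the contribution of collinear (e.g. duplicated)
features nearly evenly instead of letting one absorb the whole effect.

After training each graph is re-centered to zero mean under the training bin
distribution (the shift is folded into the intercept), so graphs of different
features are on a comparable scale and the per-feature *global relevance* —
the mean absolute local contribution over a reference set — is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class EBMTrainConfig:
    """Training hyperparameters for the cyclic booster.

    ``n_epochs`` counts full round-robin passes over the features.  ``n_bags``
    > 0 enables outer bagging: the reported model averages graphs of models
    fitted on bootstrap resamples (seeded).
    """

    learning_rate: float = 0.01
    n_epochs: int = 2000
    seed: int = 0
    n_bags: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be at least 1")
        if self.n_bags < 0:
            raise ValueError("n_bags must be nonnegative")


@dataclass
class ShapeGraph:
    """Per-bin additive contribution (log-odds units) of one feature."""

    feature_id: str
    contributions: np.ndarray  # one value per realized bin
    bin_weights: np.ndarray  # training bin distribution used for centering

    def __call__(self, bins: np.ndarray) -> np.ndarray:
        clipped = np.clip(bins, 0, len(self.contributions) - 1)
        return self.contributions[clipped]


@dataclass
class EBMModel:
    """Fitted additive model: intercept plus one shape graph per feature."""

    intercept: float
    graphs: list[ShapeGraph]
    feature_ids: list[str]
    relevance: np.ndarray  # mean |contribution| on the training set
    config: EBMTrainConfig = field(default_factory=EBMTrainConfig)

    @property
    def n_features(self) -> int:
        return len(self.graphs)

    def relevance_series(self):
        import pandas as pd

        return pd.Series(self.relevance, index=self.feature_ids)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _check_inputs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0 or X.shape[0] == 0:
        raise ValueError("X_binned must be a non-empty 2-D array of bin indices")
    if len(y) != X.shape[0]:
        raise ValueError("X_binned and y length mismatch")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("y must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("y contains a single class; cannot fit a classifier")
    return X.astype(np.intp), y


def _boost(
    X: np.ndarray, y: np.ndarray, n_bins: list[int], config: EBMTrainConfig
) -> tuple[float, list[np.ndarray]]:
    """Cyclic boosting core; returns the (uncentered) intercept and graphs."""
    n, d = X.shape
    p_base = y.mean()
    beta0 = float(np.log(p_base / (1.0 - p_base)))
    graphs = [np.zeros(nb) for nb in n_bins]
    score = np.full(n, beta0)
    lr = config.learning_rate
    cols = [np.ascontiguousarray(X[:, j]) for j in range(d)]
    eps = 1e-12
    for _ in range(config.n_epochs):
        for j in range(d):
            p = _sigmoid(score)
            residual = y - p
            hessian = p * (1.0 - p)
            bins = cols[j]
            num = np.bincount(bins, weights=residual, minlength=n_bins[j])
            den = np.bincount(bins, weights=hessian, minlength=n_bins[j])
            step = lr * num / np.maximum(den, eps)
            graphs[j] += step
            score += step[bins]
    return beta0, graphs


def fit_ebm(
    X_binned: np.ndarray,
    y: np.ndarray,
    config: Optional[EBMTrainConfig] = None,
    feature_ids: Optional[Sequence[str]] = None,
) -> EBMModel:
    """Fit the additive model on integer-binned features and binary labels.

    Graphs are indexed by bin; the number of realized bins per feature is taken
    as ``max(bin) + 1`` on the training data.  With ``n_bags > 0`` the model is
    the graph-wise average over bootstrap refits.
    """
    config = config or EBMTrainConfig()
    X, y = _check_inputs(X_binned, y)
    n, d = X.shape
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(d)]
    feature_ids = list(feature_ids)
    if len(feature_ids) != d:
        raise ValueError("feature_ids length mismatch")
    n_bins = [int(X[:, j].max()) + 1 for j in range(d)]

    if config.n_bags > 0:
        rng = np.random.default_rng(config.seed)
        acc_graphs = [np.zeros(nb) for nb in n_bins]
        acc_beta0 = 0.0
        done = 0
        for _ in range(config.n_bags):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.min() == yb.max():  # degenerate resample: skip
                continue
            b0, gs = _boost(X[idx], yb, n_bins, config)
            acc_beta0 += b0
            for g, a in zip(gs, acc_graphs):
                a += g
            done += 1
        if done == 0:
            raise ValueError("all bagging resamples were single-class")
        beta0 = acc_beta0 / done
        graphs = [a / done for a in acc_graphs]
    else:
        beta0, graphs = _boost(X, y, n_bins, config)

    # center each graph under the training bin distribution; fold into beta0
    shape_graphs: list[ShapeGraph] = []
    for j in range(d):
        weights = np.bincount(X[:, j], minlength=n_bins[j]) / n
        shift = float(graphs[j] @ weights)
        centered = graphs[j] - shift
        beta0 += shift
        shape_graphs.append(ShapeGraph(feature_ids[j], centered, weights))

    model = EBMModel(float(beta0), shape_graphs, feature_ids, np.zeros(d), config)
    model.relevance = global_relevance(model, X)
    return model


def local_explanations(model: EBMModel, X_binned: np.ndarray) -> np.ndarray:
    """(n_samples, n_features) matrix of per-sample additive contributions.

    Row sums plus the intercept reproduce :func:`predict_logit` exactly.
    Bin indices outside the trained range are clamped to the nearest realized bin.
    """
    X = np.asarray(X_binned, dtype=np.intp)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} feature columns, got shape {X.shape}"
        )
    out = np.empty(X.shape, dtype=float)
    for j, graph in enumerate(model.graphs):
        out[:, j] = graph(X[:, j])
    return out


def predict_logit(model: EBMModel, X_binned: np.ndarray) -> np.ndarray:
    return model.intercept + local_explanations(model, X_binned).sum(axis=1)


def predict_proba(model: EBMModel, X_binned: np.ndarray) -> np.ndarray:
    """P(y = 1) per sample."""
    return _sigmoid(predict_logit(model, X_binned))


def global_relevance(model: EBMModel, X_binned: np.ndarray) -> np.ndarray:
    """Mean absolute local contribution per feature over a reference set."""
    return np.abs(local_explanations(model, X_binned)).mean(axis=0)
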