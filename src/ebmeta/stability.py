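"""Selection- and rank-stability estimation across random data splits.

Two complementary questions about the pipeline's explanations:

* does the FDR screening pick the *same features* across perturbed versions of
  a dataset?  Quantified with the Nogueira chance-corrected stability of the
  binary selection matrix (1 = identical subsets, 0 = random selection), with
  an asymptotic-normal confidence interval and the conventional 0.4 / 0.7
  agreement thresholds.
* does the model rank the features' relevance *in the same order*?  Quantified
  with the hyperbolic-weighted Kendall tau between relevance vectors of every
  pair of splits — a rank correlation that penalizes disagreements at the top
  of the ranking (weight 1/(1+r) for rank r) more than in the uninformative
  tail.

The splitting schema is either RSSS (100 random stratified half-sample splits)
or the training folds of a repeated stratified CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ProfileDataset
from .evaluation import SplitPlan, cv_split_plan
from .preprocess import EmptySignatureError, PipelineConfig, fit_pipeline
from .reports import RankStabilityResult, StabilityResult


def rsss_splits(
    dataset: ProfileDataset, n_splits: int = 100, fraction: float = 0.5, seed: int = 0
) -> SplitPlan:
    """Random stability sub-sampling: stratified half-sample train/test splits."""
    y = dataset.binary_labels()
    if len(y) < 4:
        raise ValueError("need at least 4 samples")
    ids = np.asarray(dataset.sample_ids)
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        train: list[str] = []
        for cls in (0, 1):
            members = ids[y.to_numpy() == cls]
            n_train = int(round(fraction * len(members)))
            picked = rng.choice(members, size=n_train, replace=False)
            train.extend(picked)
        test = [s for s in ids if s not in set(train)]
        splits.append((train, test))
    return SplitPlan(splits=splits, schema="rsss", seed=seed)


def selection_and_relevance(
    dataset: ProfileDataset,
    plan: SplitPlan,
    config: Optional[PipelineConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the pipeline on every split's training half.

    Returns the splits x features binary selection matrix and the matching
    relevance matrix (EBM global relevance; 0 for unselected features).
    """
    config = config or PipelineConfig()
    features = pd.Index(dataset.feature_ids)
    sel_rows, rel_rows = [], []
    for train_ids, _ in plan.splits:
        try:
            pipe = fit_pipeline(dataset.subset(train_ids), config)
        except EmptySignatureError:
            # an empty selection is a legitimate outcome for the stability
            # statistics: an all-zero row (and zero relevance everywhere)
            sel_rows.append(pd.Series(0, index=features, dtype=int))
            rel_rows.append(pd.Series(0.0, index=features))
            continue
        rel = pipe.relevance_vector()
        rel_rows.append(rel)
        sel = pd.Series(0, index=rel.index, dtype=int)
        sel.loc[pipe.selected_ids] = 1
        sel_rows.append(sel)
    return pd.DataFrame(sel_rows).reset_index(drop=True), pd.DataFrame(
        rel_rows
    ).reset_index(drop=True)


def nogueira_stability(Z: np.ndarray | pd.DataFrame, alpha: float = 0.05) -> StabilityResult:
    """Chance-corrected stability of a splits x features binary selection matrix.

    The point estimate is

        S = 1 - mean_f s_f^2 / ((kbar/d) (1 - kbar/d)),

    with s_f^2 = M/(M-1) p_f (1 - p_f) the unbiased selection variance of
    feature f, p_f its selection frequency over the M splits, and kbar the mean
    number of features selected per split.  The confidence interval uses the
    estimator's asymptotic normality with variance
    (4/M^2) sum_i (phi_i - mean phi)^2, where

        phi_i = [mean_f(Z_if p_f) - k_i kbar / d^2
                 + (S/2) (2 k_i kbar / d^2 - k_i/d - kbar/d + 1)] / denom.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("selection matrix must be 2-D with at least 2 splits")
    if not np.all(np.isin(Z, (0.0, 1.0))):
        raise ValueError("selection matrix entries must be 0/1")
    M, d = Z.shape
    p_f = Z.mean(axis=0)
    k_rows = Z.sum(axis=1)
    kbar = float(k_rows.mean())
    if kbar == 0 or kbar == d:
        raise ValueError(
            "stability undefined: every split selects "
            + ("no features" if kbar == 0 else "all features")
        )
    denom = (kbar / d) * (1.0 - kbar / d)
    s2 = (M / (M - 1.0)) * p_f * (1.0 - p_f)
    score = 1.0 - s2.mean() / denom

    phi = (
        (Z * p_f).mean(axis=1)
        - k_rows * kbar / d**2
        + (score / 2.0) * (2.0 * k_rows * kbar / d**2 - k_rows / d - kbar / d + 1.0)
    ) / denom
    variance = 4.0 / M**2 * np.sum((phi - phi.mean()) ** 2)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(variance)
    return StabilityResult(
        score=float(score),
        ci_low=float(score - half),
        ci_high=float(score + half),
        alpha=alpha,
    )


def hwt(relevance_a: Sequence[float], relevance_b: Sequence[float]) -> float:
    """Hyperbolic-weighted Kendall tau between two relevance vectors.

    Inputs are scores over the same item set, higher = more relevant (the item
    with the largest score has rank 0).  Exchanges between items of rank r and
    s cost w(r) + w(s) with the additive hyperbolic weight w(r) = 1/(1+r); the
    statistic is symmetrized by averaging over which vector provides the ranks,
    and normalized so that hwt(a, a) = 1 and an exact reversal gives -1.  Tied
    scores are handled by the underlying exchange-counting (a pair tied in both
    vectors is neither concordant nor discordant).
    """
    a = np.asarray(relevance_a, dtype=float)
    b = np.asarray(relevance_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("relevance vectors must be 1-D and of equal length")
    # scipy's weightedtau default is exactly this statistic: additive
    # hyperbolic weigher, rank-averaged over (a, b) and (b, a)
    return float(stats.weightedtau(a, b).statistic)


def rank_stability(
    relevances: np.ndarray | pd.DataFrame,
) -> RankStabilityResult:
    """Mean pairwise hwt over per-split relevance vectors, with 0.25/0.75 quantiles."""
    R = np.asarray(relevances, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("need at least 2 relevance vectors")
    pairwise = [float(hwt(R[i], R[j])) for i, j in combinations(range(R.shape[0]), 2)]
    arr = np.asarray(pairwise)
    return RankStabilityResult(
        mean=float(arr.mean()),
        q25=float(np.quantile(arr, 0.25)),
        q75=float(np.quantile(arr, 0.75)),
        pairwise=pairwise,
    )


@dataclass
class StabilityAnalysis:
    """Joint selection- and rank-stability outcome under one splitting schema."""

    selection: StabilityResult
    rank: RankStabilityResult
    schema: str


def stability_analysis(
    dataset: ProfileDataset,
    config: Optional[PipelineConfig] = None,
    schema: str = "rsss",
    n_splits: int = 100,
    cv_k: int = 10,
    cv_repeats: int = 20,
    seed: int = 0,
) -> StabilityAnalysis:
    """End-to-end stability run on one binary-labeled dataset.

    ``schema="rsss"`` uses random half-sample splits; ``schema="cv"`` uses the
    training folds of a repeated stratified k-fold CV (larger training sets).
    """
    if schema == "rsss":
        plan = rsss_splits(dataset, n_splits=n_splits, seed=seed)
    elif schema == "cv":
        plan = cv_split_plan(dataset, k=cv_k, repeats=cv_repeats, seed=seed)
    else:
        raise ValueError(f"unknown schema {schema!r}")
    Z, R = selection_and_relevance(dataset, plan, config)
    return StabilityAnalysis(
        selection=nogueira_stability(Z.to_numpy()),
        rank=rank_stability(R.to_numpy()),
        schema=schema,
    )
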