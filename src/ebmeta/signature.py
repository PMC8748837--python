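"""Consensus signature across LOPO runs, permutation significance, metabolites.

Each leave-one-project-out run yields a global-relevance vector over the full
feature space (features failing the run's FDR screening enter as 0).  The
consensus score of feature i over p runs is

    score_i = (sum of per-run min-max rescaled relevances) / (p - nz_i + 1),

where nz_i counts the runs in which the feature had non-zero relevance: the
divisor rewards features that recur across projects and shrinks those that
shine in a single study.

Significance of the validation score obtained on the consensus support is
assessed with a label-permutation test: refit/rescore B times with permuted
outcomes, and report p = (#{permuted >= observed} + 1) / (B + 1), so the best
attainable p with B = 100 is 1/101 and the worst is 1.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import ProfileDataset
from .evaluation import olopo, repeated_cv
from .preprocess import PipelineConfig
from .reports import ConsensusSignature, PermutationTestResult


def consensus_signature(
    relevance_runs: pd.DataFrame | np.ndarray,
    p: Optional[int] = None,
    eps: float = 0.0,
) -> ConsensusSignature:
    """Aggregate per-run relevance vectors into the consensus signature.

    ``relevance_runs`` is runs x features (one row per LOPO run).  ``p``
    defaults to the number of rows and must match it; ``eps`` is the threshold
    below which a relevance counts as zero.
    """
    runs = (
        relevance_runs
        if isinstance(relevance_runs, pd.DataFrame)
        else pd.DataFrame(np.asarray(relevance_runs, dtype=float))
    )
    n_runs = runs.shape[0]
    if p is None:
        p = n_runs
    if p != n_runs:
        raise ValueError(f"got {n_runs} relevance runs but p={p} projects")
    values = runs.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("relevance scores must be nonnegative")

    rescaled = np.zeros_like(values)
    for i in range(n_runs):
        lo, hi = values[i].min(), values[i].max()
        if hi > lo:
            rescaled[i] = (values[i] - lo) / (hi - lo)
        else:
            warnings.warn(f"run {i} has constant relevance; contributes zeros",
                          stacklevel=2)
    nz = (values > eps).sum(axis=0)
    scores = rescaled.sum(axis=0) / (p - nz + 1)
    idx = runs.columns
    return ConsensusSignature(
        scores=pd.Series(scores, index=idx),
        p=int(p),
        nz=pd.Series(nz.astype(int), index=idx),
    )


def permutation_pvalue(observed: float, perm_scores: Sequence[float]) -> float:
    """Add-one permutation p-value: (#{perm >= observed} + 1) / (B + 1)."""
    perm = np.asarray(perm_scores, dtype=float)
    if perm.size < 1:
        raise ValueError("need at least one permutation score")
    return float((np.sum(perm >= observed) + 1) / (perm.size + 1))


def permutation_significance(
    dataset: ProfileDataset,
    signature_support: Sequence[str],
    config: Optional[PipelineConfig] = None,
    n_permutations: int = 100,
    seed: int = 0,
    mode: str = "cv",
    cv_repeats: int = 10,
    cv_k: int = 10,
) -> PermutationTestResult:
    """Label-permutation significance of the validation score on fixed features.

    The pipeline is trained only on the consensus-signature support (the
    screening stage is bypassed).  ``mode="cv"`` scores with the mean AUROC of
    a repeated stratified k-fold CV on the pooled healthy/crc samples;
    ``mode="olopo"`` scores with the mean o-LOPO AUROC.  Each of the B
    permutations shuffles the condition labels of the pooled samples and
    rescores from scratch.
    """
    support = list(signature_support)
    if not support:
        raise ValueError("signature support is empty")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    config = (config or PipelineConfig()).with_mask(support)

    def score(ds: ProfileDataset) -> float:
        if mode == "cv":
            mask = ds.metadata["condition"].isin(["healthy", "crc"])
            binary = ds.subset(list(ds.metadata.index[mask]))
            return repeated_cv(binary, config, k=cv_k, repeats=cv_repeats, seed=seed).mean
        if mode == "olopo":
            return olopo(ds, support, config).mean_auroc()
        raise ValueError(f"unknown mode {mode!r}")

    observed = score(dataset)
    rng = np.random.default_rng(seed)
    perm_scores = []
    for _ in range(n_permutations):
        shuffled = dataset.metadata.copy()
        shuffled["condition"] = rng.permutation(shuffled["condition"].to_numpy())
        perm_scores.append(score(ProfileDataset(dataset.matrix, shuffled)))
    return PermutationTestResult(
        observed=float(observed),
        perm_scores=[float(s) for s in perm_scores],
        p_value=permutation_pvalue(observed, perm_scores),
    )


def read_compound_map(path: str | Path) -> dict[str, set[str]]:
    """Read a compound -> KEGG-ortholog map TSV (columns compound_id, ko_id)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("compound_id", "ko_id") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: compound map missing columns {missing}")
    out: dict[str, set[str]] = {}
    for compound, ko in zip(frame["compound_id"], frame["ko_id"]):
        out.setdefault(compound, set()).add(ko)
    return out


def metabolite_scores(
    signature: ConsensusSignature, compound_to_ko: Mapping[str, set[str] | Sequence[str]]
) -> pd.Series:
    """Roll KEGG-ortholog signature scores up to metabolites.

    A compound's score is the sum of the consensus scores of the orthologs that
    produce or consume it; orthologs absent from the signature contribute 0.
    """
    if not compound_to_ko:
        raise ValueError("compound -> KO map is empty")
    scores = {}
    for compound, kos in compound_to_ko.items():
        scores[compound] = float(
            sum(signature.scores.get(ko, 0.0) for ko in set(kos))
        )
    return pd.Series(scores).rename_axis("compound_id")
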