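"""Risk-ordering test on unseen conditions (adenoma analysis).

The classifier is only ever trained on healthy vs CRC, yet a useful risk score
should place intermediate lesions between the two: healthy < small adenoma <
adenoma < tumor.  The test: (1) pool all projects and split the non-comorbid
healthy/CRC samples 0.7/0.3 into learning and validation sets; every remaining
sample (adenomas, other conditions, comorbid CRC) forms the test set.  (2) Fit
the pipeline on the learning set, predict P(CRC) for validation and test
samples, and compare condition groups with one-sided Mann-Whitney rank tests
(e.g. healthy < adenoma).  Healthy and tumor probabilities come from the
validation split — unseen by the model — so every compared distribution is
independent of the fit.  (3) Repeat 100 times and report per comparison the
*hit ratio*: the fraction of repeats significant at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import train_test_split

from .data import CONDITIONS, ProfileDataset, concat_datasets
from .preprocess import PipelineConfig, fit_pipeline, predict_proba
from .reports import HitRatioReport


@dataclass(frozen=True)
class ComparisonSpec:
    """One directed comparison: ``lesser`` group stochastically below ``greater``."""

    lesser: str
    greater: str
    label: str

    def __post_init__(self) -> None:
        vocab = set(CONDITIONS) | {"tumor"}
        for side in (self.lesser, self.greater):
            if side not in vocab:
                raise ValueError(f"unknown condition {side!r} in comparison")
        if self.lesser == self.greater:
            raise ValueError("comparison needs two distinct conditions")


#: The five comparisons of the radar plot, with the directions as labeled
#: there (including healthy < small adenoma).  ``tumor`` denotes the held-out
#: validation CRC samples.
DEFAULT_COMPARISONS = (
    ComparisonSpec("adenoma", "tumor", "A < T"),
    ComparisonSpec("healthy", "adenoma", "H < A"),
    ComparisonSpec("healthy", "small_adenoma", "H < S"),
    ComparisonSpec("small_adenoma", "adenoma", "S < A"),
    ComparisonSpec("healthy", "tumor", "H < T"),
)


def mann_whitney_one_sided(
    x_lesser: Sequence[float], y_greater: Sequence[float]
) -> float:
    """One-sided Mann-Whitney p for x stochastically smaller than y.

    Exact enumeration when the combined sample size is at most 12 and there
    are no ties; normal approximation with tie correction otherwise.
    """
    x = np.asarray(x_lesser, dtype=float)
    y = np.asarray(y_greater, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="less", method=method).pvalue
    )


def adenoma_partition(
    dataset: ProfileDataset, seed: int = 0, learning_fraction: float = 0.7
) -> tuple[ProfileDataset, ProfileDataset, ProfileDataset]:
    """Split the pooled dataset into (learning, validation, test).

    Learning/validation is a stratified ``learning_fraction`` split of the
    non-comorbid healthy and CRC samples; the test set collects everything
    else (adenomas, other conditions, comorbid CRC).  The three parts are
    pairwise disjoint and cover the dataset.
    """
    meta = dataset.metadata
    if not meta["condition"].isin(["adenoma", "small_adenoma"]).any():
        raise ValueError("dataset contains no adenoma samples to test on")
    eligible = meta["condition"].isin(["healthy", "crc"]) & ~meta["comorbidity"]
    train_ids = np.asarray(meta.index[eligible])
    strata = meta.loc[train_ids, "condition"].to_numpy()
    learn_ids, valid_ids = train_test_split(
        train_ids,
        train_size=learning_fraction,
        stratify=strata,
        random_state=seed,
    )
    test_ids = [s for s in meta.index if s not in set(train_ids)]
    return (
        dataset.subset(list(learn_ids)),
        dataset.subset(list(valid_ids)),
        dataset.subset(test_ids),
    )


def _groups(validation: ProfileDataset, test: ProfileDataset, probs) -> dict:
    """Condition group -> predicted probabilities.

    ``healthy`` and ``tumor`` come from the validation split (unseen by the
    model); every other condition from the test split.
    """
    v_cond = validation.metadata["condition"]
    t_cond = test.metadata["condition"]
    groups = {
        "healthy": probs.loc[v_cond.index[v_cond == "healthy"]].to_numpy(),
        "tumor": probs.loc[v_cond.index[v_cond == "crc"]].to_numpy(),
    }
    for cond in ("adenoma", "small_adenoma", "other"):
        ids = t_cond.index[t_cond == cond]
        groups[cond] = probs.loc[ids].to_numpy()
    return groups


def run_hit_ratio_test(
    dataset: ProfileDataset,
    config: Optional[PipelineConfig] = None,
    comparisons: Sequence[ComparisonSpec] = DEFAULT_COMPARISONS,
    n_repeats: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> HitRatioReport:
    """Repeated partition/fit/test loop; per-comparison hit fractions.

    A repeat where one of a comparison's groups is empty is skipped for that
    comparison only, with the denominator adjusted accordingly (and a warning).
    """
    if not comparisons:
        raise ValueError("need at least one comparison")
    config = config or PipelineConfig()
    hits = {c.label: 0 for c in comparisons}
    counted = {c.label: 0 for c in comparisons}
    rng = np.random.default_rng(seed)
    for _ in range(n_repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        learning, validation, test = adenoma_partition(dataset, seed=rep_seed)
        pipe = fit_pipeline(learning, config)
        held_out = concat_datasets([validation, test])
        probs = predict_proba(pipe, held_out)
        groups = _groups(validation, test, probs)
        for comp in comparisons:
            x = groups.get(comp.lesser, np.array([]))
            y = groups.get(comp.greater, np.array([]))
            if x.size == 0 or y.size == 0:
                warnings.warn(
                    f"comparison {comp.label!r}: empty group in a repeat; skipped",
                    stacklevel=2,
                )
                continue
            counted[comp.label] += 1
            if mann_whitney_one_sided(x, y) < alpha:
                hits[comp.label] += 1
    ratios = {
        label: (hits[label] / counted[label]) if counted[label] else float("nan")
        for label in hits
    }
    return HitRatioReport(
        ratios=ratios,
        n_effective=counted,
        n_repeats=n_repeats,
        alpha=alpha,
        seed=seed,
    )
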