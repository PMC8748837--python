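"""Result containers and their JSON serialization.

Every report type round-trips through :func:`write_report_json` /
:func:`read_report_json`.  NaN scores (e.g. undefined AUROC cells where a test
project lacks one of the two classes) are serialized as JSON ``null`` and
restored as NaN.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

#: Agreement thresholds conventionally quoted with the stability score:
#: below 0.4 poor agreement, 0.4-0.7 good enough, above 0.7 near perfect.
STABILITY_THRESHOLDS = (0.4, 0.7)


def _f(x: Any) -> float:
    """null -> NaN for float fields."""
    return math.nan if x is None else float(x)


def _flist(xs: Any) -> list[float]:
    return [_f(x) for x in xs]


@dataclass
class StabilityResult:
    """Chance-corrected feature-selection stability with its confidence interval."""

    score: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    thresholds: tuple[float, float] = STABILITY_THRESHOLDS

    def to_payload(self) -> dict:
        return {
            "score": self.score,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "alpha": self.alpha,
            "thresholds": list(self.thresholds),
        }

    @classmethod
    def from_payload(cls, p: dict) -> "StabilityResult":
        return cls(
            score=_f(p["score"]),
            ci_low=_f(p["ci_low"]),
            ci_high=_f(p["ci_high"]),
            alpha=float(p["alpha"]),
            thresholds=tuple(p["thresholds"]),
        )


@dataclass
class RankStabilityResult:
    """Mean pairwise rank correlation across splits, with spread quantiles."""

    mean: float
    q25: float
    q75: float
    pairwise: list[float] = field(default_factory=list)

    def to_payload(self) -> dict:
        return {
            "mean": self.mean,
            "q25": self.q25,
            "q75": self.q75,
            "pairwise": list(self.pairwise),
        }

    @classmethod
    def from_payload(cls, p: dict) -> "RankStabilityResult":
        return cls(_f(p["mean"]), _f(p["q25"]), _f(p["q75"]), _flist(p["pairwise"]))


@dataclass
class PerformanceResult:
    """AUROC summary over a set of evaluation splits (mean, 0.25/0.75 quantiles)."""

    aurocs: list[float]
    mean: float
    q25: float
    q75: float
    schema: str = "repeated_cv"

    def to_payload(self) -> dict:
        return {
            "aurocs": list(self.aurocs),
            "mean": self.mean,
            "q25": self.q25,
            "q75": self.q75,
            "schema": self.schema,
        }

    @classmethod
    def from_payload(cls, p: dict) -> "PerformanceResult":
        return cls(
            _flist(p["aurocs"]), _f(p["mean"]), _f(p["q25"]), _f(p["q75"]), p["schema"]
        )


@dataclass
class CrossPredictionMatrix:
    """Train-project x test-project AUROC table.

    Rows are training sources (projects, optionally plus ``LOPO``/``oLOPO``
    aggregate rows); columns are test targets.  Undefined cells are NaN.
    """

    table: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrossPredictionMatrix):
            return NotImplemented
        a, b = self.table, other.table
        return (
            list(a.index) == list(b.index)
            and list(a.columns) == list(b.columns)
            and np.allclose(a.to_numpy(float), b.to_numpy(float), equal_nan=True)
        )

    def to_payload(self) -> dict:
        return {
            "rows": list(self.table.index),
            "columns": list(self.table.columns),
            "values": [
                [None if pd.isna(v) else float(v) for v in row]
                for row in self.table.to_numpy()
            ],
        }

    @classmethod
    def from_payload(cls, p: dict) -> "CrossPredictionMatrix":
        values = [[_f(v) for v in row] for row in p["values"]]
        return cls(pd.DataFrame(values, index=p["rows"], columns=p["columns"]))


@dataclass
class ConsensusSignature:
    """Per-feature relevance aggregated over leave-one-project-out runs.

    ``scores`` holds the consensus score (sum of per-run min-max rescaled
    relevances divided by ``p - nz + 1``), ``nz`` the number of runs in which
    the feature had non-zero relevance, and ``p`` the number of projects/runs.
    """

    scores: pd.Series
    p: int
    nz: pd.Series

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConsensusSignature):
            return NotImplemented
        return (
            self.p == other.p
            and self.scores.equals(other.scores)
            and self.nz.equals(other.nz)
        )

    def support(self, eps: float = 0.0) -> list[str]:
        """Feature ids with consensus score strictly above ``eps``."""
        return list(self.scores.index[self.scores > eps])

    def top(self, n: int) -> list[str]:
        return list(self.scores.sort_values(ascending=False).index[:n])

    def to_payload(self) -> dict:
        return {
            "feature_ids": list(self.scores.index),
            "scores": [float(v) for v in self.scores],
            "p": self.p,
            "nz": [int(v) for v in self.nz],
        }

    @classmethod
    def from_payload(cls, p: dict) -> "ConsensusSignature":
        idx = pd.Index(p["feature_ids"])
        return cls(
            pd.Series(_flist(p["scores"]), index=idx),
            int(p["p"]),
            pd.Series([int(v) for v in p["nz"]], index=idx),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "nz": self.nz},
            index=self.scores.index,
        ).rename_axis("feature_id")


@dataclass
class PermutationTestResult:
    """Observed validation score against a label-permutation null distribution."""

    observed: float
    perm_scores: list[float]
    p_value: float

    def to_payload(self) -> dict:
        return {
            "observed": self.observed,
            "perm_scores": list(self.perm_scores),
            "p_value": self.p_value,
        }

    @classmethod
    def from_payload(cls, p: dict) -> "PermutationTestResult":
        return cls(_f(p["observed"]), _flist(p["perm_scores"]), _f(p["p_value"]))


@dataclass
class HitRatioReport:
    """Per-comparison fraction of repeats passing a one-sided rank test.

    ``ratios`` maps a comparison label (e.g. ``"H < A"``) to the fraction of
    counted repeats with one-sided p < ``alpha``; ``n_effective`` gives the
    number of repeats in which both groups were non-empty.
    """

    ratios: dict[str, float]
    n_effective: dict[str, int]
    n_repeats: int = 100
    alpha: float = 0.05
    seed: int = 0

    def to_payload(self) -> dict:
        return {
            "ratios": {k: v for k, v in self.ratios.items()},
            "n_effective": dict(self.n_effective),
            "n_repeats": self.n_repeats,
            "alpha": self.alpha,
            "seed": self.seed,
        }

    @classmethod
    def from_payload(cls, p: dict) -> "HitRatioReport":
        return cls(
            {k: _f(v) for k, v in p["ratios"].items()},
            {k: int(v) for k, v in p["n_effective"].items()},
            int(p["n_repeats"]),
            float(p["alpha"]),
            int(p["seed"]),
        )


_REPORT_TYPES = {
    cls.__name__: cls
    for cls in (
        StabilityResult,
        RankStabilityResult,
        PerformanceResult,
        CrossPredictionMatrix,
        ConsensusSignature,
        PermutationTestResult,
        HitRatioReport,
    )
}


def _sanitize(obj: Any) -> Any:
    """Make a payload strictly JSON-serializable; NaN becomes null."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (str, int, bool)) or obj is None:
        return obj
    raise TypeError(f"unserializable report field of type {type(obj).__name__}")


def write_report_json(report: Any, path: str | Path) -> None:
    """Serialize any report type to JSON; ``read(write(x)) == x``."""
    name = type(report).__name__
    if name not in _REPORT_TYPES:
        raise TypeError(f"unknown report type {name!r}")
    doc = {
        "schema_version": SCHEMA_VERSION,
        "type": name,
        "payload": _sanitize(report.to_payload()),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, allow_nan=False)
        fh.write("\n")


def read_report_json(path: str | Path) -> Any:
    with open(path) as fh:
        doc = json.load(fh)
    name = doc.get("type")
    if name not in _REPORT_TYPES:
        raise TypeError(f"unknown report type {name!r} in {path}")
    return _REPORT_TYPES[name].from_payload(doc["payload"])
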