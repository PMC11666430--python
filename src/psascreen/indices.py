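"""Composite inflammation indices and the PSAII construction rule.

Each index is a product-quotient of serum components:

    value = (prod of numerator components) / (prod of denominator components * scale)

The catalogue covers the eight published composite indices (SII, NLR, PLR,
LMR, NPR, SIM, PAR, CALLY) plus PSAII, the psoriatic-arthritis inflammation
index

    PSAII = lymphocyte% * CRP / (neutrophil count * eosinophil count * 10)

with published screening cutoff 18.  All indices are oriented
higher-indicates-PSA except CALLY, where values *below* the cutoff (0.61)
indicate PSA.  :func:`construct_index_from_ors` implements the development
rule that produced PSAII from a logistic model: eligible features with odds
ratio above 1 form the numerator, below 1 the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "IndexDefinition",
    "compute_index",
    "builtin_catalogue",
    "get_index",
    "classify",
    "construct_index_from_ors",
    "IndexScorer",
    "IndexClassifier",
]

HIGHER = "higher-indicates-PSA"
LOWER = "lower-indicates-PSA"


@dataclass(frozen=True)
class IndexDefinition:
    """A composite index as numerator/denominator component sets."""

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...] = ()
    scale: float = 1.0
    orientation: str = HIGHER
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if not self.numerator:
            raise ValueError(f"{self.name}: numerator must be nonempty")
        overlap = set(self.numerator) & set(self.denominator)
        if overlap:
            raise ValueError(f"{self.name}: components on both sides: {overlap}")
        if self.scale <= 0:
            raise ValueError(f"{self.name}: scale must be positive")
        if self.orientation not in (HIGHER, LOWER):
            raise ValueError(f"{self.name}: unknown orientation {self.orientation!r}")

    @property
    def components(self) -> tuple[str, ...]:
        return self.numerator + self.denominator

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "numerator": list(self.numerator),
            "denominator": list(self.denominator),
            "scale": self.scale,
            "orientation": self.orientation,
            "cutoff": self.cutoff,
        }


def compute_index(defn: IndexDefinition, subject) -> float | pd.Series:
    """Evaluate an index for one subject (mapping) or a whole table.

    Raises a KeyError for a missing component and a ZeroDivisionError-style
    ValueError naming the subject when the denominator product vanishes.
    """
    if isinstance(subject, pd.DataFrame):
        missing = [c for c in defn.components if c not in subject.columns]
        if missing:
            raise KeyError(f"{defn.name}: missing component(s) {missing}")
        num = subject[list(defn.numerator)].prod(axis=1)
        den = subject[list(defn.denominator)].prod(axis=1) * defn.scale if defn.denominator \
            else pd.Series(defn.scale, index=subject.index)
        zero = den == 0
        if zero.any():
            raise ValueError(
                f"{defn.name}: zero denominator for subject(s) "
                f"{subject.index[zero].tolist()[:5]}"
            )
        return (num / den).rename(defn.name)
    missing = [c for c in defn.components if c not in subject]
    if missing:
        raise KeyError(f"{defn.name}: missing component(s) {missing}")
    num = math.prod(float(subject[c]) for c in defn.numerator)
    den = math.prod(float(subject[c]) for c in defn.denominator) * defn.scale
    if den == 0:
        raise ValueError(f"{defn.name}: zero denominator for subject {subject!r}")
    return num / den


def builtin_catalogue() -> list[IndexDefinition]:
    """The eight published composite indices plus PSAII."""
    return [
        IndexDefinition("SII", ("platelet_count", "neutrophil_count"),
                        ("lymphocyte_count",)),
        IndexDefinition("NLR", ("neutrophil_count",), ("lymphocyte_count",)),
        IndexDefinition("PLR", ("platelet_count",), ("lymphocyte_count",)),
        IndexDefinition("LMR", ("lymphocyte_count",), ("monocyte_count",)),
        IndexDefinition("NPR", ("neutrophil_count",), ("platelet_count",)),
        IndexDefinition("SIM", ("monocyte_count", "neutrophil_count"),
                        ("lymphocyte_count",)),
        IndexDefinition("PAR", ("platelet_count",), ("albumin",)),
        IndexDefinition("CALLY", ("albumin", "lymphocyte_count"), ("crp",),
                        scale=10.0, orientation=LOWER, cutoff=0.61),
        IndexDefinition("PSAII", ("lymphocyte_pct", "crp"),
                        ("neutrophil_count", "eosinophil_count"),
                        scale=10.0, cutoff=18.0),
    ]


def get_index(name: str) -> IndexDefinition:
    """Look up one catalogue index by name."""
    for defn in builtin_catalogue():
        if defn.name == name:
            return defn
    raise KeyError(f"no builtin index named {name!r}")


def classify(value: float, cutoff: float, orientation: str = HIGHER) -> str:
    """Strict-inequality screening call for a single index value.

    Higher-indicates-PSA: positive iff value > cutoff; lower-indicates-PSA:
    positive iff value < cutoff.  Equality is negative either way.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if orientation == HIGHER:
        return "positive" if value > cutoff else "negative"
    if orientation == LOWER:
        return "positive" if value < cutoff else "negative"
    raise ValueError(f"unknown orientation {orientation!r}")


def construct_index_from_ors(
    ors: Mapping[str, float],
    eligible: Iterable[str],
    scale: float = 1.0,
    name: str = "constructed",
) -> IndexDefinition:
    """Build an index from logistic odds ratios by the PSAII development rule.

    Eligible features with OR > 1 go to the numerator, OR < 1 to the
    denominator; OR exactly 1 contributes nothing.  Features outside
    ``eligible`` (e.g. demographics like age) are ignored.  Component order
    follows the iteration order of ``ors``.
    """
    eligible = set(eligible)
    for feat, value in ors.items():
        if feat in eligible and not (np.isfinite(value) and value > 0):
            raise ValueError(f"odds ratio for {feat!r} must be finite and positive")
    numerator = tuple(f for f, v in ors.items() if f in eligible and v > 1)
    denominator = tuple(f for f, v in ors.items() if f in eligible and v < 1)
    if not numerator:
        raise ValueError("construction failed: no eligible feature has OR > 1")
    return IndexDefinition(name, numerator, denominator, scale=scale)


class IndexScorer(BaseEstimator, TransformerMixin):
    """Transformer appending one column per index to a cohort table."""

    def __init__(self, definitions: list[IndexDefinition] | None = None):
        self.definitions = definitions

    def fit(self, X: pd.DataFrame, y=None):
        defs = self.definitions if self.definitions is not None else builtin_catalogue()
        self.definitions_ = [
            d for d in defs if all(c in X.columns for c in d.components)
        ]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "definitions_")
        out = X.copy()
        for defn in self.definitions_:
            out[defn.name] = compute_index(defn, X)
        return out


class IndexClassifier(BaseEstimator, ClassifierMixin):
    """Screening classifier for one composite index.

    ``fit`` computes the index on the training table and, unless a fixed
    cutoff was supplied, selects the sensitivity/specificity-balancing
    cutoff on it.  ``predict`` applies the strict-inequality rule.
    """

    def __init__(self, definition: IndexDefinition, cutoff: float | None = None):
        self.definition = definition
        self.cutoff = cutoff

    def fit(self, X: pd.DataFrame, y):
        from .metrics import select_cutoff

        y = np.asarray(y)
        self.classes_ = np.unique(y)
        scores = np.asarray(compute_index(self.definition, X), dtype=float)
        if self.cutoff is not None:
            self.cutoff_ = float(self.cutoff)
        elif self.definition.cutoff is not None:
            self.cutoff_ = float(self.definition.cutoff)
        else:
            self.cutoff_ = select_cutoff(scores, y, orientation=self.definition.orientation)
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "cutoff_")
        scores = np.asarray(compute_index(self.definition, X), dtype=float)
        return scores if self.definition.orientation == HIGHER else -scores

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "cutoff_")
        scores = np.asarray(compute_index(self.definition, X), dtype=float)
        if self.definition.orientation == HIGHER:
            return (scores > self.cutoff_).astype(int)
        return (scores < self.cutoff_).astype(int)
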