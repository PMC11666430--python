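"""Cohort table I/O, category encoding, imputation and normalization.

A cohort table is a pandas DataFrame with one row per subject, a binary
``label`` column (0 = psoriasis, 1 = psoriatic arthritis), optional
``subject_id`` / ``cohort`` metadata columns, and numeric clinical/serum
variables (counts in 10^9/L, percentages in %, CRP in mg/dL, albumin in
g/dL).  Raw categorical vocabularies are encoded to the integer codes used
throughout: male 1 / female 0, yes 1 / no 0, race codes 1-5, rash-severity
codes 1-4.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORY_CODES",
    "SchemaError",
    "load_cohort",
    "encode_categories",
    "decode_categories",
    "filter_missingness",
    "impute_missing",
    "minmax_normalize",
    "RegressionForestImputer",
    "MinMaxNormalizer",
]

METADATA_COLUMNS = ("subject_id", "cohort", "label")

#: Documented category vocabularies and their integer codes.
CATEGORY_CODES: dict[str, dict[str, int]] = {
    "sex": {"male": 1, "female": 0},
    "yes_no": {"yes": 1, "no": 0},
    "race": {
        "mexican_american": 1,
        "other_hispanic": 2,
        "non_hispanic_white": 3,
        "non_hispanic_black": 4,
        "other_race": 5,
    },
    "education": {
        "below_junior_high": 1,
        "no_high_school_diploma": 2,
        "high_school_graduate": 3,
        "some_college": 4,
        "college_graduate": 5,
    },
    "rash_range": {
        "little_or_no": 1,
        "few_patches": 2,
        "scattered_patches": 3,
        "extensive": 4,
    },
}

#: Which vocabulary applies to which column.
_COLUMN_VOCAB = {
    "sex": "sex",
    "gender": "sex",
    "race": "race",
    "education": "education",
    "rash_range": "rash_range",
    "smoking": "yes_no",
    "drinking": "yes_no",
    "diabetes": "yes_no",
    "hypertension": "yes_no",
    "arthralgia": "yes_no",
}


class SchemaError(ValueError):
    """Raised when a cohort file violates the expected schema."""


def load_cohort(path, schema: list[str] | None = None) -> pd.DataFrame:
    """Read a cohort CSV (one header row, blank cells = missing).

    ``schema`` optionally lists the expected variable columns; columns
    outside the schema (and metadata) are dropped with a logged warning,
    and a missing schema column raises :class:`SchemaError`.  Non-numeric
    cells in numeric columns raise a parse error naming row and column.
    """
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise SchemaError(f"{path}: required column 'label' is missing")
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: schema columns missing: {missing}")
        known = set(schema) | set(METADATA_COLUMNS)
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            logger.warning("%s: ignoring unknown columns %s", path, unknown)
            df = df.drop(columns=unknown)
    numeric_cols = [
        c for c in df.columns
        if c not in ("subject_id", "cohort") and df[c].dtype == object
    ]
    for c in numeric_cols:
        # object columns are either raw categorical vocab or mis-typed numerics
        vocab = _COLUMN_VOCAB.get(c)
        if vocab is not None:
            continue
        parsed = pd.to_numeric(df[c], errors="coerce")
        bad = parsed.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{path}: non-numeric value {df[c].iloc[row]!r} in column "
                f"{c!r} at row {row}"
            )
        df[c] = parsed
    bad_labels = set(df["label"].dropna().unique()) - {0, 1}
    if df["label"].isna().any() or bad_labels:
        raise SchemaError(f"{path}: label must be 0/1 with no missing values")
    df["label"] = df["label"].astype(int)
    return df


def encode_categories(table: pd.DataFrame) -> pd.DataFrame:
    """Encode raw categorical tokens to their documented integer codes."""
    out = table.copy()
    for col in out.columns:
        vocab_name = _COLUMN_VOCAB.get(col)
        if vocab_name is None or out[col].dtype != object:
            continue
        vocab = CATEGORY_CODES[vocab_name]
        tokens = out[col].dropna().unique()
        unknown = [t for t in tokens if t not in vocab]
        if unknown:
            raise ValueError(
                f"unknown category token(s) {unknown} in variable {col!r}; "
                f"expected one of {sorted(vocab)}"
            )
        out[col] = out[col].map(vocab).astype(float)
    return out


def decode_categories(table: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`encode_categories` on the documented vocabularies."""
    out = table.copy()
    for col in out.columns:
        vocab_name = _COLUMN_VOCAB.get(col)
        if vocab_name is None or col not in out.columns:
            continue
        if out[col].dtype == object:
            continue
        inverse = {v: k for k, v in CATEGORY_CODES[vocab_name].items()}
        out[col] = out[col].map(lambda v: inverse.get(v, v) if pd.notna(v) else v)
    return out


def filter_missingness(
    table: pd.DataFrame, max_fraction: float = 1.0 / 3.0
) -> pd.DataFrame:
    """Drop subjects with more than ``max_fraction`` of variables missing."""
    cols = [c for c in table.columns if c not in METADATA_COLUMNS]
    frac = table[cols].isna().mean(axis=1)
    keep = frac <= max_fraction
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d subject(s) exceeding %.0f%% missingness",
                       dropped, 100 * max_fraction)
    return table.loc[keep].copy()


class RegressionForestImputer(BaseEstimator, TransformerMixin):
    """Iterative chained imputation with a regression-forest learner.

    Each incomplete variable is regressed on all the others with a random
    forest and the cycle repeats until the relative change falls below
    ``tol`` or ``max_iter`` rounds have run.  Imputed values are clamped to
    the range observed at fit time; observed cells are never altered.
    Deterministic given ``random_state``.
    """

    def __init__(self, n_estimators: int = 100, max_iter: int = 10,
                 tol: float = 1e-3, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _split(self, X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
        meta = [c for c in X.columns if c in METADATA_COLUMNS]
        return X.drop(columns=meta), meta

    def fit(self, X: pd.DataFrame, y=None):
        values, _ = self._split(X)
        all_missing = values.columns[values.isna().all()].tolist()
        if all_missing:
            raise ValueError(f"variable(s) entirely missing: {all_missing}")
        self.feature_names_in_ = np.asarray(values.columns, dtype=object)
        self.imputer_ = IterativeImputer(
            estimator=RandomForestRegressor(
                n_estimators=self.n_estimators, random_state=self.random_state
            ),
            max_iter=self.max_iter,
            tol=self.tol,
            min_value=values.min().to_numpy(),
            max_value=values.max().to_numpy(),
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            # the round-limit convergence warning is expected at max_iter
            warnings.simplefilter("ignore")
            self.imputer_.fit(values)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "imputer_")
        values, meta = self._split(X)
        values = values[list(self.feature_names_in_)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filled = self.imputer_.transform(values)
        out = X.copy()
        out[list(self.feature_names_in_)] = filled
        return out


def impute_missing(table: pd.DataFrame, seed: int = 0,
                   **imputer_kwargs) -> pd.DataFrame:
    """Filter subjects over the 1/3-missingness rule, then impute the rest."""
    kept = filter_missingness(table)
    if not kept.drop(columns=[c for c in METADATA_COLUMNS if c in kept], errors="ignore").isna().any().any():
        return kept
    imputer = RegressionForestImputer(random_state=seed, **imputer_kwargs)
    return imputer.fit_transform(kept)


class MinMaxNormalizer(BaseEstimator, TransformerMixin):
    """Min-max normalization E(x) = (x - min) / (max - min) with train/apply split.

    Per-variable min and max are fitted on the training partition only and
    reused on held-out rows, whose normalized values may therefore fall
    outside [0, 1].  A constant variable maps to 0 everywhere.
    """

    def __init__(self, columns: list[str] | None = None):
        self.columns = columns

    def _resolve(self, X: pd.DataFrame) -> list[str]:
        if self.columns is not None:
            return list(self.columns)
        return [c for c in X.columns if c not in METADATA_COLUMNS]

    def fit(self, X: pd.DataFrame, y=None):
        cols = self._resolve(X)
        self.columns_ = cols
        self.scaler_ = MinMaxScaler(clip=False)
        self.scaler_.fit(X[cols])
        self.data_min_ = pd.Series(self.scaler_.data_min_, index=cols)
        self.data_max_ = pd.Series(self.scaler_.data_max_, index=cols)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "scaler_")
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise KeyError(f"variables absent from table: {missing}")
        out = X.copy()
        out[self.columns_] = self.scaler_.transform(X[self.columns_])
        return out


def minmax_normalize(params: MinMaxNormalizer, table: pd.DataFrame) -> pd.DataFrame:
    """Apply a fitted :class:`MinMaxNormalizer` to a cohort table."""
    return params.transform(table)
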