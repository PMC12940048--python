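"""Tabular cleaning, min-max normalization and stratified partitioning.

The universal payload is :class:`FeatureTable`: a numeric attribute matrix
plus a binary outcome vector (1 = case, 0 = control).  Normalization is
always fitted on training data only and applied to held-out data with the
stored per-attribute minima/maxima, so the test set never leaks into the
affine map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .rng import as_generator

MISSING_MARKERS = {"", "NA", "na", "NaN", "nan"}


class PreprocessError(ValueError):
    """Raised when a table cannot be cleaned, normalized or split."""


@dataclass
class FeatureTable:
    """Rows of numeric attributes plus a binary outcome per subject."""

    attribute_names: list
    values: np.ndarray  # (n_rows, n_attributes) float
    outcome: np.ndarray  # (n_rows,) int in {0, 1}

    def __post_init__(self):
        self.attribute_names = list(self.attribute_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.outcome), -1)
        self.outcome = np.asarray(self.outcome, dtype=int)
        if self.values.shape[0] != self.outcome.shape[0]:
            raise PreprocessError("row count of values must equal outcome length")
        if self.values.shape[1] != len(self.attribute_names):
            raise PreprocessError("attribute_names length must match value columns")
        if self.outcome.size and not np.isin(self.outcome, (0, 1)).all():
            raise PreprocessError("outcome entries must be 0 or 1")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def take_rows(self, idx) -> "FeatureTable":
        idx = np.asarray(idx, dtype=int)
        return FeatureTable(self.attribute_names, self.values[idx], self.outcome[idx])

    def select_attributes(self, mask) -> "FeatureTable":
        """Restrict to the attributes where ``mask`` (bool per column) is set."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_attributes,):
            raise PreprocessError("mask length must equal attribute count")
        names = [n for n, m in zip(self.attribute_names, mask) if m]
        return FeatureTable(names, self.values[:, mask], self.outcome)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.attribute_names)
        df["Outcome"] = self.outcome
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        if "Outcome" not in df.columns:
            raise PreprocessError("expected a column named 'Outcome'")
        outcome = df["Outcome"].to_numpy()
        if np.isnan(np.asarray(outcome, dtype=float)).any():
            raise PreprocessError("Outcome column contains missing values")
        attrs = [c for c in df.columns if c != "Outcome"]
        values = df[attrs].to_numpy(dtype=float)
        return cls(attrs, values, outcome.astype(int))

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, na_values=sorted(MISSING_MARKERS), keep_default_na=False)
        return cls.from_dataframe(df)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class NormalizationParams:
    """Per-attribute observed minima and maxima from the fitting table."""

    attribute_names: list
    observed_min: np.ndarray
    observed_max: np.ndarray

    def __post_init__(self):
        self.observed_min = np.asarray(self.observed_min, dtype=float)
        self.observed_max = np.asarray(self.observed_max, dtype=float)
        if (self.observed_max < self.observed_min).any():
            raise PreprocessError("observed_max must be >= observed_min")

    def to_json(self) -> str:
        return json.dumps(
            {
                n: {"min": float(lo), "max": float(hi)}
                for n, lo, hi in zip(self.attribute_names, self.observed_min, self.observed_max)
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationParams":
        d = json.loads(text)
        names = list(d)
        return cls(names, [d[n]["min"] for n in names], [d[n]["max"] for n in names])

    def invert(self, table: FeatureTable) -> FeatureTable:
        """Map normalized values back to original units."""
        span = self.observed_max - self.observed_min
        return FeatureTable(
            table.attribute_names,
            table.values * span + self.observed_min,
            table.outcome,
        )


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    k_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise PreprocessError("train_fraction must be in (0, 1)")
        if self.k_folds < 2:
            raise PreprocessError("k_folds must be >= 2")


@dataclass
class CleaningReport:
    duplicate_rows_removed: int = 0
    rows_removed_missing: int = 0
    values_imputed: int = 0
    attributes_removed: list = field(default_factory=list)
    notes: list = field(default_factory=list)


def clean(
    table: FeatureTable,
    missing_policy: str = "drop",
    zeros_as_missing=(),
) -> tuple[FeatureTable, CleaningReport]:
    """Remove duplicate rows, zero-variance attributes and missing values.

    ``missing_policy`` is ``"drop"`` (remove offending rows, the default) or
    ``"median"`` (impute the attribute median).  ``zeros_as_missing`` names
    attributes whose literal 0 entries are recoded as missing first — off by
    default because the reference summary statistics report 0 as a genuine
    minimum for several attributes.
    """
    if table.n_rows < 1 or table.n_attributes < 1:
        raise PreprocessError("table must have at least one row and one attribute")
    if missing_policy not in ("drop", "median"):
        raise PreprocessError(f"unknown missing_policy {missing_policy!r}")
    report = CleaningReport()
    values = table.values.copy()
    names = list(table.attribute_names)
    outcome = table.outcome.copy()

    for col in zeros_as_missing:
        if col not in names:
            raise PreprocessError(f"unknown attribute {col!r} in zeros_as_missing")
        j = names.index(col)
        zeros = values[:, j] == 0.0
        values[zeros, j] = np.nan
        if zeros.any():
            report.notes.append(f"recoded {int(zeros.sum())} zeros as missing in {col}")

    missing = np.isnan(values)
    if missing.any():
        if missing_policy == "drop":
            keep = ~missing.any(axis=1)
            report.rows_removed_missing = int((~keep).sum())
            values, outcome = values[keep], outcome[keep]
        else:
            for j in range(values.shape[1]):
                col_missing = missing[:, j]
                if col_missing.any():
                    med = np.nanmedian(values[:, j])
                    if np.isnan(med):
                        raise PreprocessError(
                            f"attribute {names[j]!r} is entirely missing"
                        )
                    values[col_missing, j] = med
                    report.values_imputed += int(col_missing.sum())
    if values.shape[0] == 0:
        raise PreprocessError("all rows removed during cleaning: unusable dataset")

    # exact duplicates (attributes + outcome)
    full = np.column_stack([values, outcome])
    _, first_idx = np.unique(full, axis=0, return_index=True)
    keep = np.zeros(values.shape[0], dtype=bool)
    keep[np.sort(first_idx)] = True
    report.duplicate_rows_removed = int((~keep).sum())
    values, outcome = values[keep], outcome[keep]

    variances = values.var(axis=0)
    redundant = variances == 0.0
    if redundant.any():
        report.attributes_removed = [n for n, r in zip(names, redundant) if r]
        names = [n for n, r in zip(names, redundant) if not r]
        values = values[:, ~redundant]
    if values.shape[1] == 0:
        raise PreprocessError("all attributes removed during cleaning: unusable dataset")
    return FeatureTable(names, values, outcome), report


def min_max_fit_transform(table: FeatureTable) -> tuple[FeatureTable, NormalizationParams]:
    """Fit per-attribute min/max on ``table`` and rescale it to [0, 1]."""
    lo = table.values.min(axis=0)
    hi = table.values.max(axis=0)
    if np.isnan(table.values).any():
        raise PreprocessError("table contains missing values; clean it first")
    degenerate = hi <= lo
    if degenerate.any():
        bad = [n for n, d in zip(table.attribute_names, degenerate) if d]
        raise PreprocessError(f"constant attribute(s) reached normalization: {bad}")
    params = NormalizationParams(list(table.attribute_names), lo, hi)
    return min_max_apply(table, params, _warn_out_of_range=False), params


def min_max_apply(
    table: FeatureTable,
    params: NormalizationParams,
    _warn_out_of_range: bool = True,
) -> FeatureTable:
    """Apply stored (training-set) min/max to ``table``.

    Held-out values outside the fitted range map outside [0, 1]; that is
    permitted (the affine map is not clipped) but flagged with a warning.
    """
    if list(table.attribute_names) != list(params.attribute_names):
        raise PreprocessError("attribute names do not match normalization params")
    span = params.observed_max - params.observed_min
    if (span <= 0).any():
        bad = [n for n, s in zip(params.attribute_names, span) if s <= 0]
        raise PreprocessError(f"degenerate normalization params for: {bad}")
    scaled = (table.values - params.observed_min) / span
    if _warn_out_of_range and ((scaled < 0) | (scaled > 1)).any():
        warnings.warn(
            "values outside the fitted min/max range map outside [0, 1]",
            stacklevel=2,
        )
    return FeatureTable(table.attribute_names, scaled, table.outcome)


def _per_class_train_counts(class_sizes: dict, train_fraction: float) -> dict:
    """Largest-remainder allocation of train slots per class.

    Remainder ties go to the larger class, then by label for determinism.
    """
    total_train = int(round(train_fraction * sum(class_sizes.values())))
    floors = {c: int(np.floor(train_fraction * n)) for c, n in class_sizes.items()}
    remainder = total_train - sum(floors.values())
    fracs = {c: train_fraction * n - floors[c] for c, n in class_sizes.items()}
    order = sorted(class_sizes, key=lambda c: (-fracs[c], -class_sizes[c], c))
    counts = dict(floors)
    for c in order[:remainder]:
        counts[c] += 1
    return counts


def stratified_split(table: FeatureTable, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Partition rows into stratified train/test tables, reproducibly."""
    classes, sizes = np.unique(table.outcome, return_counts=True)
    if len(classes) < 2:
        raise PreprocessError("both outcome classes must be present")
    if (sizes < 2).any():
        raise PreprocessError("each class needs at least 2 members to stratify")
    counts = _per_class_train_counts(dict(zip(classes.tolist(), sizes.tolist())), spec.train_fraction)
    rng = as_generator(spec.seed)
    train_idx, test_idx = [], []
    for c in classes.tolist():
        idx = np.flatnonzero(table.outcome == c)
        idx = rng.permutation(idx)
        train_idx.append(idx[: counts[c]])
        test_idx.append(idx[counts[c]:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise PreprocessError("degenerate split: one side received no rows")
    test_classes = np.unique(table.outcome[test_idx])
    if len(test_classes) < 2:
        warnings.warn("test split is missing one outcome class", stacklevel=2)
    return table.take_rows(train_idx), table.take_rows(test_idx)


def kfold_indices(table: FeatureTable, spec: SplitSpec) -> list:
    """Stratified k-fold (train_idx, val_idx) pairs partitioning all rows."""
    if spec.k_folds > table.n_rows:
        raise PreprocessError("k_folds exceeds number of rows")
    _, sizes = np.unique(table.outcome, return_counts=True)
    if (sizes < spec.k_folds).any():
        raise PreprocessError("each class needs >= k_folds members for stratified folding")
    skf = StratifiedKFold(n_splits=spec.k_folds, shuffle=True, random_state=spec.seed % (2**32))
    return [
        (np.asarray(tr), np.asarray(va))
        for tr, va in skf.split(table.values, table.outcome)
    ]
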