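"""Binary diagnostic-criteria datasets: I/O, validation and descriptives.

The central container is :class:`CriteriaDataset`, a person x criterion matrix
of 0/1 indicators with a group label per person (e.g. ``"men"`` / ``"women"``).
The canonical criterion set is the nine DSM-5 indicators for gambling disorder
(A1 tolerance ... A9 bailout); a diagnosed sample requires every row to meet at
least four of them.

Descriptive operations: per-group prevalence table with chi-square group
comparison and Cramer's V, and Cronbach's alpha for internal consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DataValidationError,
    EmptyInputError,
    ParameterError,
    SchemaError,
    UndefinedReliabilityError,
)

__all__ = [
    "CriterionDefinition",
    "CriteriaDataset",
    "CsvSchema",
    "DSM5_GD_CRITERIA",
    "read_criteria_csv",
    "write_criteria_csv",
    "validate_diagnosis",
    "prevalence_table",
    "cronbach_alpha",
]


@dataclass(frozen=True)
class CriterionDefinition:
    """A single binary diagnostic criterion: short code plus free-text label."""

    code: str
    label: str = ""


#: Canonical DSM-5 gambling-disorder criteria (standard manual wording).
DSM5_GD_CRITERIA: tuple[CriterionDefinition, ...] = (
    CriterionDefinition("A1", "Needs to gamble with increasing amounts of money "
                              "in order to achieve the desired excitement (tolerance)"),
    CriterionDefinition("A2", "Restless or irritable when attempting to cut down "
                              "or stop gambling (withdrawal)"),
    CriterionDefinition("A3", "Has made repeated unsuccessful efforts to control, "
                              "cut back, or stop gambling"),
    CriterionDefinition("A4", "Is often preoccupied with gambling"),
    CriterionDefinition("A5", "Often gambles when feeling distressed"),
    CriterionDefinition("A6", "After losing money gambling, often returns another "
                              "day to get even (chasing one's losses)"),
    CriterionDefinition("A7", "Lies to conceal the extent of involvement with gambling"),
    CriterionDefinition("A8", "Has jeopardized or lost a significant relationship, job, "
                              "or educational or career opportunity because of gambling"),
    CriterionDefinition("A9", "Relies on others to provide money to relieve desperate "
                              "financial situations caused by gambling (bailout)"),
)


def _check_unique_codes(criteria: Sequence[CriterionDefinition]) -> None:
    codes = [c.code for c in criteria]
    if len(set(codes)) != len(codes):
        raise DataValidationError(f"criterion codes are not unique: {codes}")


@dataclass
class CriteriaDataset:
    """Validated person x criterion binary matrix with per-person group labels.

    Parameters
    ----------
    matrix
        ``(n_persons, n_criteria)`` array; every cell must be exactly 0 or 1.
    groups
        Length-``n_persons`` array of categorical group labels (free strings).
    criteria
        Ordered criterion definitions; length must equal the column count.
    """

    matrix: np.ndarray
    groups: np.ndarray
    criteria: Sequence[CriterionDefinition] = field(default=DSM5_GD_CRITERIA)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.matrix.ndim != 2:
            raise DataValidationError("matrix must be 2-dimensional")
        if self.matrix.shape[0] == 0:
            raise EmptyInputError("dataset contains no rows")
        _check_unique_codes(self.criteria)
        if self.matrix.shape[1] != len(self.criteria):
            raise DataValidationError(
                f"matrix has {self.matrix.shape[1]} columns but "
                f"{len(self.criteria)} criterion definitions"
            )
        if self.groups.shape[0] != self.matrix.shape[0]:
            raise DataValidationError("groups length does not match matrix rows")
        bad = ~np.isin(self.matrix, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DataValidationError(
                f"non-binary cell at row {r}, column {self.criteria[c].code!r}: "
                f"{self.matrix[r, c]!r}"
            )
        self.matrix = self.matrix.astype(np.int8)

    @property
    def n_persons(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_criteria(self) -> int:
        return self.matrix.shape[1]

    @property
    def codes(self) -> list[str]:
        return [c.code for c in self.criteria]

    def group_labels(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        return list(pd.unique(self.groups))

    def subset(self, group: str) -> "CriteriaDataset":
        """Rows belonging to one group (row order preserved)."""
        mask = self.groups == group
        if not mask.any():
            raise ParameterError(f"no rows with group label {group!r}")
        return replace(self, matrix=self.matrix[mask], groups=self.groups[mask])

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_dataframe(self, group_column: str = "group") -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.codes)
        df[group_column] = self.groups
        return df


@dataclass(frozen=True)
class CsvSchema:
    """Column mapping for criteria CSV files.

    ``criterion_columns`` maps CSV column name -> criterion code (order of the
    mapping defines node order); ``group_column`` names the group-label column.
    ``yes_token``/``no_token`` let files use textual encodings ("Yes"/"No").
    """

    criterion_columns: Mapping[str, str]
    group_column: str = "group"
    yes_token: str = "Yes"
    no_token: str = "No"

    @classmethod
    def default(cls, group_column: str = "group") -> "CsvSchema":
        return cls({c.code: c.code for c in DSM5_GD_CRITERIA}, group_column)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CsvSchema":
        try:
            cols = dict(d["criterion_columns"])
        except KeyError as exc:
            raise SchemaError("schema is missing 'criterion_columns'") from exc
        return cls(
            criterion_columns=cols,
            group_column=d.get("group_column", "group"),
            yes_token=d.get("yes_token", "Yes"),
            no_token=d.get("no_token", "No"),
        )


def read_criteria_csv(
    path: str | Path,
    schema: CsvSchema | None = None,
    criteria: Sequence[CriterionDefinition] | None = None,
) -> CriteriaDataset:
    """Read a one-row-per-person criteria CSV into a validated dataset.

    Cells may be ``0``/``1`` integers or the schema's yes/no tokens
    (case-insensitive). Row order is preserved.
    """
    schema = schema or CsvSchema.default()
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: no data rows")
    missing = [c for c in (*schema.criterion_columns, schema.group_column)
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    mapping = {"0": 0, "1": 1,
               schema.yes_token.lower(): 1, schema.no_token.lower(): 0}
    n = df.shape[0]
    mat = np.empty((n, len(schema.criterion_columns)), dtype=np.int8)
    for j, col in enumerate(schema.criterion_columns):
        vals = df[col].astype(str).str.strip().str.lower()
        coded = vals.map(mapping)
        if coded.isna().any():
            i = int(coded.index[coded.isna()][0])
            raise DataValidationError(
                f"{path}: non-binary value {df[col].iloc[i]!r} at row {i}, "
                f"column {col!r}"
            )
        mat[:, j] = coded.to_numpy()

    if criteria is None:
        by_code = {c.code: c for c in DSM5_GD_CRITERIA}
        criteria = [by_code.get(code, CriterionDefinition(code))
                    for code in schema.criterion_columns.values()]
    return CriteriaDataset(mat, df[schema.group_column].to_numpy(), criteria)


def write_criteria_csv(
    ds: CriteriaDataset, path: str | Path, group_column: str = "group"
) -> None:
    """Write the dataset as a 0/1 CSV (round-trips exactly through the reader)."""
    ds.to_dataframe(group_column).to_csv(path, index=False)


def validate_diagnosis(
    ds: CriteriaDataset, min_criteria: int = 4
) -> tuple[CriteriaDataset, int]:
    """Restrict to rows meeting at least ``min_criteria`` criteria.

    The default threshold of 4 is the DSM-5 diagnostic cut-off for gambling
    disorder. Returns the restricted dataset and the number of rows dropped.
    Idempotent; ``min_criteria=0`` is the identity.
    """
    if not 0 <= min_criteria <= ds.n_criteria:
        raise ParameterError(
            f"min_criteria must be in 0..{ds.n_criteria}, got {min_criteria}"
        )
    keep = ds.row_sums() >= min_criteria
    dropped = int((~keep).sum())
    if dropped == 0:
        return ds, 0
    if not keep.any():
        raise EmptyInputError("no rows meet the diagnostic threshold")
    return replace(ds, matrix=ds.matrix[keep], groups=ds.groups[keep]), dropped


def _cramers_v(chi2: float, n: int, r: int, c: int) -> float:
    denom = n * (min(r, c) - 1)
    return float(np.sqrt(chi2 / denom)) if denom > 0 else 0.0


def prevalence_table(
    ds: CriteriaDataset, continuity_correction: bool = False
) -> pd.DataFrame:
    """Per-group criterion prevalences with a between-group chi-square test.

    For each criterion the group x met contingency table is tested with the
    chi-square statistic (Yates continuity correction off by default) and the
    effect size reported as Cramer's V. Criteria met by everyone or no one in
    all groups have no between-group information; they are reported as
    degenerate (statistic 0, p = 1, V = 0) and flagged.

    Returns a tidy frame with one row per criterion: per-group ``count_<g>``,
    ``n_<g>``, ``prev_<g>`` columns plus ``chi2``, ``p_value``, ``cramers_v``,
    ``degenerate``.
    """
    labels = ds.group_labels()
    if not labels:
        raise ParameterError("dataset has no groups")
    rows = []
    for j, crit in enumerate(ds.criteria):
        row: dict = {"criterion": crit.code, "label": crit.label}
        counts = []
        for g in labels:
            mask = ds.groups == g
            n_g = int(mask.sum())
            if n_g == 0:
                raise ParameterError(f"group {g!r} has n=0")
            met = int(ds.matrix[mask, j].sum())
            counts.append((met, n_g - met))
            row[f"count_{g}"] = met
            row[f"n_{g}"] = n_g
            row[f"prev_{g}"] = met / n_g
        table = np.array(counts).T  # 2 x n_groups: met / not-met by group
        degenerate = (table.sum(axis=1) == 0).any() or len(labels) < 2
        if degenerate:
            chi2, p, v = 0.0, 1.0, 0.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(
                table, correction=continuity_correction
            )
            v = _cramers_v(chi2, ds.n_persons, *table.shape)
        row.update(chi2=float(chi2), p_value=float(p), cramers_v=v,
                   degenerate=bool(degenerate))
        rows.append(row)
    return pd.DataFrame(rows)


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha for a persons x items score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total scores).
    Applicable at item or criterion level; may be negative. Raises if the
    total-score variance is zero (reliability undefined).
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ParameterError("need a 2-D matrix with at least 2 items")
    if x.shape[0] < 2:
        raise ParameterError("need at least 2 persons")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedReliabilityError("total-score variance is zero")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))
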