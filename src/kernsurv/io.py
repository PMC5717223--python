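"""Data containers, readers and per-profile preprocessing.

Omic profiles are subjects x biomarkers numeric matrices.  Continuous
profiles (mRNA, miRNA, methylation, copy number) are column-standardized
to mean zero, variance one before kernel construction; somatic mutation
profiles stay on the raw 0/1 scale so that the kernel diagonal equals the
normalized per-subject mutation burden.  Standardization statistics are
always estimated on training data and applied unchanged to validation
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicMatrix",
    "SurvivalOutcome",
    "ClinicalTable",
    "StandardizationStats",
    "read_omic_matrix",
    "write_omic_matrix",
    "read_clinical_table",
    "read_survival_outcome",
    "read_gene_list",
    "standardize_profile",
    "impute_and_filter",
    "align_subjects",
]

CONTINUOUS = "continuous"
BINARY = "binary"


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class OmicMatrix:
    """One molecular profile, oriented subjects (rows) x biomarkers (columns).

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix indexed by subject id, columns are biomarker ids.
        NaN marks missing cells (continuous profiles only).
    profile_kind : {"continuous", "binary"}
        Binary profiles (somatic mutation) must contain only 0/1 and are
        never centered or scaled.
    profile_name : str
        Label such as ``"mRNA"``.
    """

    values: pd.DataFrame
    profile_kind: str = CONTINUOUS
    profile_name: str = "omic"

    def __post_init__(self) -> None:
        if self.profile_kind not in (CONTINUOUS, BINARY):
            raise ValueError(f"unknown profile_kind {self.profile_kind!r}")
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "subject ids")
        _check_unique(self.values.columns, "biomarker ids")
        if self.values.shape[1] < 1:
            raise ValueError("profile must have at least one biomarker")
        if self.profile_kind == BINARY:
            arr = self.values.to_numpy()
            finite = arr[np.isfinite(arr)]
            if not np.isin(finite, (0.0, 1.0)).all():
                raise ValueError(
                    f"binary profile {self.profile_name!r} contains values "
                    "outside {0, 1}"
                )

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def biomarker_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_biomarkers(self) -> int:
        return self.values.shape[1]

    def subset_subjects(self, ids: Sequence[str]) -> "OmicMatrix":
        return OmicMatrix(self.values.loc[list(ids)], self.profile_kind, self.profile_name)

    def subset_biomarkers(self, ids: Sequence[str]) -> "OmicMatrix":
        return OmicMatrix(self.values.loc[:, list(ids)], self.profile_kind, self.profile_name)


@dataclass
class SurvivalOutcome:
    """Right-censored survival outcome: positive times, 0/1 event flags."""

    values: pd.DataFrame  # columns: time, event; index: subject id

    def __post_init__(self) -> None:
        required = {"time", "event"}
        if not required.issubset(self.values.columns):
            raise ValueError("outcome table needs columns 'time' and 'event'")
        _check_unique(self.values.index, "subject ids")
        if (self.values["time"] <= 0).any():
            raise ValueError("all survival times must be positive")
        ev = self.values["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def time(self) -> np.ndarray:
        return self.values["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.values["event"].to_numpy(int)

    @property
    def n_events(self) -> int:
        return int(self.values["event"].sum())

    def subset_subjects(self, ids: Sequence[str]) -> "SurvivalOutcome":
        return SurvivalOutcome(self.values.loc[list(ids)])


@dataclass
class ClinicalTable:
    """Fixed-effect covariates, numeric after indicator encoding."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "subject ids")
        _check_unique(self.values.columns, "covariate names")
        nonnum = self.values.select_dtypes(exclude="number").columns.tolist()
        if nonnum:
            # expand categorical columns into 0/1 indicators (drop-first)
            self.values = pd.get_dummies(
                self.values, columns=nonnum, drop_first=True, dtype=float
            )
        if self.values.isna().any().any():
            raise ValueError("clinical table contains missing values after encoding")
        self.values = self.values.astype(float)

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def covariate_names(self) -> list:
        return list(self.values.columns)

    def subset_subjects(self, ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.values.loc[list(ids)])


@dataclass
class StandardizationStats:
    """Training-set column means/SDs plus the ids of dropped biomarkers."""

    mean: pd.Series
    sd: pd.Series
    dropped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            bad = self.sd.index[self.sd <= 0].tolist()
            raise ValueError(f"non-positive standard deviations for {bad}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_omic_matrix(
    path,
    profile_kind: str = CONTINUOUS,
    orientation: str = "subjects_rows",
    profile_name: str = "omic",
) -> OmicMatrix:
    """Read a tab-delimited numeric matrix into an :class:`OmicMatrix`.

    The file has one header row and one id column.  ``orientation`` says
    whether rows are subjects or biomarkers; the result is always oriented
    subjects x biomarkers.  Empty cells become NaN (missing).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise ValueError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}"
                )
        raise
    if orientation == "biomarkers_rows":
        df = df.T
    elif orientation != "subjects_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicMatrix(df, profile_kind=profile_kind, profile_name=profile_name)


def write_omic_matrix(Z: OmicMatrix, path) -> None:
    Z.values.to_csv(path, sep="\t", index_label="id")


def read_survival_outcome(path) -> SurvivalOutcome:
    """Read a TSV with columns subject_id, time, event."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return SurvivalOutcome(df[["time", "event"]])


def read_clinical_table(path, drop: Iterable[str] = ("time", "event")) -> ClinicalTable:
    """Read covariates from a clinical TSV, dropping outcome columns."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df = df.drop(columns=[c for c in drop if c in df.columns])
    return ClinicalTable(df)


def read_gene_list(path) -> tuple[str, list]:
    """Read a signature file: first line is the signature name, then one id per line."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"gene list {path} needs a name header and at least one id")
    return lines[0], lines[1:]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def standardize_profile(
    Z: OmicMatrix, stats: Optional[StandardizationStats] = None
) -> tuple[OmicMatrix, StandardizationStats]:
    """Column-standardize a continuous profile to mean 0, variance 1.

    The population standard deviation (divide by n) is used so that the
    linear kernel of a standardized profile has unit mean diagonal.  When
    ``stats`` is given (estimated on training data) it is applied
    unchanged: means/SDs are not recomputed and the same zero-variance
    columns are dropped.  Binary profiles must not be standardized.
    """
    if Z.profile_kind == BINARY:
        raise ValueError(
            "binary profiles are kept on the 0/1 scale; do not standardize "
            f"{Z.profile_name!r}"
        )
    if stats is None:
        mean = Z.values.mean(axis=0)
        sd = Z.values.std(axis=0, ddof=0)
        dropped = sd.index[sd <= 0].tolist()
        keep = sd.index[sd > 0]
        if len(keep) == 0:
            raise ValueError("all columns have zero variance")
        stats = StandardizationStats(mean[keep], sd[keep], dropped)
    else:
        missing = set(stats.mean.index) - set(Z.values.columns)
        if missing:
            raise ValueError(f"stats refer to absent biomarkers: {sorted(missing)[:5]}")
    kept = Z.values.loc[:, stats.mean.index]
    out = (kept - stats.mean) / stats.sd
    return OmicMatrix(out, Z.profile_kind, Z.profile_name), stats


def impute_and_filter(
    Z: OmicMatrix,
    max_missing_frac: float = 0.2,
    expression_filter: bool = False,
    expression_floor: float = 0.0,
) -> tuple[OmicMatrix, dict]:
    """Remove high-missingness biomarkers, mean-impute the rest.

    Biomarkers with a missing fraction strictly above ``max_missing_frac``
    are removed (the default 0.2 drops anything with more than 20% missing
    cells).  Remaining missing cells are set to the biomarker's observed
    mean.  With ``expression_filter`` on, biomarkers whose median value is
    at or below ``expression_floor`` are also removed — intended for
    median-normalized log expression, where a non-positive median marks a
    lowly-expressed gene.
    """
    vals = Z.values
    miss_frac = vals.isna().mean(axis=0)
    keep = miss_frac.index[miss_frac <= max_missing_frac]
    report = {
        "removed_missing": miss_frac.index[miss_frac > max_missing_frac].tolist(),
        "removed_low_expression": [],
        "imputed_cells": 0,
    }
    vals = vals.loc[:, keep]
    if expression_filter:
        med = vals.median(axis=0)
        low = med.index[med <= expression_floor]
        report["removed_low_expression"] = low.tolist()
        vals = vals.drop(columns=low)
    if vals.shape[1] == 0:
        raise ValueError("filtering removed every biomarker")
    n_missing = int(vals.isna().sum().sum())
    if n_missing:
        vals = vals.fillna(vals.mean(axis=0))
    report["imputed_cells"] = n_missing
    return OmicMatrix(vals, Z.profile_kind, Z.profile_name), report


def align_subjects(tables: Sequence) -> tuple[list, int]:
    """Restrict tables to the common subjects, in a shared order.

    Accepts any mix of :class:`OmicMatrix`, :class:`ClinicalTable` and
    :class:`SurvivalOutcome`.  The order of the first table's surviving
    subjects is imposed on all outputs.  Returns (aligned tables, number
    of subjects dropped across the union).
    """
    if not tables:
        raise ValueError("need at least one table")
    common = set(tables[0].subject_ids)
    union = set(tables[0].subject_ids)
    for t in tables[1:]:
        common &= set(t.subject_ids)
        union |= set(t.subject_ids)
    if not common:
        raise ValueError("no subjects shared by all tables")
    order = [s for s in tables[0].subject_ids if s in common]
    aligned = [t.subset_subjects(order) for t in tables]
    return aligned, len(union) - len(common)
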