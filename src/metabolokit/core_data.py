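"""Core data model and flat-file I/O.

The central container is :class:`Dataset`: a feature-by-sample intensity
matrix aligned with per-sample metadata (group factors, pairing subject,
batch, injection order, sample type) and per-feature annotations (external
identifiers, optional substructure fingerprints).  Statistics tables,
annotation sets (GMT) and weighted edge lists round-trip through plain
TSV/CSV so every analysis stage can be run standalone from files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "AnnotationSet",
    "ValidationReport",
    "read_dataset",
    "validate_dataset",
    "read_stats_table",
    "write_stats_table",
    "read_gmt",
    "write_gmt",
    "write_table",
]

SAMPLE_TYPES = ("biological", "qc", "blank")

#: canonical sample-metadata column names recognised throughout the package
SUBJECT_COL = "subject"
BATCH_COL = "batch"
ORDER_COL = "injection_order"
TYPE_COL = "sample_type"


class DataError(ValueError):
    """Raised when an input file or object violates the data model."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`: hard violations and warnings."""

    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff clean
        return self.ok and not self.warnings


@dataclass
class Dataset:
    """Feature x sample intensity matrix plus aligned metadata.

    Parameters
    ----------
    intensities
        DataFrame with feature ids as index and sample ids as columns.
        Values are non-negative reals; missing cells stay ``NaN`` and are
        never imputed by the constructor.
    sample_meta
        DataFrame indexed by sample id.  Recognised columns: arbitrary
        categorical group factors, ``subject`` (pairing), ``batch``,
        ``injection_order`` (int), ``sample_type`` in
        ``{"biological", "qc", "blank"}``.
    feature_meta
        DataFrame indexed by feature id; free-form annotation columns
        (external ids, fingerprint bit lists, ...).
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.intensities.columns)
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=self.intensities.index)
        if not self.intensities.index.is_unique:
            dup = self.intensities.index[self.intensities.index.duplicated()].unique()
            raise DataError(f"duplicate feature ids: {list(dup)}")
        if not self.intensities.columns.is_unique:
            dup = self.intensities.columns[self.intensities.columns.duplicated()].unique()
            raise DataError(f"duplicate sample ids: {list(dup)}")
        if not self.sample_meta.index.equals(self.intensities.columns):
            self.sample_meta = self.sample_meta.reindex(self.intensities.columns)
        if not self.feature_meta.index.equals(self.intensities.index):
            self.feature_meta = self.feature_meta.reindex(self.intensities.index)

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def sample_types(self) -> pd.Series:
        """Per-sample type; defaults to ``biological`` when absent."""
        if TYPE_COL in self.sample_meta.columns:
            return self.sample_meta[TYPE_COL].fillna("biological")
        return pd.Series("biological", index=self.intensities.columns)

    def biological_mask(self) -> np.ndarray:
        return (self.sample_types() == "biological").to_numpy()

    def with_intensities(self, values: pd.DataFrame) -> "Dataset":
        """Copy of the dataset with a replaced intensity matrix."""
        return Dataset(values, self.sample_meta.copy(), self.feature_meta.copy())

    def copy(self) -> "Dataset":
        return Dataset(
            self.intensities.copy(), self.sample_meta.copy(), self.feature_meta.copy()
        )


@dataclass
class AnnotationSet:
    """A named annotation term and its member entity ids (the ORA/FCS unit)."""

    term_id: str
    term_name: str
    members: frozenset[str]
    source: str = "custom"

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise DataError(f"annotation set {self.term_id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# intensity tables


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_dataset(
    data_path: str | Path,
    meta_columns: Sequence[str] = (),
    orientation: str = "features_as_rows",
    sep: str | None = None,
    sample_meta_path: str | Path | None = None,
) -> Dataset:
    """Read an intensity table (features as rows by default) into a Dataset.

    ``meta_columns`` name non-numeric per-sample columns when samples are
    rows (``orientation="samples_as_rows"``); with the default orientation
    the sample metadata arrives as a separate table via
    ``sample_meta_path`` (first column = sample id).

    Missing cells are preserved as NaN, never imputed.  Duplicate feature
    or sample ids and non-numeric intensity cells are hard errors.
    """
    s = _sep_for(data_path, sep)
    with open(data_path) as fh:
        header = fh.readline().rstrip("\n").split(s)[1:]
    dup_cols = pd.Index(header)[pd.Index(header).duplicated()].unique().tolist()
    if dup_cols and orientation == "features_as_rows":
        raise DataError(f"duplicate sample ids: {dup_cols}")
    if dup_cols and orientation == "samples_as_rows":
        raise DataError(f"duplicate feature ids: {dup_cols}")
    raw = pd.read_csv(data_path, sep=s, index_col=0, dtype=str)
    sample_meta = None
    if orientation == "samples_as_rows":
        meta = [c for c in meta_columns if c in raw.columns]
        missing_cols = set(meta_columns) - set(meta)
        if missing_cols:
            raise DataError(f"declared meta columns absent: {sorted(missing_cols)}")
        sample_meta = raw[meta].copy()
        raw = raw.drop(columns=meta).T
    elif orientation != "features_as_rows":
        raise DataError(f"unknown orientation {orientation!r}")

    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate feature ids: {dup}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise DataError(f"duplicate sample ids: {dup}")

    mat = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            row = raw.index[bad][0]
            raise DataError(
                f"non-numeric intensity at feature {row!r}, sample {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        mat[col] = converted

    if sample_meta_path is not None:
        sm = pd.read_csv(sample_meta_path, sep=_sep_for(sample_meta_path, sep), index_col=0)
        sample_meta = sm
    if sample_meta is not None and ORDER_COL in sample_meta.columns:
        sample_meta[ORDER_COL] = pd.to_numeric(sample_meta[ORDER_COL])
    return Dataset(mat, sample_meta)


def write_dataset(d: Dataset, data_path: str | Path, sample_meta_path: str | Path | None = None) -> None:
    d.intensities.to_csv(data_path, sep=_sep_for(data_path, None))
    if sample_meta_path is not None:
        d.sample_meta.to_csv(sample_meta_path, sep=_sep_for(sample_meta_path, None))


def validate_dataset(d: Dataset, design=None) -> ValidationReport:
    """Check Dataset invariants; returns a report instead of raising.

    An empty report (no violations, no warnings) means the dataset is
    clean.  A design (from :mod:`metabolokit.stats`) may be passed to
    additionally check that its factors exist and have enough levels.
    """
    rep = ValidationReport()
    vals = d.intensities.to_numpy(dtype=float)
    if (vals < 0).any():
        n = int((vals < 0).sum())
        rep.violations.append(f"{n} negative intensity value(s)")
    if BATCH_COL in d.sample_meta.columns and ORDER_COL in d.sample_meta.columns:
        order = d.sample_meta[ORDER_COL]
        for batch, grp in order.groupby(d.sample_meta[BATCH_COL]):
            g = grp.dropna()
            if g.duplicated().any():
                rep.violations.append(f"duplicate injection order in batch {batch!r}")
    if TYPE_COL in d.sample_meta.columns:
        bad = set(d.sample_meta[TYPE_COL].dropna()) - set(SAMPLE_TYPES)
        if bad:
            rep.violations.append(f"unknown sample_type value(s): {sorted(bad)}")
    if design is not None:
        for factor in design.factors:
            if factor not in d.sample_meta.columns:
                rep.violations.append(f"design factor {factor!r} missing from sample metadata")
            else:
                levels = d.sample_meta.loc[d.biological_mask(), factor].dropna().unique()
                if len(levels) < 2:
                    rep.warnings.append(
                        f"factor {factor!r} has {len(levels)} level(s); "
                        "at least 2 required for group comparison"
                    )
        if design.requires_subject and SUBJECT_COL not in d.sample_meta.columns:
            rep.violations.append("paired design requires a 'subject' metadata column")
    return rep


# ---------------------------------------------------------------------------
# statistics tables

STATS_COLUMNS = ["entity_id", "entity_type", "method", "statistic", "df", "p", "pFDR", "log2FC"]


def write_stats_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-entity statistics table as TSV (round-trip safe)."""
    table.to_csv(path, sep=_sep_for(path, None), index=False)


def read_stats_table(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep=_sep_for(path, None))
    if "p" in t.columns:
        bad = t["p"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise DataError("p-values outside [0, 1]")
    return t


def write_table(obj, path: str | Path) -> None:
    """Generic TSV writer for DataFrames produced by any stage."""
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep=_sep_for(path, None), index=False)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# GMT annotation sets


def read_gmt(path: str | Path, source: str = "custom") -> list[AnnotationSet]:
    """Read annotation sets from GMT (term, description, members...)."""
    sets: list[AnnotationSet] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            members = [m for m in parts[2:] if m]
            if not members:
                warnings.warn(f"GMT term {parts[0]!r} has no members; skipped")
                continue
            sets.append(AnnotationSet(parts[0], parts[1] or parts[0], frozenset(members), source))
    return sets


def write_gmt(sets: Iterable[AnnotationSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.members)]) + "\n")
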