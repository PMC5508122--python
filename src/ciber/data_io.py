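"""Reading, validating, and scoring questionnaire data.

A determinant study dataset is a rectangular respondents x variables table
of numeric item scores on bounded response scales (e.g., 7-point agreement
or semantic-differential items), usually exported from survey software as
delimited text.  This module wraps such tables in :class:`QuestionnaireDataset`,
attaches optional per-item display metadata (:class:`ItemMetadata`), and
scores multi-item target scales (e.g., a three-item intention measure) into
per-respondent composite scores.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell values treated as missing when no explicit list is given.
DEFAULT_MISSING_CODES = ("", "NA")


class DataError(ValueError):
    """Raised for malformed input files or invalid dataset operations."""


@dataclass
class ValidationReport:
    """Per-column accounting of missing and coerced cells produced on read."""

    missing_counts: dict[str, int] = field(default_factory=dict)
    coerced_cells: dict[str, int] = field(default_factory=dict)

    def log(self, log: logging.Logger = logger) -> None:
        for name, n in sorted(self.missing_counts.items()):
            if n:
                log.info("column %r: %d missing value(s)", name, n)
        for name, n in sorted(self.coerced_cells.items()):
            if n:
                log.warning("column %r: %d unparseable cell(s) coerced to missing", name, n)


@dataclass
class ItemMetadata:
    """Display metadata for one questionnaire item.

    ``left_anchor`` and ``right_anchor`` are the verbal labels of the scale
    endpoints (e.g., "much worse" / "much better" for a semantic
    differential).  Scale bounds may be left unset and inferred later from
    the observed data range.
    """

    item_id: str
    question_text: str = ""
    left_anchor: str = ""
    right_anchor: str = ""
    scale_min: float | None = None
    scale_max: float | None = None

    def __post_init__(self) -> None:
        if not self.item_id:
            raise DataError("item_id must be non-empty")
        if (
            self.scale_min is not None
            and self.scale_max is not None
            and not self.scale_min < self.scale_max
        ):
            raise DataError(
                f"item {self.item_id!r}: scale_min ({self.scale_min}) must be "
                f"strictly below scale_max ({self.scale_max})"
            )


class QuestionnaireDataset:
    """Respondents x variables table with explicit missingness.

    Thin wrapper around a :class:`pandas.DataFrame` (rows = respondents,
    columns = variables, ``NaN`` = missing) that enforces unique, non-empty
    variable names and carries the read-time validation report.
    """

    def __init__(self, data: pd.DataFrame, validation: ValidationReport | None = None):
        names = list(data.columns)
        if any(not isinstance(n, str) or not n for n in names):
            raise DataError("all variable names must be non-empty strings")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DataError(f"duplicate variable names: {dupes}")
        self.data = data.reset_index(drop=True)
        self.validation = validation or ValidationReport()

    @property
    def variable_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_respondents(self) -> int:
        return len(self.data)

    def require_columns(self, names: Sequence[str]) -> None:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise DataError(f"unknown variable name(s): {missing}")

    def numeric_column(self, name: str) -> np.ndarray:
        """Values of one variable as a float vector with NaN for missing."""
        self.require_columns([name])
        return pd.to_numeric(self.data[name], errors="coerce").to_numpy(dtype=float)

    def __repr__(self) -> str:
        return (
            f"QuestionnaireDataset({self.n_respondents} respondents x "
            f"{len(self.variable_names)} variables)"
        )


def _read_header(path: Path, delimiter: str) -> list[str]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise DataError(f"{path}: empty file") from None
    return header


def _sniff_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(
    path: str | Path,
    *,
    delimiter: str | None = None,
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
    numeric_columns: Sequence[str] | None = None,
) -> QuestionnaireDataset:
    """Read a delimited survey export into a :class:`QuestionnaireDataset`.

    Parameters
    ----------
    path
        CSV/TSV file with a mandatory header row of variable names.
    delimiter
        Field delimiter; inferred from the file extension when omitted.
    missing_codes
        Cell values (exact string match after stripping) treated as missing.
    numeric_columns
        Columns that must parse as numeric (typically the determinant and
        target columns).  Unparseable cells in these columns become missing
        and are counted in the validation report.  ``None`` attempts numeric
        coercion on every column but keeps fully non-numeric columns as text.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    delimiter = delimiter or _sniff_delimiter(path)

    header = _read_header(path, delimiter)
    if len(set(header)) != len(header):
        dupes = sorted({n for n in header if header.count(n) > 1})
        raise DataError(f"{path}: duplicate column header(s): {dupes}")

    frame = pd.read_csv(
        path,
        sep=delimiter,
        na_values=list(missing_codes),
        keep_default_na=False,
        skipinitialspace=True,
        dtype=str,
    )
    if frame.empty:
        raise DataError(f"{path}: header only, zero data rows")

    report = ValidationReport()
    targets = list(numeric_columns) if numeric_columns is not None else list(frame.columns)
    for name in targets:
        if name not in frame.columns:
            raise DataError(f"{path}: unknown column {name!r}")
        raw = frame[name]
        declared_missing = raw.isna()
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & ~declared_missing
        if numeric_columns is None and bad.all() and not declared_missing.all():
            # Entirely non-numeric column (e.g., free text) left as-is.
            report.missing_counts[name] = int(declared_missing.sum())
            continue
        frame[name] = coerced
        report.missing_counts[name] = int(coerced.isna().sum())
        report.coerced_cells[name] = int(bad.sum())
    report.log()
    return QuestionnaireDataset(frame, report)


def write_dataset(
    dataset: QuestionnaireDataset,
    path: str | Path,
    *,
    delimiter: str = ",",
    missing_code: str = "",
) -> None:
    """Write a dataset back to delimited text (round-trips with read_dataset)."""
    out = dataset.data.copy()
    for name in out.columns:
        col = out[name]
        if pd.api.types.is_float_dtype(col) and np.all(
            np.isnan(col.to_numpy()) | (np.mod(col.to_numpy(), 1) == 0)
        ):
            out[name] = col.astype("Int64")  # keep integer scores unpolluted by ".0"
    out.to_csv(path, sep=delimiter, index=False, na_rep=missing_code)


_METADATA_REQUIRED = ("id", "text", "left_anchor", "right_anchor")


def read_item_metadata(path: str | Path, *, delimiter: str | None = None) -> list[ItemMetadata]:
    """Read an item-metadata table (id, text, anchors, optional scale bounds)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    delimiter = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in _METADATA_REQUIRED if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing mandatory metadata column(s): {missing}")

    out: list[ItemMetadata] = []
    for _, row in frame.iterrows():
        bounds: dict[str, float | None] = {}
        for key in ("scale_min", "scale_max"):
            val = row.get(key, "")
            bounds[key] = float(val) if isinstance(val, str) and val.strip() else None
        out.append(
            ItemMetadata(
                item_id=row["id"],
                question_text=row["text"],
                left_anchor=row["left_anchor"],
                right_anchor=row["right_anchor"],
                scale_min=bounds["scale_min"],
                scale_max=bounds["scale_max"],
            )
        )
    return out


def write_item_metadata(items: Sequence[ItemMetadata], path: str | Path) -> None:
    rows = [
        {
            "id": it.item_id,
            "text": it.question_text,
            "left_anchor": it.left_anchor,
            "right_anchor": it.right_anchor,
            "scale_min": "" if it.scale_min is None else it.scale_min,
            "scale_max": "" if it.scale_max is None else it.scale_max,
        }
        for it in items
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def infer_scale_bounds(
    dataset: QuestionnaireDataset,
    item_id: str,
    metadata: ItemMetadata | None = None,
) -> tuple[float, float]:
    """Scale bounds for an item: declared metadata if set, else observed range.

    Falling back to the observed range is logged because the diamond fill
    color and the scale midpoint depend on the bounds.
    """
    if metadata is not None and metadata.scale_min is not None and metadata.scale_max is not None:
        return float(metadata.scale_min), float(metadata.scale_max)
    x = dataset.numeric_column(item_id)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise DataError(f"cannot infer scale bounds for all-missing item {item_id!r}")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    logger.warning(
        "item %r: scale bounds not declared, using observed range [%g, %g]", item_id, lo, hi
    )
    return lo, hi


def score_scale(
    dataset: QuestionnaireDataset,
    item_ids: Sequence[str],
    min_valid: int | None = None,
) -> np.ndarray:
    """Score a multi-item scale as the per-respondent mean of its items.

    A respondent's score is the arithmetic mean of their non-missing listed
    items when at least ``min_valid`` of them are present, else missing.
    The default ``min_valid`` requires *all* items, which avoids silently
    mean-imputing partial responses.
    """
    dataset.require_columns(item_ids)
    if not item_ids:
        raise DataError("item_ids must be non-empty")
    k = len(item_ids)
    if min_valid is None:
        min_valid = k
    if not 1 <= min_valid <= k:
        raise DataError(f"min_valid must be in [1, {k}], got {min_valid}")
    values = np.column_stack([dataset.numeric_column(i) for i in item_ids])
    present = ~np.isnan(values)
    n_present = present.sum(axis=1)
    sums = np.where(present, values, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / n_present
    means[n_present < min_valid] = np.nan
    return means
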