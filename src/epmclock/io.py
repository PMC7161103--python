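"""Delimited-text input/output and Pearson site selection.

Matrices are stored as TSV/CSV tables with a header row of individual ids and
a first column of site ids (canonical sites x individuals orientation); age
tables are two-column (individual_id, age) files.  Floating-point output uses
17 significant digits so that a write/read cycle is bit-stable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AgeVector, MethylationMatrix, SiteSelection
from .exceptions import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "read_methylation_matrix",
    "write_methylation_matrix",
    "read_ages",
    "write_ages",
    "select_sites",
    "write_selection_metadata",
]

_FLOAT_FMT = "%.17g"


def _sep_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_methylation_matrix(
    path: str | Path,
    orientation: str = "sites_by_individuals",
    delimiter: str | None = None,
) -> MethylationMatrix:
    """Read a delimited methylation table into canonical orientation.

    Parameters
    ----------
    path
        TSV (default) or CSV file; header row of ids, first column of ids.
    orientation
        ``"sites_by_individuals"`` if rows are sites (canonical), or
        ``"individuals_by_sites"`` if the table is transposed on disk.
    delimiter
        Explicit field separator; by default inferred from the extension
        (``.csv`` -> comma, anything else -> tab).

    Raises
    ------
    DataError
        On a missing or non-numeric cell (the first offender is named),
        or on duplicate row/column ids.
    """
    if orientation not in ("sites_by_individuals", "individuals_by_sites"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell == "":
                raise DataError(
                    f"missing cell at (row {row_ids[i]!r}, column {col_ids[j]!r})"
                )
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise DataError(
                    f"non-numeric cell {cell!r} at "
                    f"(row {row_ids[i]!r}, column {col_ids[j]!r})"
                ) from None
    if orientation == "individuals_by_sites":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return MethylationMatrix(values=values, site_ids=row_ids, individual_ids=col_ids)


def write_methylation_matrix(
    matrix: MethylationMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a matrix in canonical orientation with full float precision."""
    sep = _sep_for(path, delimiter)
    df = pd.DataFrame(
        matrix.values, index=matrix.site_ids, columns=matrix.individual_ids
    )
    df.to_csv(path, sep=sep, float_format=_FLOAT_FMT, index_label="site_id")


def read_ages(path: str | Path, matrix: MethylationMatrix, delimiter: str | None = None) -> AgeVector:
    """Read a two-column (individual_id, age) table aligned to ``matrix``.

    Rows may appear in any order; the returned vector follows the matrix
    column order.  A header line is detected by a non-numeric second field.
    Individuals absent from the matrix are dropped with a warning; a matrix
    individual absent from the file is a hard error.
    """
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise DataError(f"age table must have exactly 2 columns, got {df.shape[1]}")
    rows = [(r[0].strip(), r[1].strip()) for r in df.to_numpy()]
    if rows and not _is_number(rows[0][1]):
        rows = rows[1:]  # header line
    mapping: dict[str, float] = {}
    for ind, raw_age in rows:
        if ind in mapping:
            raise DataError(f"duplicate individual id in age table: {ind!r}")
        if not _is_number(raw_age):
            raise DataError(f"non-numeric age {raw_age!r} for individual {ind!r}")
        mapping[ind] = float(raw_age)
    missing = [i for i in matrix.individual_ids if i not in mapping]
    if missing:
        raise DataError(f"age table lacks matrix individuals: {missing}")
    extra = sorted(set(mapping) - set(matrix.individual_ids))
    if extra:
        logger.warning("age table has %d individuals not in the matrix; dropped: %s",
                       len(extra), extra)
    ages = np.array([mapping[i] for i in matrix.individual_ids])
    return AgeVector(ages=ages, individual_ids=list(matrix.individual_ids))


def write_ages(ages: AgeVector, path: str | Path, delimiter: str | None = None) -> None:
    sep = _sep_for(path, delimiter)
    with open(path, "w") as fh:
        fh.write(f"individual_id{sep}age\n")
        for ind, t in zip(ages.individual_ids, ages.ages):
            fh.write(f"{ind}{sep}{_FLOAT_FMT % t}\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def select_sites(
    matrix: MethylationMatrix,
    ages: AgeVector,
    k: int,
    signed: bool = False,
) -> SiteSelection:
    """Keep the k sites whose levels correlate most strongly with age.

    By default ranks by |Pearson r| — negatively methylating sites are as
    informative as positively methylating ones, and the model permits
    negative rates.  With ``signed=True`` ranks by signed r descending.
    Zero-variance sites have undefined correlation and are always excluded;
    ties are broken by original site order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    t = ages.ages
    vals = matrix.values
    centered = vals - vals.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    row_ss = np.einsum("ij,ij->i", centered, centered)
    t_ss = float(tc @ tc)
    eligible = row_ss > 0
    if not np.any(eligible):
        raise DataError("all sites have zero variance; no correlation defined")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered @ tc) / np.sqrt(row_ss * t_ss)
    corr = np.clip(corr, -1.0, 1.0)
    idx = np.flatnonzero(eligible)
    key = corr[idx] if signed else np.abs(corr[idx])
    # stable sort on descending key preserves original site order at ties
    order = np.argsort(-key, kind="stable")
    keep = idx[order][:k]
    return SiteSelection(kept_site_indices=[int(i) for i in keep],
                         correlations=corr[keep])


def write_selection_metadata(
    selection: SiteSelection, matrix: MethylationMatrix, k: int, path: str | Path
) -> None:
    """JSON sidecar recording the requested k and per-kept-site correlation."""
    payload = {
        "k_requested": int(k),
        "k_kept": len(selection.kept_site_indices),
        "sites": [
            {"site_id": matrix.site_ids[i], "index": int(i), "pearson_r": float(r)}
            for i, r in zip(selection.kept_site_indices, selection.correlations)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
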