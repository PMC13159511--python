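"""Reading and writing the package's tab-separated text formats.

Site-table dialect: UTF-8, tab-delimited, header ``chrom pos category d_x
n_x d_y n_y``, one site per line, 1-based positions, rows sorted by
(chrom, pos) — unsorted input is sorted on load with a logged notice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sites import SITE_COLUMNS, SiteTable

__all__ = ["read_site_table", "write_site_table", "write_tsv", "write_json"]

logger = logging.getLogger("rxyjack")


class SiteTableFormatError(ValueError):
    """Malformed site-table file (message carries the 1-based line number)."""


def read_site_table(path: str | Path) -> SiteTable:
    """Parse and validate a site-table TSV.

    Raises :class:`SiteTableFormatError` naming the offending line for
    count violations (d > n, n <= 0, pos < 1) and duplicate (chrom, pos)
    pairs; missing columns fail immediately.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "category": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise SiteTableFormatError(f"{path}: cannot parse: {exc}") from exc
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise SiteTableFormatError(f"{path}: missing column(s): {', '.join(missing)}")
    for col in ("pos", "d_x", "n_x", "d_y", "n_y"):
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise SiteTableFormatError(
                f"{path}: column {col!r} is not integer: {exc}"
            ) from exc

    # line numbers: header is line 1, first data row is line 2
    def fail(mask: pd.Series, what: str) -> None:
        if mask.any():
            line = int(mask.idxmax()) + 2
            raise SiteTableFormatError(f"{path}: line {line}: {what}")

    fail(df["pos"] < 1, "position must be >= 1")
    fail((df["n_x"] <= 0) | (df["n_y"] <= 0), "zero haploid sample size")
    fail((df["d_x"] < 0) | (df["d_x"] > df["n_x"]), "d_x outside [0, n_x]")
    fail((df["d_y"] < 0) | (df["d_y"] > df["n_y"]), "d_y outside [0, n_y]")
    dup = df.duplicated(subset=["chrom", "pos"])
    fail(dup, "duplicate (chrom, pos)")

    sorted_ok = (
        df[["chrom", "pos"]]
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
        .equals(df[["chrom", "pos"]].reset_index(drop=True))
    )
    if not sorted_ok:
        logger.info("%s: rows not sorted by (chrom, pos); sorting on load", path)
    return SiteTable(df)


def write_site_table(table: SiteTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def write_tsv(rows: list[dict], path: str | Path, columns: list[str]) -> None:
    """Deterministic TSV export (fixed column order, %.10g floats, NA for
    missing) so identical runs give byte-identical files."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c)) for c in columns) + "\n")


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def write_json(payload, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
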