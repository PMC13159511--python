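"""Per-site allele-count tables for two populations.

The fundamental input is one row per genomic site: chromosome, 1-based
position, a mutation-impact category label (e.g. ``high``, ``moderate``,
``low``, ``intergenic``), and for each of two populations the allele count
``d`` and haploid sample size ``n``. Whether ``d`` counts derived or
non-reference alleles is the caller's choice; counts are taken at face value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["SiteRecord", "SiteTable", "SITE_COLUMNS"]

#: Canonical column order of the tabular representation.
SITE_COLUMNS = ("chrom", "pos", "category", "d_x", "n_x", "d_y", "n_y")


@dataclass(frozen=True)
class SiteRecord:
    """A single polymorphic site with allele counts for populations X and Y.

    Attributes
    ----------
    chrom : str
        Chromosome or scaffold label.
    pos : int
        1-based physical position.
    category : str
        Mutation-impact label.
    d_x, d_y : int
        Allele counts in X and Y (0 <= d <= n).
    n_x, n_y : int
        Haploid sample sizes (2x diploid individuals at autosomal sites).
    """

    chrom: str
    pos: int
    category: str
    d_x: int
    n_x: int
    d_y: int
    n_y: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for pop, d, n in (("x", self.d_x, self.n_x), ("y", self.d_y, self.n_y)):
            if n <= 0:
                raise ValueError(f"zero haploid sample size (n_{pop}={n})")
            if not 0 <= d <= n:
                raise ValueError(f"require 0 <= d_{pop} <= n_{pop}, got d={d}, n={n}")


class SiteTable:
    """An ordered collection of sites, sorted by (chrom, pos).

    Wraps a :class:`pandas.DataFrame` with columns ``chrom, pos, category,
    d_x, n_x, d_y, n_y``. Rows are sorted lexicographically by chromosome and
    numerically by position, and (chrom, pos) pairs must be unique.

    Parameters
    ----------
    df : pandas.DataFrame
        Site data; a defensive copy is made.
    validate : bool, default True
        Check invariants (d <= n, n > 0, pos >= 1, uniqueness).
    """

    def __init__(self, df: pd.DataFrame, *, validate: bool = True) -> None:
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(SITE_COLUMNS)].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["category"] = df["category"].astype(str)
        for col in ("pos", "d_x", "n_x", "d_y", "n_y"):
            df[col] = df[col].astype(np.int64)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if validate:
            self._validate(df)
        self._df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if (df["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        if (df[["n_x", "n_y"]] <= 0).any().any():
            raise ValueError("zero haploid sample size")
        if ((df["d_x"] < 0) | (df["d_x"] > df["n_x"])).any():
            raise ValueError("require 0 <= d_x <= n_x at every site")
        if ((df["d_y"] < 0) | (df["d_y"] > df["n_y"])).any():
            raise ValueError("require 0 <= d_y <= n_y at every site")
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise ValueError(f"duplicate site ({row['chrom']}, {row['pos']})")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[SiteRecord]) -> "SiteTable":
        rows = [
            (r.chrom, r.pos, r.category, r.d_x, r.n_x, r.d_y, r.n_y) for r in records
        ]
        if not rows:
            raise ValueError("no sites")
        return cls(pd.DataFrame(rows, columns=list(SITE_COLUMNS)))

    # -- accessors --------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        """The underlying (sorted, validated) DataFrame. Do not mutate."""
        return self._df

    @property
    def n_sites(self) -> int:
        return len(self._df)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sorted(self._df["category"].unique()))

    @property
    def chromosomes(self) -> tuple[str, ...]:
        """Chromosome labels in table (lexicographic) order."""
        return tuple(self._df["chrom"].unique())

    def __len__(self) -> int:
        return len(self._df)

    def records(self) -> list[SiteRecord]:
        return [
            SiteRecord(
                chrom=r.chrom, pos=int(r.pos), category=r.category,
                d_x=int(r.d_x), n_x=int(r.n_x), d_y=int(r.d_y), n_y=int(r.n_y),
            )
            for r in self._df.itertuples(index=False)
        ]

    # -- subsetting (already-sorted data stays sorted) --------------------

    def restrict_category(self, category: str) -> "SiteTable":
        """Sites of one mutation-impact category, preserving order."""
        mask = self._df["category"].to_numpy() == category
        if not mask.any():
            raise ValueError(f"category not found: {category!r}")
        return self._from_sorted(self._df.loc[mask])

    def select(self, indices: Sequence[int] | np.ndarray) -> "SiteTable":
        """Subset by positional indices into the sorted table.

        Indices need not be sorted or unique (a bootstrap resample repeats
        blocks); the result is re-sorted, with duplicate (chrom, pos) pairs
        permitted, since a resample legitimately repeats sites.
        """
        sub = self._df.iloc[np.asarray(indices, dtype=np.intp)]
        sub = sub.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        return self._from_sorted(sub)

    def drop(self, indices: Sequence[int] | np.ndarray) -> "SiteTable":
        """Table with the given positional indices removed (leave-block-out)."""
        mask = np.ones(len(self._df), dtype=bool)
        mask[np.asarray(indices, dtype=np.intp)] = False
        return self._from_sorted(self._df.loc[mask])

    @classmethod
    def _from_sorted(cls, df: pd.DataFrame) -> "SiteTable":
        obj = cls.__new__(cls)
        obj._df = df.reset_index(drop=True)
        return obj

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SiteTable({self.n_sites} sites, "
            f"{len(self.chromosomes)} chromosomes, "
            f"categories={list(self.categories)})"
        )
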