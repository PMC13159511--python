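"""Partition a site table into contiguous blocks for block resampling.

Loci in close physical proximity share evolutionary history (linkage), so
resampling treats a contiguous block of loci as one observation. Blocks never
span chromosome boundaries and are defined by locus count, not physical
length: either ~equal-count blocks (largest-remainder apportionment across
chromosomes) or one block per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sites import SiteTable

__all__ = [
    "Block",
    "BlockPartition",
    "partition_equal_count",
    "partition_by_chromosome",
    "block_map_frame",
]


@dataclass(frozen=True)
class Block:
    """A contiguous run of sites on one chromosome.

    ``first_index``/``last_index`` are inclusive positional indices into the
    sorted table; ``m_j`` is the block's locus count.
    """

    block_id: int
    chrom: str
    first_index: int
    last_index: int

    @property
    def m_j(self) -> int:
        return self.last_index - self.first_index + 1

    def indices(self) -> np.ndarray:
        return np.arange(self.first_index, self.last_index + 1, dtype=np.intp)


@dataclass(frozen=True)
class BlockPartition:
    """Disjoint contiguous blocks covering every site exactly once."""

    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        expect = 0
        for j, b in enumerate(self.blocks):
            if b.block_id != j:
                raise ValueError("block ids must be 0..g-1 in order")
            if b.first_index != expect:
                raise ValueError("blocks must be contiguous and disjoint")
            if b.m_j < 1:
                raise ValueError("empty block")
            expect = b.last_index + 1

    @property
    def g(self) -> int:
        return len(self.blocks)

    @property
    def n(self) -> int:
        return self.blocks[-1].last_index + 1 if self.blocks else 0

    @property
    def sizes(self) -> np.ndarray:
        """Per-block locus counts m_j."""
        return np.array([b.m_j for b in self.blocks], dtype=np.int64)

    def block_slices(self) -> list[slice]:
        return [slice(b.first_index, b.last_index + 1) for b in self.blocks]


def _apportion(counts: dict[str, int], g: int) -> dict[str, int]:
    """Largest-remainder apportionment of g blocks across chromosomes,
    proportional to locus counts, each chromosome receiving >= 1 block and at
    most its locus count.

    Ties in remainders are broken toward the chromosome with more loci, then
    by chromosome sort order. Deterministic.
    """
    chroms = sorted(counts)
    n = sum(counts.values())
    quota = {c: g * counts[c] / n for c in chroms}
    alloc = {c: int(np.floor(quota[c])) for c in chroms}
    # lower/upper bounds
    for c in chroms:
        alloc[c] = min(max(alloc[c], 1), counts[c])
    # distribute (or reclaim) the difference by remainder order
    def remainder_order() -> list[str]:
        return sorted(
            chroms,
            key=lambda c: (-(quota[c] - np.floor(quota[c])), -counts[c], c),
        )

    diff = g - sum(alloc.values())
    order = remainder_order()
    k = 0
    while diff > 0:
        c = order[k % len(order)]
        if alloc[c] < counts[c]:
            alloc[c] += 1
            diff -= 1
        k += 1
        if k > 2 * g * len(order):  # pragma: no cover - guarded by g <= n
            raise RuntimeError("apportionment failed to converge")
    # reclaim from smallest remainders (reverse order), respecting the >= 1 bound
    k = 0
    rev = order[::-1]
    while diff < 0:
        c = rev[k % len(rev)]
        if alloc[c] > 1:
            alloc[c] -= 1
            diff += 1
        k += 1
        if k > 2 * g * len(rev):  # pragma: no cover
            raise RuntimeError("apportionment failed to converge")
    return alloc


def partition_equal_count(sites: SiteTable, g: int) -> BlockPartition:
    """g contiguous blocks of roughly equal locus count.

    Within each chromosome block sizes differ by at most one (earlier blocks
    take the extra locus); across chromosomes blocks are apportioned by the
    largest-remainder rule proportional to per-chromosome locus counts. No
    block spans a chromosome boundary, so g must be at least the number of
    chromosomes and at most the number of loci.
    """
    n = sites.n_sites
    if g < 2:
        raise ValueError("need at least g=2 blocks for resampling")
    if g > n:
        raise ValueError(f"cannot make g={g} blocks from {n} loci")
    chrom_col = sites.df["chrom"].to_numpy()
    chrom_labels = list(sites.chromosomes)
    counts = {c: int((chrom_col == c).sum()) for c in chrom_labels}
    if g < len(chrom_labels):
        raise ValueError(
            "cannot avoid spanning chromosomes: "
            f"g={g} < {len(chrom_labels)} chromosomes"
        )
    alloc = _apportion(counts, g)

    blocks: list[Block] = []
    offset = 0
    bid = 0
    for c in chrom_labels:  # table order == lexicographic
        nc, k = counts[c], alloc[c]
        base, extra = divmod(nc, k)
        start = offset
        for i in range(k):
            size = base + (1 if i < extra else 0)
            blocks.append(Block(bid, c, start, start + size - 1))
            bid += 1
            start += size
        offset += nc
    return BlockPartition(tuple(blocks))


def partition_by_chromosome(sites: SiteTable) -> BlockPartition:
    """One block per chromosome (the whole-chromosome jackknife dialect)."""
    chrom_col = sites.df["chrom"].to_numpy()
    labels = list(sites.chromosomes)
    if len(labels) < 2:
        raise ValueError("need >= 2 chromosomes to use chromosomes as blocks")
    blocks: list[Block] = []
    offset = 0
    for bid, c in enumerate(labels):
        nc = int((chrom_col == c).sum())
        blocks.append(Block(bid, c, offset, offset + nc - 1))
        offset += nc
    return BlockPartition(tuple(blocks))


def block_map_frame(sites: SiteTable, partition: BlockPartition) -> pd.DataFrame:
    """Tabular block map: block_id, chrom, start_pos, end_pos, n_loci
    (1-based inclusive site positions)."""
    pos = sites.df["pos"].to_numpy()
    rows = [
        (b.block_id, b.chrom, int(pos[b.first_index]), int(pos[b.last_index]), b.m_j)
        for b in partition.blocks
    ]
    return pd.DataFrame(
        rows, columns=["block_id", "chrom", "start_pos", "end_pos", "n_loci"]
    )
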