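"""Block jackknife and block bootstrap over site tables.

The delete-one (or delete-block) jackknife recomputes a statistic with each
block removed, giving g leave-one-out values theta_-j. For blocks of unequal
locus count m_j the weighted block jackknife combines them as

    theta_wbj = g * theta_hat - sum_j (n - m_j) * theta_-j / n
    SE_wbj    = sqrt( (1/g) * sum_j ((n - m_j) / m_j) * (theta_hat - theta_-j)^2 )

with theta_hat the full-data estimate and n the total locus count. The block
bootstrap instead redraws g blocks with replacement per replicate and uses
the locus-count-weighted mean and standard deviation of the replicate
statistics.

The raw standard deviation of jackknife leave-one-out values is *not* a
standard error — it underestimates it by a factor of about sqrt(g)/(g-1) —
but is retained here (:func:`naive_pseudovalue_sd`, always flagged) so the
bias can be demonstrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .blocks import BlockPartition
from .rxy import RxyUndefinedError, site_contributions
from .sites import SiteTable

__all__ = [
    "JackknifeReplicates",
    "BootstrapReplicates",
    "ResampleSummary",
    "KNOWN_BIASED_FLAG",
    "delete_one_pseudovalues",
    "jackknife_se_simple",
    "block_jackknife",
    "weighted_jackknife_estimate",
    "weighted_jackknife_se",
    "jackknife_summary",
    "block_bootstrap",
    "bootstrap_block_indices",
    "bootstrap_summary",
    "naive_pseudovalue_sd",
    "bootstrap_cv_trace",
    "rxy_block_jackknife",
    "rxy_block_bootstrap",
]

Statistic = Callable[[SiteTable], float]

#: Machine-readable flag carried by results of the biased pseudo-value method.
KNOWN_BIASED_FLAG = "known-biased method: pseudo-value SD underestimates SE"


@dataclass(frozen=True)
class JackknifeReplicates:
    """Full-data estimate plus leave-one-block-out estimates.

    ``replicates`` holds one ``(block_id, m_j, theta_minus_j)`` triple per
    block, in block order.
    """

    theta_full: float
    replicates: tuple[tuple[int, int, float], ...]
    statistic_label: str = "statistic"

    def __post_init__(self) -> None:
        if len(self.replicates) < 2:
            raise ValueError("jackknife needs g >= 2 blocks")

    @property
    def g(self) -> int:
        return len(self.replicates)

    @property
    def n(self) -> int:
        return int(sum(m for _, m, _ in self.replicates))

    @property
    def sizes(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.replicates], dtype=np.int64)

    @property
    def values(self) -> np.ndarray:
        """Leave-one-out estimates theta_-j in block order."""
        return np.array([t for _, _, t in self.replicates], dtype=np.float64)


@dataclass(frozen=True)
class BootstrapReplicates:
    """B block-bootstrap replicate estimates with locus-count weights.

    ``replicates`` holds ``(theta_b, w_b)`` pairs for the successful
    replicates; ``n_failed`` counts resamples on which the statistic was
    undefined (e.g. an R_XY denominator of zero) and was dropped.
    """

    replicates: tuple[tuple[float, int], ...]
    B: int
    seed: int
    statistic_label: str = "statistic"
    n_failed: int = 0

    @property
    def values(self) -> np.ndarray:
        return np.array([t for t, _ in self.replicates], dtype=np.float64)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.replicates], dtype=np.float64)


@dataclass(frozen=True)
class ResampleSummary:
    """Point estimate and standard error from one resampling method."""

    estimate: float
    se: float
    method: str  # weighted_block_jackknife | block_bootstrap | naive_pseudovalue_sd | simple_jackknife
    g_or_B: int
    statistic_label: str = "statistic"
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


# ---------------------------------------------------------------------------
# simple (delete-one) jackknife


def delete_one_pseudovalues(
    values: Sequence[float], statistic: Callable[[np.ndarray], float]
) -> np.ndarray:
    """Recompute ``statistic`` with each observation removed in turn."""
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    keep = ~np.eye(n, dtype=bool)
    return np.array([statistic(x[keep[j]]) for j in range(n)], dtype=np.float64)


def jackknife_se_simple(pseudovalues: Sequence[float]) -> float:
    """Jackknife standard error from delete-one values:
    sqrt(((n-1)/n) * sum_j (x_-j - xbar)^2).

    For the sample mean this equals the classical s/sqrt(n) exactly.
    """
    x = np.asarray(pseudovalues, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pseudo-values")
    return float(math.sqrt((n - 1) / n * np.sum((x - x.mean()) ** 2)))


# ---------------------------------------------------------------------------
# block jackknife


def block_jackknife(
    sites: SiteTable, partition: BlockPartition, statistic: Statistic
) -> JackknifeReplicates:
    """Leave-one-block-out replicates of an arbitrary site-table statistic.

    The statistic must be defined on every leave-one-out subset: the jackknife
    equations need exactly g replicates, so an undefined replicate aborts
    (naming the offending block) rather than being dropped.
    """
    if partition.n != sites.n_sites:
        raise ValueError("partition does not cover the site table")
    if partition.g < 2:
        raise ValueError("jackknife needs g >= 2 blocks")
    theta_full = float(statistic(sites))
    reps = []
    for b in partition.blocks:
        sub = sites.drop(b.indices())
        try:
            theta_j = float(statistic(sub))
        except (RxyUndefinedError, ValueError, ZeroDivisionError) as exc:
            raise RxyUndefinedError(
                f"statistic undefined when leaving out block {b.block_id} "
                f"({b.chrom}): {exc}"
            ) from exc
        reps.append((b.block_id, b.m_j, theta_j))
    return JackknifeReplicates(
        theta_full=theta_full,
        replicates=tuple(reps),
        statistic_label=getattr(statistic, "label", "statistic"),
    )


def weighted_jackknife_estimate(reps: JackknifeReplicates) -> float:
    """Bias-corrected weighted block jackknife mean
    g*theta_hat - sum_j (n - m_j)*theta_-j / n."""
    m = reps.sizes.astype(np.float64)
    n = m.sum()
    return float(reps.g * reps.theta_full - np.sum((n - m) * reps.values) / n)


def weighted_jackknife_se(reps: JackknifeReplicates) -> float:
    """Weighted block jackknife standard error
    sqrt((1/g) * sum_j ((n - m_j)/m_j) * (theta_hat - theta_-j)^2)."""
    m = reps.sizes.astype(np.float64)
    n = m.sum()
    dev = reps.theta_full - reps.values
    return float(math.sqrt(np.sum((n - m) / m * dev**2) / reps.g))


def jackknife_summary(reps: JackknifeReplicates) -> ResampleSummary:
    """Weighted block jackknife estimate and SE as a ResampleSummary."""
    return ResampleSummary(
        estimate=weighted_jackknife_estimate(reps),
        se=weighted_jackknife_se(reps),
        method="weighted_block_jackknife",
        g_or_B=reps.g,
        statistic_label=reps.statistic_label,
    )


def naive_pseudovalue_sd(reps: JackknifeReplicates) -> ResampleSummary:
    """Mean and raw sample SD of the leave-one-out values.

    This is the widespread *misuse* of the jackknife: treating leave-one-out
    values like bootstrap replicates. The SD underestimates the standard
    error by roughly sqrt(g)/(g-1) and the result is flagged accordingly;
    reporting layers must warn when they emit it.
    """
    vals = reps.values
    return ResampleSummary(
        estimate=float(vals.mean()),
        se=float(vals.std(ddof=1)),
        method="naive_pseudovalue_sd",
        g_or_B=reps.g,
        statistic_label=reps.statistic_label,
        flags=frozenset({KNOWN_BIASED_FLAG}),
    )


# ---------------------------------------------------------------------------
# block bootstrap


def bootstrap_block_indices(seed: int, b: int, g: int) -> np.ndarray:
    """Block indices drawn by bootstrap replicate ``b``.

    Each replicate's draw derives from ``(seed, b)`` so results do not depend
    on execution order and any single replicate can be reproduced alone.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
    return rng.integers(0, g, size=g)


def block_bootstrap(
    sites: SiteTable,
    partition: BlockPartition,
    statistic: Statistic,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapReplicates:
    """B block-bootstrap replicates: each draws g blocks uniformly with
    replacement and recomputes the statistic on the concatenated loci.

    Replicates on which the statistic is undefined are dropped and counted in
    ``n_failed`` (the bootstrap is a Monte-Carlo average, so losing a few
    replicates is benign, unlike the jackknife).
    """
    if partition.n != sites.n_sites:
        raise ValueError("partition does not cover the site table")
    if partition.g < 2:
        raise ValueError("block bootstrap needs g >= 2 blocks")
    if B < 1:
        raise ValueError("B must be >= 1")
    slices = partition.block_slices()
    sizes = partition.sizes
    reps: list[tuple[float, int]] = []
    n_failed = 0
    for b in range(B):
        idx_blocks = bootstrap_block_indices(seed, b, partition.g)
        site_idx = np.concatenate(
            [np.arange(slices[i].start, slices[i].stop, dtype=np.intp) for i in idx_blocks]
        )
        w_b = int(sizes[idx_blocks].sum())
        try:
            theta_b = float(statistic(sites.select(site_idx)))
        except (RxyUndefinedError, ValueError, ZeroDivisionError):
            n_failed += 1
            continue
        reps.append((theta_b, w_b))
    return BootstrapReplicates(
        replicates=tuple(reps),
        B=B,
        seed=seed,
        statistic_label=getattr(statistic, "label", "statistic"),
        n_failed=n_failed,
    )


def _weighted_mean_sd(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    wsum = weights.sum()
    mean = float(np.sum(weights * values) / wsum)
    sd = float(math.sqrt(np.sum(weights * (values - mean) ** 2) / wsum))
    return mean, sd


def bootstrap_summary(reps: BootstrapReplicates) -> ResampleSummary:
    """Locus-count-weighted mean and SD of bootstrap replicate statistics.

    The weighted SD of replicate values *is* the bootstrap standard error
    (weights w_b compensate for uneven total loci across resamples).
    """
    if len(reps.replicates) < 2:
        raise ValueError("need >= 2 successful bootstrap replicates")
    est, sd = _weighted_mean_sd(reps.values, reps.weights)
    return ResampleSummary(
        estimate=est,
        se=sd,
        method="block_bootstrap",
        g_or_B=reps.B,
        statistic_label=reps.statistic_label,
    )


def bootstrap_cv_trace(
    reps: BootstrapReplicates, window: int = 10
) -> list[tuple[int, float]]:
    """Stability diagnostic: running coefficient of variation of the SE
    estimate as replicates accumulate.

    For each prefix length b >= 10 the weighted SD of the first b replicates
    is the running SE estimate; the CV at b is the SD of the last ``window``
    running estimates divided by their mean (0 where that mean is 0). The
    trace flattening toward 0 indicates B is large enough.
    """
    vals, wts = reps.values, reps.weights
    B = vals.size
    if B < 10:
        raise ValueError("need at least 10 replicates for a CV trace")
    running = np.empty(B - 9)
    for b in range(10, B + 1):
        _, sd = _weighted_mean_sd(vals[:b], wts[:b])
        running[b - 10] = sd
    trace: list[tuple[int, float]] = []
    for i in range(running.size):
        lo = max(0, i - window + 1)
        win = running[lo : i + 1]
        mean = win.mean()
        cv = 0.0 if mean == 0 else float(win.std(ddof=0) / mean)
        trace.append((i + 10, cv))
    return trace


# ---------------------------------------------------------------------------
# fast exact paths for R_XY (via additivity of the L sums)


def _category_block_sums(
    sites: SiteTable, partition: BlockPartition, category: str | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block partial L sums (numerator and denominator direction) over
    sites of ``category`` (or all sites when None)."""
    a, b = site_contributions(sites)
    if category is not None:
        mask = sites.df["category"].to_numpy() == category
        if not mask.any():
            raise ValueError(f"category not found: {category!r}")
        a, b = np.where(mask, a, 0.0), np.where(mask, b, 0.0)
    bounds = np.array([blk.first_index for blk in partition.blocks] + [partition.n])
    csum_a = np.concatenate([[0.0], np.cumsum(a)])
    csum_b = np.concatenate([[0.0], np.cumsum(b)])
    return np.diff(csum_a[bounds]), np.diff(csum_b[bounds])


def _ratio_or_error(num: float, den: float, context: str) -> float:
    if den == 0.0:
        raise RxyUndefinedError(f"R_XY undefined: denominator L is zero ({context})")
    return num / den


def _rxy_from_block_sums(
    sums: list[tuple[np.ndarray, np.ndarray]], keep: np.ndarray | None, context: str
) -> float:
    """Evaluate (standardised) R_XY from per-block L sums, using either all
    blocks (keep=None) or the multiset of block indices in ``keep``."""
    def total(arr: np.ndarray) -> float:
        return float(arr.sum() if keep is None else arr[keep].sum())

    value = _ratio_or_error(total(sums[0][0]), total(sums[0][1]), context)
    if len(sums) == 2:  # standardised: divide by the neutral-category ratio
        neut = _ratio_or_error(total(sums[1][0]), total(sums[1][1]), context)
        value = _ratio_or_error(value, neut, context + ", neutral R_XY zero")
    return value


def _rxy_sums(
    sites: SiteTable,
    partition: BlockPartition,
    focal_category: str | None,
    neutral_category: str | None,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], str]:
    if partition.n != sites.n_sites:
        raise ValueError("partition does not cover the site table")
    sums = [_category_block_sums(sites, partition, focal_category)]
    label = "Rxy" if focal_category is None else f"Rxy[{focal_category}]"
    if neutral_category is not None:
        if focal_category is None:
            raise ValueError("neutral_category requires focal_category")
        sums.append(_category_block_sums(sites, partition, neutral_category))
        label += f"/Rxy[{neutral_category}]"
    return sums, label


def rxy_block_jackknife(
    sites: SiteTable,
    partition: BlockPartition,
    focal_category: str | None = None,
    neutral_category: str | None = None,
) -> JackknifeReplicates:
    """Leave-one-block-out R_XY replicates computed from per-block partial L
    sums.

    Exactly equivalent to :func:`block_jackknife` with an R_XY statistic
    (L is additive over any partition of sites) but O(n + g) instead of
    O(n * g); the generic route re-subsets the table g times.
    """
    sums, label = _rxy_sums(sites, partition, focal_category, neutral_category)
    theta_full = _rxy_from_block_sums(sums, None, "full data")
    g = partition.g
    all_idx = np.arange(g)
    reps = []
    for b in partition.blocks:
        keep = all_idx[all_idx != b.block_id]
        theta_j = _rxy_from_block_sums(
            sums, keep, f"leaving out block {b.block_id} ({b.chrom})"
        )
        reps.append((b.block_id, b.m_j, theta_j))
    return JackknifeReplicates(theta_full, tuple(reps), statistic_label=label)


def rxy_block_bootstrap(
    sites: SiteTable,
    partition: BlockPartition,
    focal_category: str | None = None,
    neutral_category: str | None = None,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapReplicates:
    """Block bootstrap of R_XY from per-block partial L sums.

    Draws the same block indices as :func:`block_bootstrap` for a given seed
    and yields the same replicate values (up to float summation order).
    """
    sums, label = _rxy_sums(sites, partition, focal_category, neutral_category)
    sizes = partition.sizes
    reps: list[tuple[float, int]] = []
    n_failed = 0
    for b in range(B):
        idx = bootstrap_block_indices(seed, b, partition.g)
        try:
            theta_b = _rxy_from_block_sums(sums, idx, f"bootstrap replicate {b}")
        except RxyUndefinedError:
            n_failed += 1
            continue
        reps.append((theta_b, int(sizes[idx].sum())))
    return BootstrapReplicates(
        replicates=tuple(reps), B=B, seed=seed, statistic_label=label,
        n_failed=n_failed,
    )
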