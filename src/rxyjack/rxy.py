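"""The R_XY relative-mutation-load statistic.

For a focal population X and reference population Y, the expected probability
of drawing an allele from one random haploid genome of X but not from one of
Y, summed over sites, is

    L_X,notY = sum_i (d_Xi / n_Xi) * (1 - d_Yi / n_Yi)

where d is the allele count and n the haploid sample size at site i. The
ratio

    R_XY = L_X,notY / L_Y,notX

equals 1 when per-site allele frequencies are identical in the two
populations; values below 1 indicate a depletion of the scored alleles in X
relative to Y (e.g. purging of deleterious variants), values above 1 an
enrichment. Comparisons across mutation-impact categories are made on the
standardised form: category R_XY divided by the R_XY of a putatively neutral
category (typically intergenic sites).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .sites import SiteTable

__all__ = [
    "LPair",
    "RxyEstimate",
    "RxyUndefinedError",
    "l_statistic",
    "l_pair",
    "rxy",
    "standardized_rxy",
    "site_contributions",
    "rxy_statistic",
]

Direction = Literal["x_not_y", "y_not_x"]


class RxyUndefinedError(ZeroDivisionError):
    """Raised when an R_XY denominator L sum is zero (no private-allele
    probability mass in the reference direction)."""


@dataclass(frozen=True)
class LPair:
    """Both directed L sums over the same set of sites.

    Each site contributes a product of two probabilities, hence each L lies
    in [0, n_sites].
    """

    l_x_not_y: float
    l_y_not_x: float
    n_sites: int


@dataclass(frozen=True)
class RxyEstimate:
    """An R_XY point estimate with provenance.

    ``standardized`` is True when ``value`` is a category R_XY divided by the
    neutral-category R_XY (in which case ``l_pair`` refers to the focal
    category's sums and ``neutral_category`` is set).
    """

    value: float
    l_pair: LPair
    category: str = "all"
    standardized: bool = False
    neutral_category: str | None = None


def site_contributions(sites: SiteTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-site terms of the two L sums.

    Returns arrays ``(a, b)`` where ``a[i] = (d_x/n_x)(1 - d_y/n_y)`` and
    ``b[i] = (d_y/n_y)(1 - d_x/n_x)``, in table order. L sums are their
    totals; because L is additive over any partition of sites, block-resampled
    L sums are partial sums of these arrays.
    """
    df = sites.df
    px = df["d_x"].to_numpy(dtype=np.float64) / df["n_x"].to_numpy(dtype=np.float64)
    py = df["d_y"].to_numpy(dtype=np.float64) / df["n_y"].to_numpy(dtype=np.float64)
    return px * (1.0 - py), py * (1.0 - px)


def l_statistic(sites: SiteTable, direction: Direction) -> float:
    """Directed private-allele probability mass, summed over sites.

    Parameters
    ----------
    sites : SiteTable
    direction : {"x_not_y", "y_not_x"}
        Which population is focal (the one contributing ``d/n``) and which is
        the reference (contributing ``1 - d/n``).
    """
    if sites.n_sites == 0:
        raise ValueError("no sites")
    if direction not in ("x_not_y", "y_not_x"):
        raise ValueError(f"unknown direction {direction!r}")
    a, b = site_contributions(sites)
    return float(a.sum() if direction == "x_not_y" else b.sum())


def l_pair(sites: SiteTable) -> LPair:
    """Both L sums in one pass."""
    if sites.n_sites == 0:
        raise ValueError("no sites")
    a, b = site_contributions(sites)
    return LPair(float(a.sum()), float(b.sum()), sites.n_sites)


def rxy(sites: SiteTable, category: str = "all") -> RxyEstimate:
    """Unstandardised R_XY = L_X,notY / L_Y,notX over all sites in the table.

    Raises
    ------
    RxyUndefinedError
        If the denominator L_Y,notX is zero.
    """
    lp = l_pair(sites)
    if lp.l_y_not_x == 0.0:
        raise RxyUndefinedError("R_XY undefined: denominator L is zero")
    return RxyEstimate(value=lp.l_x_not_y / lp.l_y_not_x, l_pair=lp, category=category)


def standardized_rxy(
    sites: SiteTable, focal_category: str, neutral_category: str
) -> RxyEstimate:
    """Focal-category R_XY divided by neutral-category R_XY.

    The neutral category (typically intergenic variants) calibrates the
    statistic so that a focal class under the same average selective effect as
    the neutral class yields exactly 1.
    """
    focal = rxy(sites.restrict_category(focal_category), category=focal_category)
    neutral = rxy(sites.restrict_category(neutral_category), category=neutral_category)
    if neutral.value == 0.0:
        raise RxyUndefinedError("standardisation undefined: neutral R_XY is zero")
    return RxyEstimate(
        value=focal.value / neutral.value,
        l_pair=focal.l_pair,
        category=focal_category,
        standardized=True,
        neutral_category=neutral_category,
    )


def rxy_statistic(focal_category: str | None = None, neutral_category: str | None = None):
    """Build a labelled ``SiteTable -> float`` statistic for resampling.

    With no arguments, plain R_XY over all sites. With only ``focal_category``,
    R_XY restricted to that category. With both, the standardised form; the
    neutral L sums are recomputed on every (re)sampled table passed in.
    """
    if focal_category is None and neutral_category is not None:
        raise ValueError("neutral_category requires focal_category")

    if neutral_category is not None:
        def stat(sites: SiteTable) -> float:
            return standardized_rxy(sites, focal_category, neutral_category).value
        stat.label = f"Rxy[{focal_category}]/Rxy[{neutral_category}]"
    elif focal_category is not None:
        def stat(sites: SiteTable) -> float:
            return rxy(sites.restrict_category(focal_category), focal_category).value
        stat.label = f"Rxy[{focal_category}]"
    else:
        def stat(sites: SiteTable) -> float:
            return rxy(sites).value
        stat.label = "Rxy"
    return stat
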