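"""Hypothesis tests on resampled estimates.

The statistically sound route is a single-sample t-test on (estimate, SE)
from the weighted block jackknife or the block bootstrap. Treating jackknife
leave-one-out values as if they were independent samples (the paired t-test
on pseudo-values) inflates significance dramatically; it is provided for
demonstration only and its results always carry an anticonservative flag.

Z-scores from jackknife SEs come with a caveat inherited from the
introgression literature: the normal approximation is unreliable for |Z| > 2,
so beyond that threshold a Z-score is reported without a p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .resampling import JackknifeReplicates, ResampleSummary

__all__ = [
    "TestResult",
    "ANTICONSERVATIVE_FLAG",
    "Z_UNRELIABLE_FLAG",
    "one_sample_t",
    "paired_t_on_pseudovalues",
    "z_score",
]

ANTICONSERVATIVE_FLAG = "pseudovalues-as-samples: anticonservative"
Z_UNRELIABLE_FLAG = "Z>2: normal approximation unreliable"


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided test against a point null."""

    statistic_value: float
    df: int | None
    p_two_sided: float | None
    null_value: float
    method: str  # one_sample_t | paired_t_naive | z_score
    warning_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.p_two_sided is not None and not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def one_sample_t(
    summary: ResampleSummary, null_value: float = 1.0, df: int | None = None
) -> TestResult:
    """Two-sided single-sample t-test of (estimate, SE) against a null value.

    ``df`` defaults to g - 1 (jackknife) or B - 1 (bootstrap), the
    resampling-unit convention.
    """
    if summary.se <= 0:
        raise ValueError("degenerate SE")
    if df is None:
        df = summary.g_or_B - 1
    if df < 1:
        raise ValueError("df must be >= 1")
    t = (summary.estimate - null_value) / summary.se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(
        statistic_value=float(t),
        df=int(df),
        p_two_sided=min(p, 1.0),
        null_value=null_value,
        method="one_sample_t",
        warning_flags=summary.flags,
    )


def paired_t_on_pseudovalues(
    reps_a: JackknifeReplicates, reps_b: JackknifeReplicates
) -> TestResult:
    """Classic paired t-test on per-block leave-one-out values (demonstration
    of a misuse; always flagged anticonservative).

    Both replicate sets must come from the same block partition, so the j-th
    values are paired by jackknife replicate.
    """
    if reps_a.g != reps_b.g or not np.array_equal(reps_a.sizes, reps_b.sizes):
        raise ValueError("replicate sets use different block partitions")
    ids_a = [i for i, _, _ in reps_a.replicates]
    ids_b = [i for i, _, _ in reps_b.replicates]
    if ids_a != ids_b:
        raise ValueError("replicate sets use different block partitions")
    d = reps_a.values - reps_b.values
    g = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate paired test: zero-variance differences")
    t = float(d.mean() / (sd / math.sqrt(g)))
    p = 2.0 * float(stats.t.sf(abs(t), g - 1))
    return TestResult(
        statistic_value=t,
        df=g - 1,
        p_two_sided=min(p, 1.0),
        null_value=0.0,
        method="paired_t_naive",
        warning_flags=frozenset({ANTICONSERVATIVE_FLAG}),
    )


def z_score(summary: ResampleSummary, null_value: float = 1.0) -> TestResult:
    """Z-score of (estimate, SE) against a null value.

    For |Z| <= 2 a two-sided normal p-value is returned; beyond that the
    p-value is withheld (None) and a warning flag set, since the normality of
    jackknife Z-scores degrades in the tails.
    """
    if summary.se <= 0:
        raise ValueError("degenerate SE")
    z = float((summary.estimate - null_value) / summary.se)
    flags = set(summary.flags)
    if abs(z) > 2.0:
        p: float | None = None
        flags.add(Z_UNRELIABLE_FLAG)
    else:
        p = min(2.0 * float(stats.norm.sf(abs(z))), 1.0)
    return TestResult(
        statistic_value=z,
        df=None,
        p_two_sided=p,
        null_value=null_value,
        method="z_score",
        warning_flags=frozenset(flags),
    )
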