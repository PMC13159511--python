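"""The L statistic and the R_XY ratio: examples, errors, and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxyjack.rxy import (
    RxyUndefinedError,
    l_pair,
    l_statistic,
    rxy,
    rxy_statistic,
    standardized_rxy,
)
from rxyjack.sites import SiteRecord, SiteTable

from conftest import make_table


def brute_force_l(records, direction):
    """Independent site-by-site loop, no vectorisation."""
    total = 0.0
    for r in records:
        if direction == "x_not_y":
            total += (r.d_x / r.n_x) * (1 - r.d_y / r.n_y)
        else:
            total += (r.d_y / r.n_y) * (1 - r.d_x / r.n_x)
    return total


@pytest.mark.parametrize(
    "rows, direction, expected",
    [
        # a zero allele count contributes zero
        ([("1", 1, "all", 0, 2, 1, 2)], "x_not_y", 0.0),
        # (1/2)(1 - 1/2)
        ([("1", 1, "all", 1, 2, 1, 2)], "x_not_y", 0.25),
        # hand-summed two-site values, both directions
        ([("1", 1, "all", 1, 2, 1, 2), ("1", 2, "all", 2, 2, 0, 2)], "x_not_y", 1.25),
        ([("1", 1, "all", 1, 2, 1, 2), ("1", 2, "all", 2, 2, 0, 2)], "y_not_x", 0.25),
    ],
)
def test_l_statistic_hand_values(rows, direction, expected):
    assert l_statistic(make_table(rows), direction) == pytest.approx(expected, abs=1e-15)


def test_l_statistic_rejects_empty_and_bad_direction(two_site_table):
    with pytest.raises(ValueError, match="direction"):
        l_statistic(two_site_table, "sideways")
    with pytest.raises(ValueError):
        SiteTable(pd.DataFrame(columns=["chrom", "pos"]))


def test_zero_sample_size_rejected_at_construction():
    with pytest.raises(ValueError, match="zero haploid sample size"):
        make_table([("1", 1, "all", 0, 0, 1, 2)])
    with pytest.raises(ValueError, match="zero haploid sample size"):
        SiteRecord("1", 1, "all", 0, 0, 1, 2)


def test_rxy_two_site_ratio(two_site_table):
    est = rxy(two_site_table)
    assert est.value == pytest.approx(5.0, abs=1e-15)
    assert est.l_pair.l_x_not_y == pytest.approx(1.25)
    assert est.l_pair.n_sites == 2
    assert not est.standardized


def test_rxy_is_one_for_identical_frequencies():
    # same per-site frequencies, different sample sizes
    t = make_table([
        ("1", 1, "all", 1, 2, 2, 4),
        ("1", 2, "all", 3, 4, 3, 4),
        ("2", 1, "all", 0, 5, 0, 10),
    ])
    assert rxy(t).value == 1.0


def test_rxy_zero_denominator_is_an_error():
    t = make_table([("1", 1, "all", 2, 2, 0, 2), ("1", 2, "all", 2, 2, 0, 2)])
    with pytest.raises(RxyUndefinedError, match="denominator"):
        rxy(t)


def test_standardized_rxy_ratio_of_hand_computed_ratios():
    # focal category: p_x/(1-p_x) = 0.8 with p_y = 1/2 -> R = 0.8
    # neutral category: p_x/(1-p_x) = 1.1 -> R = 1.1
    t = make_table([
        ("1", 1, "focal", 4, 9, 1, 2),
        ("1", 2, "neutral", 11, 21, 1, 2),
    ])
    est = standardized_rxy(t, "focal", "neutral")
    assert est.value == pytest.approx(0.8 / 1.1, abs=1e-12)
    assert est.standardized and est.neutral_category == "neutral"


def test_standardized_rxy_identical_patterns_cancel():
    t = make_table([
        ("1", 1, "focal", 1, 4, 2, 5),
        ("1", 2, "neutral", 1, 4, 2, 5),
    ])
    assert standardized_rxy(t, "focal", "neutral").value == pytest.approx(1.0, abs=1e-15)


def test_standardized_rxy_missing_category(two_site_table):
    with pytest.raises(ValueError, match="category not found"):
        standardized_rxy(two_site_table, "absent", "all")


site_strategy = st.tuples(
    st.integers(min_value=1, max_value=12),   # n_x
    st.integers(min_value=1, max_value=12),   # n_y
    st.integers(min_value=0, max_value=12),   # d_x (clamped below)
    st.integers(min_value=0, max_value=12),   # d_y
    st.sampled_from(["chr1", "chr2"]),
)


def tables_from_sites(sites):
    rows = []
    pos = {"chr1": 0, "chr2": 0}
    for n_x, n_y, d_x, d_y, chrom in sites:
        pos[chrom] += 1
        rows.append((chrom, pos[chrom], "all", min(d_x, n_x), n_x, min(d_y, n_y), n_y))
    return make_table(rows)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(site_strategy, min_size=1, max_size=50))
def test_l_matches_brute_force_loop(sites):
    t = tables_from_sites(sites)
    for direction in ("x_not_y", "y_not_x"):
        assert l_statistic(t, direction) == pytest.approx(
            brute_force_l(t.records(), direction), abs=1e-12
        )


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(site_strategy, min_size=1, max_size=50))
def test_population_swap_exchanges_l_sums_exactly(sites):
    t = tables_from_sites(sites)
    df = t.df.rename(columns={"d_x": "d_y", "d_y": "d_x", "n_x": "n_y", "n_y": "n_x"})
    swapped = SiteTable(df)
    lp, lp_swap = l_pair(t), l_pair(swapped)
    assert lp_swap.l_x_not_y == lp.l_y_not_x
    assert lp_swap.l_y_not_x == lp.l_x_not_y
    # hence R_XY maps to its reciprocal
    if lp.l_x_not_y > 0 and lp.l_y_not_x > 0:
        assert rxy(swapped).value == pytest.approx(1.0 / rxy(t).value, rel=1e-12)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(site_strategy, min_size=1, max_size=50),
       st.integers(min_value=2, max_value=5))
def test_count_scale_invariance(sites, k):
    t = tables_from_sites(sites)
    df = t.df.copy()
    for col in ("d_x", "n_x", "d_y", "n_y"):
        df[col] = df[col] * k
    scaled = SiteTable(df)
    for direction in ("x_not_y", "y_not_x"):
        assert l_statistic(scaled, direction) == pytest.approx(
            l_statistic(t, direction), rel=1e-12
        )


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(site_strategy, min_size=2, max_size=50), st.randoms(use_true_random=False))
def test_l_is_additive_over_partitions(sites, rnd):
    t = tables_from_sites(sites)
    cut = rnd.randrange(1, t.n_sites) if t.n_sites > 1 else 1
    left = t.select(np.arange(cut))
    right = t.select(np.arange(cut, t.n_sites))
    for direction in ("x_not_y", "y_not_x"):
        assert l_statistic(t, direction) == pytest.approx(
            l_statistic(left, direction) + l_statistic(right, direction), abs=1e-12
        )


def test_rxy_statistic_factory_labels(two_site_table):
    stat = rxy_statistic()
    assert stat(two_site_table) == pytest.approx(5.0)
    assert stat.label == "Rxy"
    with pytest.raises(ValueError):
        rxy_statistic(None, "neutral")
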