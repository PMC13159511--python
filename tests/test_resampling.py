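"""Jackknife and bootstrap machinery: equations, equivalences, determinism."""

import math

import numpy as np
import pytest

from rxyjack.blocks import partition_equal_count
from rxyjack.resampling import (
    KNOWN_BIASED_FLAG,
    BootstrapReplicates,
    JackknifeReplicates,
    block_bootstrap,
    block_jackknife,
    bootstrap_block_indices,
    bootstrap_cv_trace,
    bootstrap_summary,
    delete_one_pseudovalues,
    jackknife_se_simple,
    jackknife_summary,
    naive_pseudovalue_sd,
    rxy_block_bootstrap,
    rxy_block_jackknife,
    weighted_jackknife_estimate,
    weighted_jackknife_se,
)
from rxyjack.rxy import RxyUndefinedError, rxy_statistic

from conftest import column_mean_statistic, make_table, random_table


def two_block_reps(theta=1.0, minus=(0.9, 1.1)):
    return JackknifeReplicates(
        theta_full=theta,
        replicates=((0, 1, minus[0]), (1, 1, minus[1])),
    )


# -- delete-one jackknife ---------------------------------------------------

def test_delete_one_pseudovalues_for_the_mean():
    out = delete_one_pseudovalues([1.0, 2.0, 3.0], np.mean)
    assert np.allclose(out, [2.5, 2.0, 1.5])
    with pytest.raises(ValueError):
        delete_one_pseudovalues([1.0], np.mean)


def test_delete_one_mean_identity(rng):
    x = rng.normal(size=50)
    loo = delete_one_pseudovalues(x, np.mean)
    assert loo.mean() == pytest.approx(x.mean(), abs=1e-12)


def test_jackknife_se_simple_hand_value_and_closed_form(rng):
    assert jackknife_se_simple([2.5, 2.0, 1.5]) == pytest.approx(
        math.sqrt(2 / 3 * 0.5), abs=1e-12
    )
    assert jackknife_se_simple([1.0, 1.0, 1.0]) == 0.0
    # for the mean, the jackknife SE equals the classical s/sqrt(n)
    x = rng.normal(size=80)
    loo = delete_one_pseudovalues(x, np.mean)
    assert jackknife_se_simple(loo) == pytest.approx(
        x.std(ddof=1) / math.sqrt(x.size), abs=1e-12
    )


# -- weighted block jackknife equations -------------------------------------

def test_weighted_estimate_hand_value():
    assert weighted_jackknife_estimate(two_block_reps()) == pytest.approx(1.0, abs=1e-12)


def test_weighted_se_hand_value():
    assert weighted_jackknife_se(two_block_reps()) == pytest.approx(0.1, abs=1e-12)


def test_no_deviation_means_no_correction():
    reps = two_block_reps(theta=2.0, minus=(2.0, 2.0))
    assert weighted_jackknife_estimate(reps) == pytest.approx(2.0)
    assert weighted_jackknife_se(reps) == 0.0


def test_weighted_estimate_is_theta_for_linear_statistic_equal_blocks(rng):
    t = random_table(rng, 120, n_chroms=1)
    part = partition_equal_count(t, 12)
    stat = column_mean_statistic("d_y")
    reps = block_jackknife(t, part, stat)
    assert weighted_jackknife_estimate(reps) == pytest.approx(stat(t), abs=1e-12)


def test_singleton_blocks_reduce_to_delete_one(rng):
    t = random_table(rng, 40, n_chroms=1)
    part = partition_equal_count(t, t.n_sites)
    stat = column_mean_statistic("d_x")
    reps = block_jackknife(t, part, stat)
    col = t.df["d_x"].to_numpy(dtype=float)
    loo = delete_one_pseudovalues(col, np.mean)
    assert np.allclose(reps.values, loo, atol=1e-12)
    # ... and the weighted SE coincides with the simple jackknife SE = s/sqrt(n)
    assert weighted_jackknife_se(reps) == pytest.approx(
        jackknife_se_simple(loo), abs=1e-12
    )
    assert weighted_jackknife_se(reps) == pytest.approx(
        col.std(ddof=1) / math.sqrt(col.size), abs=1e-12
    )


def test_block_jackknife_constant_table_gives_flat_replicates():
    t = make_table([("1", i + 1, "all", 1, 2, 1, 2) for i in range(12)])
    reps = block_jackknife(t, partition_equal_count(t, 4), rxy_statistic())
    assert reps.theta_full == 1.0
    assert np.all(reps.values == 1.0)
    assert reps.g == 4 and reps.n == 12


def test_block_jackknife_names_offending_block():
    # only block 0 carries allele mass in Y: leaving it out zeroes the denominator
    rows = [("1", 1, "all", 1, 2, 1, 2), ("1", 2, "all", 1, 2, 1, 2)]
    rows += [("1", i + 3, "all", 1, 2, 0, 2) for i in range(6)]
    t = make_table(rows)
    part = partition_equal_count(t, 4)
    with pytest.raises(RxyUndefinedError, match="block 0"):
        block_jackknife(t, part, rxy_statistic())


def test_naive_pseudovalue_sd_is_flagged_and_matches_formulas(rng):
    reps = two_block_reps()
    summary = naive_pseudovalue_sd(reps)
    assert summary.method == "naive_pseudovalue_sd"
    assert KNOWN_BIASED_FLAG in summary.flags
    # g=2: sample SD of two points is |a-b|/sqrt(2)
    assert summary.se == pytest.approx(abs(0.9 - 1.1) / math.sqrt(2), abs=1e-12)
    assert summary.estimate == pytest.approx(1.0)
    # singleton blocks, mean statistic: pseudo-value SD is s/(n-1)
    t = random_table(rng, 60, n_chroms=1)
    jack = block_jackknife(
        t, partition_equal_count(t, t.n_sites), column_mean_statistic("d_x")
    )
    col = t.df["d_x"].to_numpy(dtype=float)
    assert naive_pseudovalue_sd(jack).se == pytest.approx(
        col.std(ddof=1) / (col.size - 1), abs=1e-12
    )


def test_naive_to_weighted_ratio_near_root_g_over_g_minus_one(rng):
    # near-linear statistic (R_XY on many loci), g=100 equal blocks
    t = random_table(rng, 3000, n_chroms=1)
    part = partition_equal_count(t, 100)
    reps = rxy_block_jackknife(t, part)
    ratio = naive_pseudovalue_sd(reps).se / weighted_jackknife_se(reps)
    assert ratio == pytest.approx(math.sqrt(100) / 99, rel=0.05)


# -- block bootstrap ---------------------------------------------------------

def test_bootstrap_is_deterministic_given_seed(rng):
    t = random_table(rng, 60, n_chroms=2)
    part = partition_equal_count(t, 6)
    stat = rxy_statistic()
    a = block_bootstrap(t, part, stat, B=25, seed=11)
    b = block_bootstrap(t, part, stat, B=25, seed=11)
    assert a.replicates == b.replicates
    c = block_bootstrap(t, part, stat, B=25, seed=12)
    assert a.replicates != c.replicates


def test_bootstrap_replicate_draws_depend_only_on_seed_and_index():
    idx = bootstrap_block_indices(5, 3, 10)
    assert np.array_equal(idx, bootstrap_block_indices(5, 3, 10))
    assert not np.array_equal(idx, bootstrap_block_indices(5, 4, 10))


def test_bootstrap_constant_statistic_gives_zero_se():
    t = make_table([("1", i + 1, "all", 1, 2, 1, 2) for i in range(12)])
    reps = block_bootstrap(t, partition_equal_count(t, 4), rxy_statistic(), B=20, seed=0)
    summary = bootstrap_summary(reps)
    assert summary.estimate == pytest.approx(1.0)
    assert summary.se == 0.0


def test_bootstrap_se_matches_analytic_block_mean_se(rng):
    t = random_table(rng, 200, n_chroms=1)
    g = 20
    part = partition_equal_count(t, g)
    stat = column_mean_statistic("d_x")
    reps = block_bootstrap(t, part, stat, B=1000, seed=2)
    se = bootstrap_summary(reps).se
    # resample mean = mean of g block means drawn with replacement
    col = t.df["d_x"].to_numpy(dtype=float)
    block_means = col.reshape(g, -1).mean(axis=1)
    analytic = block_means.std(ddof=0) / math.sqrt(g)
    assert se == pytest.approx(analytic, rel=0.15)


def test_bootstrap_summary_weighted_hand_values():
    reps = BootstrapReplicates(replicates=((0.0, 1), (4.0, 3)), B=2, seed=0)
    summary = bootstrap_summary(reps)
    assert summary.estimate == pytest.approx(3.0)
    assert summary.se == pytest.approx(math.sqrt(3.0), abs=1e-12)
    # equal weights reduce to the plain mean / population SD
    reps = BootstrapReplicates(replicates=((1.0, 5), (3.0, 5)), B=2, seed=0)
    summary = bootstrap_summary(reps)
    assert summary.estimate == pytest.approx(2.0)
    assert summary.se == pytest.approx(1.0)


def test_failed_bootstrap_replicates_are_dropped_not_fatal():
    # block 1 carries all Y mass; resamples without it are undefined
    rows = [("1", 1, "all", 1, 2, 0, 2), ("1", 2, "all", 1, 2, 0, 2)]
    rows += [("1", 3, "all", 1, 2, 2, 2), ("1", 4, "all", 1, 2, 2, 2)]
    t = make_table(rows)
    part = partition_equal_count(t, 2)
    reps = block_bootstrap(t, part, rxy_statistic(), B=40, seed=1)
    assert reps.n_failed > 0
    assert len(reps.replicates) + reps.n_failed == 40


# -- CV trace ----------------------------------------------------------------

def test_cv_trace_contract_and_constant_case():
    reps = BootstrapReplicates(replicates=tuple((2.0, 1) for _ in range(30)), B=30, seed=0)
    trace = bootstrap_cv_trace(reps)
    assert len(trace) == 30 - 9
    assert trace[0][0] == 10 and trace[-1][0] == 30
    assert all(cv == 0.0 for _, cv in trace)


def test_cv_trace_decreases_on_average_for_iid_replicates():
    firsts, lasts = [], []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        vals = rng.normal(1.0, 0.2, size=400)
        reps = BootstrapReplicates(
            replicates=tuple((float(v), 1) for v in vals), B=400, seed=seed
        )
        cvs = [cv for _, cv in bootstrap_cv_trace(reps)]
        half = len(cvs) // 2
        firsts.append(np.mean(cvs[:half]))
        lasts.append(np.mean(cvs[half:]))
    assert np.mean(lasts) < np.mean(firsts)


# -- fast R_XY paths agree with the generic statistic route ------------------

def test_rxy_fast_jackknife_matches_generic(rng):
    t = random_table(rng, 150, n_chroms=2, categories=("neutral", "focal"))
    part = partition_equal_count(t, 10)
    for focal, neutral in [(None, None), ("focal", None), ("focal", "neutral")]:
        fast = rxy_block_jackknife(t, part, focal, neutral)
        generic = block_jackknife(t, part, rxy_statistic(focal, neutral))
        assert fast.theta_full == pytest.approx(generic.theta_full, rel=1e-10)
        assert np.allclose(fast.values, generic.values, rtol=1e-10)
        assert np.array_equal(fast.sizes, generic.sizes)


def test_rxy_fast_bootstrap_matches_generic(rng):
    t = random_table(rng, 150, n_chroms=2, categories=("neutral", "focal"))
    part = partition_equal_count(t, 10)
    fast = rxy_block_bootstrap(t, part, "focal", "neutral", B=30, seed=9)
    generic = block_bootstrap(t, part, rxy_statistic("focal", "neutral"), B=30, seed=9)
    assert fast.n_failed == generic.n_failed
    assert np.allclose(fast.values, generic.values, rtol=1e-10)
    assert np.array_equal(fast.weights, generic.weights)


def test_jackknife_summary_object(rng):
    t = random_table(rng, 80, n_chroms=1)
    reps = rxy_block_jackknife(t, partition_equal_count(t, 8))
    summary = jackknife_summary(reps)
    assert summary.method == "weighted_block_jackknife"
    assert summary.g_or_B == 8
    assert summary.se >= 0
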