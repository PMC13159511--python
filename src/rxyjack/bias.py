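"""Bias of three standard-error estimators for the mean of normal samples.

For samples of size n from Normal(mu, sigma), three candidate estimators of
the standard error of the mean are compared with the truth sigma/sqrt(n):

- ``naive_jackknife_sd``: the raw SD of the delete-one jackknife values of
  the mean. Biased low by a factor sqrt(n)/(n - 1) — about one tenth of the
  truth at n = 100 — so the mean ratio follows a power law close to n^-0.5.
- ``bootstrap_sd``: the SD of bootstrap replicate means. Consistent.
- ``jackknife_se``: the proper jackknife SE formula. Equals s/sqrt(n) for the
  mean, hence unbiased up to E[s]/sigma.

:func:`fit_power_law` recovers the exponent of the relative underestimation
by ordinary least squares on log-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = ["ESTIMATORS", "BiasRow", "BiasCurve", "simulate_bias_curve", "fit_power_law"]

ESTIMATORS = ("naive_jackknife_sd", "bootstrap_sd", "jackknife_se")

DEFAULT_N_GRID = (10, 20, 50, 100, 200, 500, 1000)


class BiasRow(NamedTuple):
    n: int
    estimator: str
    mean_ratio: float
    n_replicates: int


@dataclass(frozen=True)
class BiasCurve:
    """Mean estimator/truth ratios per sample size, one row per
    (n, estimator)."""

    rows: tuple[BiasRow, ...]
    mu: float
    sigma: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["n", "estimator", "mean_ratio", "n_replicates"])

    def ratios(self, estimator: str) -> pd.DataFrame:
        df = self.to_frame()
        out = df[df["estimator"] == estimator].sort_values("n").reset_index(drop=True)
        if out.empty:
            raise ValueError(f"no rows for estimator {estimator!r}")
        return out


def _loo_means(x: np.ndarray) -> np.ndarray:
    """Delete-one jackknife values of the mean, for each row of a 2-D sample
    array: loo[r, j] = mean of row r without element j."""
    n = x.shape[1]
    return (x.sum(axis=1, keepdims=True) - x) / (n - 1)


def simulate_bias_curve(
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    replicates: int = 1000,
    B_boot: int = 500,
    mu: float = 10.0,
    sigma: float = 1.0,
    seed: int = 0,
    estimators: Sequence[str] = ESTIMATORS,
    empirical_se: str = "exact",
) -> BiasCurve:
    """Monte-Carlo bias curves for SE estimators of the mean.

    For every n in ``n_grid`` and every simulation replicate, a Normal(mu,
    sigma) sample of size n is drawn and each requested estimator is divided
    by the standard error to give a bias ratio; the mean ratio over
    replicates is recorded.

    Parameters
    ----------
    empirical_se : {"exact", "monte_carlo"}
        Denominator of the ratio: the known truth sigma/sqrt(n) (default; the
        generative parameters are known, so this removes one layer of noise)
        or the SD of the replicate sample means (the fully empirical
        alternative).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if replicates < 10:
        raise ValueError("need at least 10 replicates")
    if any(n < 3 for n in n_grid):
        raise ValueError("every sample size must be >= 3")
    unknown = set(estimators) - set(ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimator(s): {sorted(unknown)}")
    if empirical_se not in ("exact", "monte_carlo"):
        raise ValueError("empirical_se must be 'exact' or 'monte_carlo'")

    rows: list[BiasRow] = []
    for n in n_grid:
        rng = np.random.default_rng(np.random.SeedSequence([seed, int(n)]))
        x = rng.normal(mu, sigma, size=(replicates, n))
        if empirical_se == "exact":
            true_se = sigma / np.sqrt(n)
        else:
            true_se = x.mean(axis=1).std(ddof=1)

        per_est: dict[str, np.ndarray] = {}
        if "naive_jackknife_sd" in estimators or "jackknife_se" in estimators:
            loo = _loo_means(x)
            if "naive_jackknife_sd" in estimators:
                per_est["naive_jackknife_sd"] = loo.std(axis=1, ddof=1)
            if "jackknife_se" in estimators:
                dev = loo - loo.mean(axis=1, keepdims=True)
                per_est["jackknife_se"] = np.sqrt((n - 1) / n * (dev**2).sum(axis=1))
        if "bootstrap_sd" in estimators:
            boot_sd = np.empty(replicates)
            for r in range(replicates):
                idx = rng.integers(0, n, size=(B_boot, n))
                boot_sd[r] = x[r][idx].mean(axis=1).std(ddof=1)
            per_est["bootstrap_sd"] = boot_sd

        for est in estimators:
            ratio = per_est[est] / true_se
            rows.append(BiasRow(int(n), est, float(ratio.mean()), replicates))
    return BiasCurve(rows=tuple(rows), mu=mu, sigma=sigma, seed=seed)


def fit_power_law(curve: BiasCurve, estimator: str) -> tuple[float, float]:
    """OLS fit of log(mean_ratio) on log(n): returns (exponent, intercept).

    An unbiased estimator gives exponent ~ 0; the naive pseudo-value SD gives
    ~ -0.5 (underestimation worsens as the square root of sample size).
    """
    df = curve.ratios(estimator)
    if df["n"].nunique() < 3:
        raise ValueError("need >= 3 distinct sample sizes to fit a power law")
    slope, intercept = np.polyfit(np.log(df["n"]), np.log(df["mean_ratio"]), 1)
    return float(slope), float(intercept)
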