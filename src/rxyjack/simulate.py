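"""Synthetic allele-count tables with known ground-truth R_XY per category.

The generator emulates the structure of real load analyses: several
chromosomes of unequal locus counts, mutation-impact categories (high /
moderate / low / intergenic), and category-specific shifts in allele
frequency between a focal population X and a reference population Y.

Per site, a baseline frequency p is drawn from Beta(freq_alpha, freq_beta);
the reference population carries p_y = p, the focal population
p_x = clip(effect_c * p, 0, 1) for the site's category c; allele counts are
then binomial draws given the haploid sample sizes. Under this model

    E[R_XY] for a category = E[p_x (1 - p_y)] / E[p_y (1 - p_x)],

which :func:`expected_rxy` evaluates by Monte Carlo, giving a truth value
for every estimator and test in the package to be checked against. Sites are
independent (no linkage within blocks is simulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sites import SITE_COLUMNS, SiteTable

__all__ = ["SimConfig", "default_config", "generate_site_table", "expected_rxy"]


def _default_chroms() -> dict[str, int]:
    # 16 chromosomes of unequal size totalling 50,000 loci (an insect-like
    # karyotype with a realistic size spread).
    sizes = [6000, 5500, 5100, 4700, 4300, 4000, 3600, 3300,
             3000, 2700, 2300, 1900, 1300, 1000, 800, 500]
    return {f"chr{i + 1:02d}": s for i, s in enumerate(sizes)}


def _default_proportions() -> dict[str, float]:
    # high-impact annotations are rare; intergenic sites dominate
    return {"intergenic": 0.70, "low": 0.15, "moderate": 0.10, "high": 0.05}


def _default_effects() -> dict[str, float]:
    return {"intergenic": 1.0, "low": 1.0, "moderate": 1.0, "high": 1.0}


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic two-population site table.

    Attributes
    ----------
    chrom_locus_counts : dict[str, int]
        Loci per chromosome (all > 0).
    category_proportions : dict[str, float]
        Mixing proportions of impact categories; must sum to 1.
    n_x, n_y : int
        Haploid sample sizes (40 = 20 diploid individuals each by default).
    freq_alpha, freq_beta : float
        Beta shape parameters of the baseline allele-frequency distribution;
        the default Beta(0.5, 2) is rare-allele heavy, like an empirical
        folded site-frequency spectrum.
    category_effect : dict[str, float]
        Multiplicative factor on population-X frequencies per category
        (1 = neutral, < 1 depletion/purging in X, > 1 enrichment).
    fixed_freq : float or None
        If set, use the degenerate baseline p = fixed_freq instead of the
        Beta draw (useful for closed-form checks).
    seed : int
        Drives all random draws; identical configs give identical tables.
    """

    chrom_locus_counts: dict[str, int] = field(default_factory=_default_chroms)
    category_proportions: dict[str, float] = field(default_factory=_default_proportions)
    n_x: int = 40
    n_y: int = 40
    freq_alpha: float = 0.5
    freq_beta: float = 2.0
    category_effect: dict[str, float] = field(default_factory=_default_effects)
    fixed_freq: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_locus_counts:
            raise ValueError("need at least one chromosome")
        for c, k in self.chrom_locus_counts.items():
            if k <= 0:
                raise ValueError(f"chromosome {c!r} has 0 loci")
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions sum to {total}, not 1")
        if set(self.category_effect) != set(self.category_proportions):
            raise ValueError("category_effect keys must match category_proportions")
        if any(e <= 0 for e in self.category_effect.values()):
            raise ValueError("effect factors must be > 0")
        if self.n_x <= 0 or self.n_y <= 0:
            raise ValueError("haploid sample sizes must be positive")
        if self.freq_alpha <= 0 or self.freq_beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if self.fixed_freq is not None and not 0.0 <= self.fixed_freq <= 1.0:
            raise ValueError("fixed_freq must lie in [0, 1]")

    def with_effects(self, **effects: float) -> "SimConfig":
        """A copy with some category effects replaced."""
        merged = {**self.category_effect, **effects}
        return replace(self, category_effect=merged)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The package's reference study conditions (null: all effects 1)."""
    return replace(SimConfig(seed=seed), **overrides) if overrides else SimConfig(seed=seed)


def _draw_baseline(rng: np.random.Generator, config: SimConfig, size: int) -> np.ndarray:
    if config.fixed_freq is not None:
        return np.full(size, config.fixed_freq)
    return rng.beta(config.freq_alpha, config.freq_beta, size=size)


def generate_site_table(config: SimConfig) -> tuple[SiteTable, dict[str, float]]:
    """Simulate a site table and return it with per-category truth values.

    Returns
    -------
    (table, truth)
        ``truth`` maps each category to its expected (unstandardised) R_XY
        under the config, from :func:`expected_rxy`; standardised truths are
        ratios of these entries.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    cats = sorted(config.category_proportions)
    probs = np.array([config.category_proportions[c] for c in cats])
    effects = np.array([config.category_effect[c] for c in cats])

    frames = []
    for chrom in sorted(config.chrom_locus_counts):
        k = config.chrom_locus_counts[chrom]
        gaps = rng.integers(1, 100, size=k)
        pos = np.cumsum(gaps)
        cat_idx = rng.choice(len(cats), size=k, p=probs)
        p = _draw_baseline(rng, config, k)
        p_x = np.clip(effects[cat_idx] * p, 0.0, 1.0)
        d_x = rng.binomial(config.n_x, p_x)
        d_y = rng.binomial(config.n_y, p)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "category": np.array(cats, dtype=object)[cat_idx],
            "d_x": d_x,
            "n_x": config.n_x,
            "d_y": d_y,
            "n_y": config.n_y,
        }))
    df = pd.concat(frames, ignore_index=True)[list(SITE_COLUMNS)]
    table = SiteTable(df)
    truth = {c: expected_rxy(config, c) for c in cats}
    return table, truth


def expected_rxy(config: SimConfig, category: str, mc_draws: int = 200_000) -> float:
    """Ground-truth E-ratio R_XY for one category under the config's
    frequency model: E[p_x (1 - p_y)] / E[p_y (1 - p_x)], by Monte Carlo.

    Sample allele frequencies d/n are unbiased for the true frequencies and
    the populations are drawn independently, so the expected L sums are sums
    of these per-site expectations; category membership is independent of p,
    hence a single expectation over p suffices. The Monte-Carlo seed derives
    from the config seed (independently of the table draws), so truths are
    reproducible.
    """
    if category not in config.category_effect:
        raise ValueError(f"category not found: {category!r}")
    effect = config.category_effect[category]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    p = _draw_baseline(rng, config, mc_draws)
    p_x = np.clip(effect * p, 0.0, 1.0)
    num = float(np.mean(p_x * (1.0 - p)))
    den = float(np.mean(p * (1.0 - p_x)))
    if den == 0.0:
        raise ZeroDivisionError("expected R_XY undefined: denominator is zero")
    return num / den
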