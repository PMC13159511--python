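import numpy as np
import pandas as pd
import pytest

from rxyjack.sites import SITE_COLUMNS, SiteTable


def make_table(rows):
    """Build a SiteTable from (chrom, pos, category, d_x, n_x, d_y, n_y) rows."""
    return SiteTable(pd.DataFrame(rows, columns=list(SITE_COLUMNS)))


def random_table(rng, n_sites, n_chroms=2, categories=("neutral", "focal"), n_max=20):
    """A random valid site table with positive allele mass in both directions."""
    chroms = [f"chr{c + 1}" for c in rng.integers(0, n_chroms, size=n_sites)]
    rows = []
    pos_counter = {}
    for i in range(n_sites):
        c = chroms[i]
        pos_counter[c] = pos_counter.get(c, 0) + int(rng.integers(1, 50))
        n_x = int(rng.integers(1, n_max))
        n_y = int(rng.integers(1, n_max))
        rows.append((
            c, pos_counter[c], categories[int(rng.integers(0, len(categories)))],
            int(rng.integers(0, n_x + 1)), n_x,
            int(rng.integers(0, n_y + 1)), n_y,
        ))
    return make_table(rows)


@pytest.fixture
def two_site_table():
    """Two sites with hand-computable L sums: L_X,notY = 1.25, L_Y,notX = 0.25."""
    return make_table([
        ("1", 1, "all", 1, 2, 1, 2),
        ("1", 2, "all", 2, 2, 0, 2),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def column_mean_statistic(column="d_x"):
    """Mean of a numeric site column — a linear statistic for equivalence tests."""
    def stat(table):
        return float(table.df[column].to_numpy(dtype=float).mean())
    stat.label = f"mean[{column}]"
    return stat
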