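"""Replicate the published stick-insect (Dryococelus australis) load analysis.

Downloads (or uses a local clone of) the public repository holding the
captive-vs-wild allele-frequency data

    https://github.com/OliverPStuart/2025_Jackknife_Review/

converts its per-site allele counts into the site-table dialect used here,
and runs the full pipeline: standardised R_XY per impact category (high /
moderate / low, standardised by intergenic), with weighted block jackknife
(g = 100 equal-count blocks, and one block per autosome) and block bootstrap
(B in {100, 500, 1000}) uncertainty.

Expected ballpark, from the published analysis: whole-genome standardised
R_XY ~ 0.73 (high), ~ 1.01 (low), ~ 1.01 (moderate); block-jackknife
mean +/- SE for the high category ~ 0.725 +/- 0.103.

Because the upstream repository's exact file layout may change, the column
mapping is exposed as flags; point --table at the allele-count file and name
the columns if the defaults do not match. This script needs network access
(or --data pointing at an existing clone) and is not part of the test suite.

Usage:
    python scripts/replicate_worked_example.py --workdir scratch/replication
    python scripts/replicate_worked_example.py --data /path/to/clone \
        --table Data/allele_counts.tsv
"""

from __future__ import annotations

import argparse
import subprocess
import sys
from pathlib import Path

import pandas as pd

from rxyjack.blocks import partition_by_chromosome, partition_equal_count
from rxyjack.inference import one_sample_t
from rxyjack.resampling import (
    bootstrap_summary,
    jackknife_summary,
    rxy_block_bootstrap,
    rxy_block_jackknife,
)
from rxyjack.sites import SITE_COLUMNS, SiteTable

REPO_URL = "https://github.com/OliverPStuart/2025_Jackknife_Review.git"


def fetch_repo(workdir: Path) -> Path:
    clone = workdir / "2025_Jackknife_Review"
    if not clone.exists():
        workdir.mkdir(parents=True, exist_ok=True)
        subprocess.run(["git", "clone", "--depth", "1", REPO_URL, str(clone)], check=True)
    return clone


def find_candidate_tables(root: Path) -> list[Path]:
    exts = {".tsv", ".txt", ".csv", ".gz"}
    return sorted(
        p for p in root.rglob("*")
        if p.is_file() and p.suffix.lower() in exts and p.stat().st_size > 1024
    )


def load_site_table(path: Path, args: argparse.Namespace) -> SiteTable:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    mapping = {
        args.chrom_col: "chrom",
        args.pos_col: "pos",
        args.category_col: "category",
        args.dx_col: "d_x",
        args.nx_col: "n_x",
        args.dy_col: "d_y",
        args.ny_col: "n_y",
    }
    missing = [c for c in mapping if c not in df.columns]
    if missing:
        raise SystemExit(
            f"{path}: missing column(s) {missing}; available: {list(df.columns)}.\n"
            "Use --chrom-col/--pos-col/... to map the repository's column names."
        )
    df = df.rename(columns=mapping)[list(SITE_COLUMNS)]
    return SiteTable(df)


def report(table: SiteTable, neutral: str, seed: int) -> None:
    focal = [c for c in table.categories if c != neutral]
    partitions = {"block (g=100)": partition_equal_count(table, 100)}
    try:
        partitions["chromosome"] = partition_by_chromosome(table)
    except ValueError:
        pass
    for name, part in partitions.items():
        print(f"\n== weighted block jackknife, {name} ==")
        for cat in focal:
            s = jackknife_summary(rxy_block_jackknife(table, part, cat, neutral))
            t = one_sample_t(s, null_value=1.0)
            print(f"{cat:12s} mean={s.estimate:.3f} se={s.se:.3f} "
                  f"t={t.statistic_value:.3f} p={t.p_two_sided:.3f}")
    part = partitions["block (g=100)"]
    for B in (100, 500, 1000):
        print(f"\n== block bootstrap, B={B} ==")
        for cat in focal:
            s = bootstrap_summary(
                rxy_block_bootstrap(table, part, cat, neutral, B=B, seed=seed)
            )
            t = one_sample_t(s, null_value=1.0)
            print(f"{cat:12s} mean={s.estimate:.3f} se={s.se:.3f} "
                  f"t={t.statistic_value:.3f} p={t.p_two_sided:.3f}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workdir", type=Path, default=Path("scratch/replication"))
    parser.add_argument("--data", type=Path, default=None,
                        help="Existing clone of the data repository (skips download).")
    parser.add_argument("--table", type=Path, default=None,
                        help="Allele-count file inside the repository.")
    parser.add_argument("--neutral-category", default="intergenic")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--chrom-col", default="chrom")
    parser.add_argument("--pos-col", default="pos")
    parser.add_argument("--category-col", default="category")
    parser.add_argument("--dx-col", default="d_x")
    parser.add_argument("--nx-col", default="n_x")
    parser.add_argument("--dy-col", default="d_y")
    parser.add_argument("--ny-col", default="n_y")
    args = parser.parse_args()

    root = args.data if args.data is not None else fetch_repo(args.workdir)
    if args.table is not None:
        table_path = root / args.table if not args.table.is_absolute() else args.table
    else:
        candidates = find_candidate_tables(root)
        if not candidates:
            raise SystemExit(f"no tabular data files found under {root}")
        print("candidate data files:", file=sys.stderr)
        for p in candidates:
            print(f"  {p.relative_to(root)}", file=sys.stderr)
        raise SystemExit("re-run with --table pointing at the allele-count file")

    table = load_site_table(table_path, args)
    print(f"loaded {table.n_sites} sites, categories: {list(table.categories)}")
    report(table, args.neutral_category, args.seed)


if __name__ == "__main__":
    main()
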