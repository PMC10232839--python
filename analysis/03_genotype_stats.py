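#!/usr/bin/env python
"""Permutation statistics of the WT vs K78R comparison.

Reads the normalized feature table, runs the label-permutation
Mann-Whitney test per feature on per-well DIV-combined values, combines
per-plate p-values with Fisher's method (a single plate here, so the
combination is the identity), and writes ``results/mea/genotype_stats.csv``.
"""

import argparse
from pathlib import Path

from meaphen import io
from meaphen.config import AnalysisConfig
from meaphen.stats import fisher_combine, genotype_comparison

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-perm", type=int, default=1000)
    args = ap.parse_args()

    cfg = AnalysisConfig().override("stats", n_perm=args.n_perm)
    outdir = ROOT / "results" / "mea"
    table = io.read_feature_table(outdir / "features_normalized.csv")
    pmap = io.read_plate_map(outdir / "sim" / "plate_map.csv")

    stats = genotype_comparison(table, pmap, params=cfg.stats, seed=args.seed)
    stats["p_fisher"] = [fisher_combine([p]) for p in stats["p_perm"]]
    stats.to_csv(outdir / "genotype_stats.csv", index=False)

    print(f"{args.n_perm}-permutation MWU, {stats['n_wt'].iloc[0]} WT vs "
          f"{stats['n_mut'].iloc[0]} K78R wells:\n")
    show = stats[["feature", "p_perm", "direction"]].copy()
    show["direction"] = show["direction"].map(lambda d: "up in K78R" if d > 0 else "down in K78R")
    print(show.to_string(index=False))
    print(f"\nresults -> {outdir}/genotype_stats.csv")


if __name__ == "__main__":
    main()
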