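#!/usr/bin/env python
"""Encode all DEFRlncRNA pairs as within-sample 0/1 indicators and drop
pairs outside the 20-80% frequency band (no certain class).

Reads the screened gene list from 02_screen_lncrnas.py and writes the
filtered pair-indicator matrix.
"""

import argparse
from pathlib import Path

import ferropair as fp
from ferropair import io


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--low", type=float, default=0.20)
    ap.add_argument("--high", type=float, default=0.80)
    args = ap.parse_args()

    expr = io.read_expression(args.datadir / "expression.tsv")
    genes = io.read_gene_list(args.outdir / "defrlncrna.txt", "DEFRlncRNA")

    pm = fp.build_pair_matrix(expr, sorted(genes.members))
    kept = fp.filter_pairs(pm, args.low, args.high)
    io.write_table(kept, args.outdir / "pair_indicators.tsv")

    n = len(genes)
    print(f"pairing: {n} genes -> {len(pm.pair_ids)} pairs (= {n}*{n-1}/2)")
    print(f"frequency filter ({args.low:.0%}, {args.high:.0%}): "
          f"retained {len(kept.pair_ids)}, removed {kept.n_removed}")


if __name__ == "__main__":
    main()
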