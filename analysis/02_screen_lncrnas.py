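#!/usr/bin/env python
"""Screen lncRNAs: FRG coexpression (Pearson r > 0.4, p < 0.001 on
log2(x+1) values) followed by tumor-vs-normal differential expression
(rank-sum, BH FDR < 0.05, |log2FC| >= 1.5).

Reads the cohort written by 01_simulate_cohort.py and writes the
coexpression table, the DE table, and the screened gene lists.
"""

import argparse
from pathlib import Path

import ferropair as fp
from ferropair import io


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--r-min", type=float, default=0.4)
    ap.add_argument("--p-max", type=float, default=0.001)
    ap.add_argument("--fdr", type=float, default=0.05)
    ap.add_argument("--lfc", type=float, default=1.5)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    expr = io.read_expression(args.datadir / "expression.tsv")
    ann = io.read_biotype_table(args.datadir / "annotation.tsv")
    frg = io.read_gene_list(args.datadir / "frg.txt", "FRG")

    lnc_ids = [g for g in ann.genes_with_biotype("lncRNA") if g in expr.gene_ids]
    frg_ids = sorted(set(frg.members) & set(expr.gene_ids) - set(lnc_ids))

    coex = fp.pearson_screen(expr, lnc_ids, frg_ids, r_min=args.r_min, p_max=args.p_max)
    io.write_table(coex.table, args.outdir / "coexpression.tsv")
    io.write_gene_list(
        fp.GeneSet.from_iterable("FRlncRNA", coex.frlnc_ids),
        args.outdir / "frlncrna.txt",
    )
    print(f"coexpression screen: {len(coex.frlnc_ids)}/{len(lnc_ids)} lncRNAs "
          f"have an FRG partner at r > {args.r_min}, p < {args.p_max}")

    de = fp.differential_expression(expr, coex.frlnc_ids, fdr_max=args.fdr,
                                    lfc_min=args.lfc)
    io.write_table(de.table, args.outdir / "differential_expression.tsv")
    io.write_gene_list(
        fp.GeneSet.from_iterable("DEFRlncRNA", de.de_ids),
        args.outdir / "defrlncrna.txt",
    )
    print(f"differential expression: {len(de.de_ids)} DEFRlncRNAs "
          f"({de.n_up} up, {de.n_down} down) at FDR < {args.fdr}, "
          f"|log2FC| >= {args.lfc}")


if __name__ == "__main__":
    main()
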