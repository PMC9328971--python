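#!/usr/bin/env python
"""Validate the fitted signature: Kaplan-Meier curves and log-rank test for
the risk groups, chi-squared / rank-sum clinical associations, univariate
and multivariate independence Cox models, decision-curve analysis and a
nomogram at 1/3/5 years, and a risk-group comparison of a gene panel.

Reads the outputs of 04_fit_signature.py.
"""

import argparse
from pathlib import Path

import pandas as pd

import ferropair as fp
from ferropair import io
from ferropair.evaluate import (
    build_nomogram,
    clinical_association,
    clinical_design,
    decision_curve,
    independence_cox,
    km_estimate,
    logrank_test,
    panel_group_compare,
)

DAYS_PER_YEAR = 365.25


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    expr = io.read_expression(args.datadir / "expression.tsv")
    clin = io.read_clinical(args.datadir / "clinical.tsv")
    prof = io.read_risk_profile(args.outdir / "risk_profile.tsv")
    shared = [s for s in prof.sample_ids if s in clin.sample_ids]
    clin = clin.subset(shared)
    surv = clin.survival

    curves = km_estimate(surv, prof.group)
    km = pd.concat(
        [c.to_frame().assign(group=label) for label, c in curves.items()],
        ignore_index=True,
    )
    io.write_table(km, args.outdir / "km_curves.tsv")
    stat, p = logrank_test(surv, prof.group)
    print(f"log-rank high vs low risk: chi2 = {stat:.2f}, p = {p:.3g}")

    assoc = clinical_association(prof, clin)
    io.write_table(assoc, args.outdir / "clinical_association.tsv")
    sig = assoc[(assoc.test == "chi2") & (assoc.p < 0.05)]["feature"].tolist()
    print(f"clinical features associated with the risk group (chi2 p < 0.05): "
          f"{sig or 'none'}")

    indep = independence_cox(prof, clin)
    io.write_table(indep.univariate, args.outdir / "cox_univariate.tsv")
    io.write_table(indep.multivariate, args.outdir / "cox_multivariate.tsv")
    row = indep.multivariate.set_index("covariate").loc["score"]
    print(f"risk score in the joint Cox model: HR = {row['hr']:.2f} "
          f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}], p = {row['p']:.3g}")

    nb = decision_curve(prof.scores, surv, horizon=5 * DAYS_PER_YEAR)
    io.write_table(nb, args.outdir / "decision_curve_5yr.tsv")
    useful = nb[nb.nb_model > nb[["nb_all", "nb_none"]].max(axis=1)]
    if len(useful):
        print(f"DCA: the model beats treat-all/none for thresholds "
              f"{useful.p_t.min():.2f}-{useful.p_t.max():.2f}")

    X = clinical_design(prof, clin)
    nom = build_nomogram(X, surv)
    pts = pd.DataFrame({
        "covariate": nom.betas.index,
        "beta": nom.betas.to_numpy(),
        "reference": nom.reference.loc[nom.betas.index].to_numpy(),
        "points_per_unit": (nom.scale * nom.betas).to_numpy(),
    })
    io.write_table(pts, args.outdir / "nomogram_points.tsv")
    ref_surv = {y: nom.predict_survival(nom.reference, y * DAYS_PER_YEAR)
                for y in (1, 3, 5)}
    print("nomogram baseline survival at reference profile: "
          + ", ".join(f"{y}y = {s:.2f}" for y, s in ref_surv.items()))

    # stand-in checkpoint panel: the first five FRGs of the synthetic cohort
    frg = io.read_gene_list(args.datadir / "frg.txt", "FRG")
    panel = fp.GeneSet.from_iterable("FRG_panel", sorted(frg.members)[:5])
    cmp = panel_group_compare(expr, panel, prof)
    io.write_table(cmp, args.outdir / "panel_comparison.tsv")
    n_sig = int((cmp["q"] < 0.05).sum())
    print(f"panel comparison: {n_sig}/{len(cmp)} genes differ between risk "
          f"groups at q < 0.05")


if __name__ == "__main__":
    main()
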