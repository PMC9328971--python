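"""Coexpression and differential-expression screens for ferroptosis-related
lncRNAs.

A lncRNA is "ferroptosis-related" (FRlncRNA) when it is coexpressed with at
least one ferroptosis-related gene (Pearson r > 0.4, p < 0.001 by default);
the differentially expressed subset (tumor vs normal, rank-sum + BH with a
fold-change floor) feeds the pair encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, NORMAL, TUMOR

log = logging.getLogger("ferropair")


@dataclass
class CoexpressionResult:
    """Per (lncRNA, FRG) Pearson correlation with its t-transform p-value."""

    table: pd.DataFrame  # columns: lncrna, frg, r, p
    frlnc_ids: list[str]


@dataclass
class DifferentialResult:
    """Per-gene tumor-vs-normal differential expression."""

    table: pd.DataFrame  # columns: gene, log2fc, p, q, direction
    de_ids: list[str]

    @property
    def n_up(self) -> int:
        de = self.table.set_index("gene").loc[self.de_ids]
        return int((de["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        de = self.table.set_index("gene").loc[self.de_ids]
        return int((de["direction"] == "down").sum())


def pearson_correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of Pearson r via the t transform with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def pearson_screen(
    expr: ExpressionMatrix,
    lnc_ids,
    frg_ids,
    r_min: float = 0.4,
    p_max: float = 0.001,
    absolute_r: bool = False,
    samples: str = "all",
) -> CoexpressionResult:
    """Screen lncRNAs for coexpression with ferroptosis-related genes.

    Correlations are Pearson r on log2(x+1) values across ``samples``
    ("all" by default, "tumor" restricts to tumor samples). A lncRNA enters
    the FRlncRNA set iff it has at least one FRG partner with r > ``r_min``
    (|r| with ``absolute_r``) and p < ``p_max``. Constant-expression genes
    are skipped with a warning. Raw p-values are used (no multiplicity
    adjustment at this stage).
    """
    lnc_ids = list(lnc_ids)
    frg_ids = list(frg_ids)
    if not lnc_ids or not frg_ids:
        raise ValueError("lnc_ids and frg_ids must be non-empty")
    if set(lnc_ids) & set(frg_ids):
        raise ValueError("lnc_ids and frg_ids must be disjoint")

    logx = expr.log2p1()
    if samples == TUMOR:
        logx = logx[expr.samples_of(TUMOR)]
    elif samples != "all":
        raise ValueError("samples must be 'all' or 'tumor'")
    n = logx.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 samples for a correlation screen, got {n}")

    L = logx.loc[lnc_ids].to_numpy()
    F = logx.loc[frg_ids].to_numpy()
    lnc_sd = L.std(axis=1)
    frg_sd = F.std(axis=1)
    keep_l = lnc_sd > 0
    keep_f = frg_sd > 0
    if not keep_l.all():
        log.warning("skipping %d constant lncRNAs in coexpression screen", int((~keep_l).sum()))
    if not keep_f.all():
        log.warning("skipping %d constant FRGs in coexpression screen", int((~keep_f).sum()))
    lnc_used = [g for g, k in zip(lnc_ids, keep_l) if k]
    frg_used = [g for g, k in zip(frg_ids, keep_f) if k]
    if not lnc_used or not frg_used:
        return CoexpressionResult(
            pd.DataFrame(columns=["lncrna", "frg", "r", "p"]), []
        )

    Lz = (L[keep_l] - L[keep_l].mean(axis=1, keepdims=True)) / lnc_sd[keep_l, None]
    Fz = (F[keep_f] - F[keep_f].mean(axis=1, keepdims=True)) / frg_sd[keep_f, None]
    R = (Lz @ Fz.T) / n
    P = pearson_correlation_pvalues(R, n)

    table = pd.DataFrame(
        {
            "lncrna": np.repeat(lnc_used, len(frg_used)),
            "frg": np.tile(frg_used, len(lnc_used)),
            "r": R.ravel(),
            "p": P.ravel(),
        }
    )
    r_ok = np.abs(R) > r_min if absolute_r else R > r_min
    hit = (r_ok & (P < p_max)).any(axis=1)
    frlnc = [g for g, h in zip(lnc_used, hit) if h]
    return CoexpressionResult(table, frlnc)


def differential_expression(
    expr: ExpressionMatrix,
    gene_ids,
    fdr_max: float = 0.05,
    lfc_min: float = 1.5,
) -> DifferentialResult:
    """Tumor-vs-normal differential expression on the given genes.

    log2FC = log2((mean_tumor + 1) / (mean_normal + 1)) on the linear scale;
    p from the two-sided Wilcoxon rank-sum (Mann-Whitney) test; q by
    Benjamini-Hochberg across the tested genes. A gene is differentially
    expressed iff q < ``fdr_max`` and |log2FC| >= ``lfc_min``.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        return DifferentialResult(
            pd.DataFrame(columns=["gene", "log2fc", "p", "q", "direction"]), []
        )
    tumor = expr.samples_of(TUMOR)
    normal = expr.samples_of(NORMAL)
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("both conditions need >= 2 samples for the DE screen")

    T = expr.values.loc[gene_ids, tumor].to_numpy()
    N = expr.values.loc[gene_ids, normal].to_numpy()
    log2fc = np.log2((T.mean(axis=1) + 1.0) / (N.mean(axis=1) + 1.0))
    pvals = np.empty(len(gene_ids))
    for i in range(len(gene_ids)):
        if np.ptp(T[i]) == 0 and np.ptp(N[i]) == 0 and T[i][0] == N[i][0]:
            pvals[i] = 1.0  # identical constant values in both groups
            continue
        pvals[i] = stats.mannwhitneyu(T[i], N[i], alternative="two-sided").pvalue
    qvals = bh_adjust(pvals)
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    table = pd.DataFrame(
        {"gene": gene_ids, "log2fc": log2fc, "p": pvals, "q": qvals, "direction": direction}
    )
    de = (qvals < fdr_max) & (np.abs(log2fc) >= lfc_min)
    de_ids = [g for g, d in zip(gene_ids, de) if d]
    return DifferentialResult(table, de_ids)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, clipped at
    1; returned in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
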