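"""End-to-end orchestration: screening -> pair encoding -> signature fitting
-> risk stratification, with a frozen-model application path for held-out
cohorts. The analysis drivers, test suite and acceptance script all run the
pipeline through this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model as sig
from .evaluate import logrank_test
from .pairs import build_pair_matrix, filter_pairs
from .screening import (
    CoexpressionResult,
    DifferentialResult,
    differential_expression,
    pearson_screen,
)
from .types import (
    ClinicalTable,
    EmptySignatureError,
    ExpressionMatrix,
    GeneAnnotation,
    GeneSet,
    PairIndicatorMatrix,
    RiskProfile,
    SignatureModel,
    TUMOR,
)

log = logging.getLogger("ferropair")

DAYS_PER_YEAR = 365.25


@dataclass
class PipelineParams:
    """All config-exposed thresholds of the selection cascade."""

    r_min: float = 0.4
    p_max_coexpr: float = 0.001
    absolute_r: bool = False
    coexpr_samples: str = "all"
    fdr_max: float = 0.05
    lfc_min: float = 1.5
    freq_low: float = 0.20
    freq_high: float = 0.80
    p_max_univariate: float = 0.05
    lasso_folds: int = 10
    lasso_rule: str = "min"
    stepwise: bool = True
    roc_years: tuple = (1, 3, 5)
    cutoff_year: int = 5
    seed: int = 0


@dataclass
class PipelineResult:
    """Everything the cascade produced; ``model`` is None when no pair
    survives selection (the empty-model path)."""

    coexpression: CoexpressionResult | None = None
    differential: DifferentialResult | None = None
    frlnc_ids: list = field(default_factory=list)
    defrlnc_ids: list = field(default_factory=list)
    pair_matrix: PairIndicatorMatrix | None = None
    filtered_pairs: PairIndicatorMatrix | None = None
    univariate: sig.UnivariateCoxResult | None = None
    lasso_candidates: list = field(default_factory=list)
    model: SignatureModel | None = None
    scores: pd.Series | None = None
    roc: dict = field(default_factory=dict)
    cutoff: float | None = None
    aic_profile: pd.DataFrame | None = None
    profile: RiskProfile | None = None
    logrank: tuple | None = None
    stopped_at: str | None = None  # set when the cascade ended early

    @property
    def counts(self) -> dict:
        return {
            "n_frlncrna": len(self.frlnc_ids),
            "n_defrlncrna": len(self.defrlnc_ids),
            "n_pairs": 0 if self.pair_matrix is None else len(self.pair_matrix.pair_ids),
            "n_pairs_filtered": 0 if self.filtered_pairs is None
            else len(self.filtered_pairs.pair_ids),
            "n_univariate_significant": 0 if self.univariate is None
            else len(self.univariate.retained_ids),
            "n_lasso_candidates": len(self.lasso_candidates),
            "n_signature_pairs": 0 if self.model is None else len(self.model),
        }


def run_pipeline(
    expr: ExpressionMatrix,
    annotation: GeneAnnotation,
    frg: GeneSet,
    clinical: ClinicalTable,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full cascade on a cohort.

    Screens lncRNAs by FRG coexpression, keeps the tumor/normal DE subset,
    encodes and frequency-filters all pairs, then selects a signature with
    univariate Cox -> LASSO-Cox -> stepwise multivariate Cox, scores tumor
    samples and dichotomizes at the AIC-minimizing cutoff on the
    ``cutoff_year`` ROC. Ends early (with ``stopped_at`` set) when a stage
    leaves nothing to select from.
    """
    p = params or PipelineParams()
    res = PipelineResult()

    lnc_ids = [g for g in annotation.genes_with_biotype("lncRNA") if g in expr.gene_ids]
    frg_ids = [g for g in sorted(frg.members) if g in expr.gene_ids and g not in lnc_ids]
    if not lnc_ids or not frg_ids:
        raise ValueError("no lncRNAs or no FRGs present in the expression matrix")

    res.coexpression = pearson_screen(
        expr, lnc_ids, frg_ids, r_min=p.r_min, p_max=p.p_max_coexpr,
        absolute_r=p.absolute_r, samples=p.coexpr_samples,
    )
    res.frlnc_ids = res.coexpression.frlnc_ids
    if not res.frlnc_ids:
        res.stopped_at = "coexpression"
        return res

    res.differential = differential_expression(
        expr, res.frlnc_ids, fdr_max=p.fdr_max, lfc_min=p.lfc_min
    )
    res.defrlnc_ids = res.differential.de_ids
    if len(res.defrlnc_ids) < 2:
        res.stopped_at = "differential_expression"
        return res

    res.pair_matrix = build_pair_matrix(expr, res.defrlnc_ids)
    res.filtered_pairs = filter_pairs(res.pair_matrix, p.freq_low, p.freq_high)
    if len(res.filtered_pairs.pair_ids) == 0:
        res.stopped_at = "pair_filter"
        return res

    tumor_ids = [s for s in expr.samples_of(TUMOR) if s in clinical.sample_ids]
    surv = clinical.subset(tumor_ids).survival
    pm_tumor = res.filtered_pairs.subset_samples(tumor_ids)

    res.univariate = univ = sig.univariate_cox_screen(pm_tumor, surv, p.p_max_univariate)
    retained = univ.retained_ids
    if not retained:
        res.stopped_at = "univariate_cox"
        return res

    if len(retained) >= 2:
        res.lasso_candidates = sig.lasso_cox_select(
            pm_tumor.subset_pairs(retained), surv,
            n_folds=p.lasso_folds, seed=p.seed, rule=p.lasso_rule,
        )
    else:
        res.lasso_candidates = list(retained)
    if not res.lasso_candidates:
        res.stopped_at = "lasso"
        return res

    try:
        res.model = sig.multivariate_cox_fit(
            pm_tumor, surv, candidates=res.lasso_candidates, stepwise=p.stepwise
        )
    except EmptySignatureError:
        res.stopped_at = "stepwise"
        return res

    res.scores = sig.risk_score(res.model, pm_tumor)
    for y in p.roc_years:
        horizon = y * DAYS_PER_YEAR
        try:
            res.roc[y] = sig.time_dependent_roc(res.scores, surv, horizon)
        except ValueError as exc:
            log.warning("ROC at %d years unavailable: %s", y, exc)
    res.cutoff, res.aic_profile = sig.choose_cutoff(
        res.scores, surv, roc=res.roc.get(p.cutoff_year)
    )
    res.profile = sig.assign_groups(res.scores, res.cutoff)
    groups = res.profile.group
    if groups.nunique() == 2:
        res.logrank = logrank_test(surv, groups)
    return res


def apply_model(
    model: SignatureModel, expr: ExpressionMatrix, cutoff: float | None = None
) -> tuple[pd.Series, RiskProfile | None]:
    """Score a new cohort with a frozen signature.

    Pair indicators are re-derived from raw expression — no normalization is
    needed, because the encoding only uses within-sample gene orderings.
    Returns the scores, and a risk profile when a cutoff is supplied.
    """
    genes = sorted({g for pid in model.pairs for g in pid.split("|")})
    missing = [g for g in genes if g not in expr.gene_ids]
    if missing:
        raise KeyError(f"signature genes absent from the new cohort: {missing}")
    pm = build_pair_matrix(expr, genes).subset_pairs(model.pairs)
    scores = sig.risk_score(model, pm)
    profile = sig.assign_groups(scores, cutoff) if cutoff is not None else None
    return scores, profile
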