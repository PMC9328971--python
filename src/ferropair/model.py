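"""Prognostic-signature selection and risk scoring.

The selection cascade mirrors the standard survival-signature recipe:
a univariate Cox screen over all candidate pair indicators, L1-penalized
(LASSO) Cox with a cross-validated penalty to prune the survivors, and a
backward-forward stepwise multivariate Cox fit minimizing AIC to fix the
final pair set. The risk score of a sample is the Cox linear predictor
sum_i beta_i * indicator_i; because indicators only encode within-sample
orderings, the score is invariant to any strictly increasing per-sample
transform of expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .cox import (
    cox_fit_multi,
    cox_fit_single,
    cox_loglik_breslow,
    cox_loglik_single,
    km_eval,
    km_step,
)
from .types import (
    EmptySignatureError,
    PairIndicatorMatrix,
    RiskProfile,
    SignatureModel,
    SurvivalData,
)

log = logging.getLogger("ferropair")

DAYS_PER_YEAR = 365.25


@dataclass
class UnivariateCoxResult:
    """Per-pair single-covariate Cox fits with the retention decision."""

    table: pd.DataFrame  # index pair_id; columns beta, hr, se, z, p, retained
    p_max: float

    @property
    def retained_ids(self) -> list[str]:
        return self.table.index[self.table["retained"]].tolist()


def univariate_cox_screen(
    pm: PairIndicatorMatrix, surv: SurvivalData, p_max: float = 0.05
) -> UnivariateCoxResult:
    """One single-covariate Cox PH fit (Efron ties) per pair indicator.

    A pair is retained when its Wald p-value is below ``p_max``. Pairs whose
    indicator is constant over the modeled samples cannot be fit and are
    skipped with a warning (they cannot occur after the frequency filter on
    the same cohort).
    """
    ind = pm.subset_samples(list(surv.sample_ids)).indicators
    if surv.n_events == 0:
        raise ValueError("no events in the survival data")
    if surv.n_events < 10:
        log.warning("only %d events; univariate screen is unstable", surv.n_events)

    rows = {}
    X = ind.to_numpy(dtype=float)
    for i, pid in enumerate(ind.index):
        x = X[i]
        if np.ptp(x) == 0:
            log.warning("pair %s has a constant indicator; skipped", pid)
            continue
        fit = cox_fit_single(x, surv.time, surv.event)
        rows[pid] = (fit.beta, fit.hr, fit.se, fit.z, fit.p)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["beta", "hr", "se", "z", "p"]
    )
    table.index.name = "pair_id"
    table["retained"] = table["p"] < p_max
    return UnivariateCoxResult(table, p_max)


def lasso_cox_select(
    pm: PairIndicatorMatrix,
    surv: SurvivalData,
    n_folds: int = 10,
    seed: int = 0,
    rule: str = "min",
    lambda_override: float | None = None,
) -> list[str]:
    """LASSO-Cox selection of candidate pairs.

    Fits the L1-penalized Cox path over the pair indicators and picks the
    penalty by K-fold cross-validated partial-likelihood deviance
    (Verweij-van Houwelingen form, Breslow ties to match the coxnet
    objective): lambda_min with ``rule="min"``, the one-standard-error
    lambda with ``rule="1se"``. Pairs with a nonzero coefficient at the
    chosen penalty are returned. ``lambda_override=0`` is the unpenalized
    limit and returns every input pair.
    """
    ind = pm.subset_samples(list(surv.sample_ids)).indicators
    pair_ids = ind.index.tolist()
    if len(pair_ids) < 2:
        raise ValueError("need >= 2 candidate pairs for LASSO selection")
    X = ind.to_numpy(dtype=float).T  # samples x pairs
    if np.unique(X, axis=1).shape[1] == 1:
        raise ValueError("degenerate design: all pair indicators are identical")
    if lambda_override is not None and lambda_override == 0:
        return pair_ids

    y = Surv.from_arrays(event=surv.event.astype(bool), time=surv.time)
    if lambda_override is not None:
        net = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[lambda_override])
        net.fit(X, y)
        coef = net.coef_[:, 0]
        return [p for p, c in zip(pair_ids, coef) if c != 0.0]

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=100)
    path.fit(X, y)
    alphas = path.alphas_

    n_folds = min(n_folds, surv.n_events)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    n_alphas = len(alphas)
    fold_scores = np.zeros((n_folds, n_alphas))
    for k, (train, _) in enumerate(kf.split(X)):
        net = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net.fit(X[train], y[train])
        fitted = {a: j for j, a in enumerate(net.alphas_)}
        for j, a in enumerate(alphas):
            beta = net.coef_[:, fitted[a]] if a in fitted else np.zeros(X.shape[1])
            ll_all = cox_loglik_breslow(X, surv.time, surv.event, beta)
            ll_train = cox_loglik_breslow(
                X[train], surv.time[train], surv.event[train], beta
            )
            fold_scores[k, j] = ll_all - ll_train  # held-out partial log-likelihood
    cv = fold_scores.sum(axis=0)
    j_min = int(np.argmax(cv))
    if rule == "1se":
        se = fold_scores.std(axis=0, ddof=1) * np.sqrt(n_folds)
        ok = cv >= cv[j_min] - se[j_min]
        j_sel = int(np.flatnonzero(ok)[0])  # alphas are descending: largest first
    elif rule == "min":
        j_sel = j_min
    else:
        raise ValueError("rule must be 'min' or '1se'")
    coef = path.coef_[:, j_sel]
    selected = [p for p, c in zip(pair_ids, coef) if c != 0.0]
    log.info(
        "LASSO: lambda=%.5g (%s rule) keeps %d of %d pairs",
        alphas[j_sel], rule, len(selected), len(pair_ids),
    )
    return selected


def multivariate_cox_fit(
    pm: PairIndicatorMatrix,
    surv: SurvivalData,
    candidates: list[str] | None = None,
    stepwise: bool = True,
) -> SignatureModel:
    """Final multivariate Cox fit, by default with backward-forward stepwise
    elimination minimizing AIC = 2k - 2 logPL starting from the full model.

    Raises :class:`EmptySignatureError` when the empty model minimizes AIC
    (nothing prognostic among the candidates).
    """
    candidates = list(candidates) if candidates is not None else pm.pair_ids.tolist()
    if not candidates:
        raise EmptySignatureError("no candidate pairs to fit")
    ind = pm.subset_samples(list(surv.sample_ids)).indicators
    if surv.n_events <= len(candidates):
        log.warning(
            "events (%d) do not exceed candidate count (%d); fit may be unstable",
            surv.n_events, len(candidates),
        )
    X_all = ind.loc[candidates].to_numpy(dtype=float).T  # samples x candidates
    col_of = {p: i for i, p in enumerate(candidates)}
    ll_null = cox_loglik_single(
        np.arange(len(surv.time), dtype=float), surv.time, surv.event, 0.0
    )

    def fit_of(pairs: tuple[str, ...]):
        if not pairs:
            return -2.0 * ll_null, None
        try:
            fit = cox_fit_multi(
                X_all[:, [col_of[p] for p in pairs]], surv.time, surv.event
            )
        except (RuntimeError, np.linalg.LinAlgError):
            return np.inf, None
        return fit.aic, fit

    current = tuple(sorted(candidates))
    best_aic, best_fit = fit_of(current)
    if not np.isfinite(best_aic):
        raise RuntimeError("full multivariate Cox fit failed to converge")

    if stepwise:
        cache: dict[tuple[str, ...], float] = {current: best_aic}
        improved = True
        while improved:
            improved = False
            moves = [tuple(q for q in current if q != p) for p in current]
            moves += [
                tuple(sorted(current + (p,))) for p in candidates if p not in current
            ]
            for cand in moves:
                if cand not in cache:
                    cache[cand] = fit_of(cand)[0]
                if cache[cand] < best_aic - 1e-10:
                    best_aic, current = cache[cand], cand
                    improved = True
        if not current:
            raise EmptySignatureError("stepwise AIC eliminated every pair")
        best_aic, best_fit = fit_of(current)

    assert best_fit is not None
    return SignatureModel(
        pairs=list(current),
        coefficients=best_fit.beta,
        metadata={
            "n": len(surv),
            "events": surv.n_events,
            "aic": best_aic,
            "stepwise": stepwise,
            "n_candidates": len(candidates),
        },
    )


def risk_score(model: SignatureModel, pm: PairIndicatorMatrix) -> pd.Series:
    """Per-sample risk score: the Cox linear predictor over pair indicators."""
    missing = [p for p in model.pairs if p not in pm.pair_ids]
    if missing:
        raise KeyError(f"model pairs absent from the indicator matrix: {missing}")
    ind = pm.indicators.loc[model.pairs].to_numpy(dtype=float)
    scores = model.coefficients @ ind
    return pd.Series(scores, index=pm.sample_ids, name="score")


@dataclass
class TimeDependentROC:
    """Cumulative-case / dynamic-control ROC at a fixed horizon."""

    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    aic_profile: pd.DataFrame | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def time_dependent_roc(
    scores: pd.Series, surv: SurvivalData, horizon: float
) -> TimeDependentROC:
    """Time-dependent ROC for right-censored outcomes at ``horizon``.

    Cases are subjects with an observed event by the horizon, controls those
    still at risk past it; both are weighted by inverse probabilities from
    the Kaplan-Meier estimate of the censoring distribution, so sensitivity
    and specificity are monotone along the threshold sweep and the AUC
    (trapezoidal) reduces exactly to the binary AUC when no censoring occurs
    before the horizon. Subjects censored before the horizon contribute to
    neither class (their status is unknown).
    """
    s = scores.loc[list(surv.sample_ids)].to_numpy(dtype=float)
    t, e = surv.time, surv.event
    if horizon <= 0 or horizon > t.max():
        raise ValueError("horizon must lie within the follow-up range")
    case = (t <= horizon) & (e == 1)
    control = t > horizon
    if case.sum() == 0:
        raise ValueError("no events before the horizon")

    # KM of the censoring distribution; G(t-) weights cases, G(horizon) controls
    g_times, g_surv = km_step(t, 1 - e)
    g_case = km_eval(g_times, g_surv, t[case], left=True)
    g_ctrl = km_eval(g_times, g_surv, np.array([horizon]))[0]
    floor = max(min(g_surv.min(initial=1.0), g_ctrl) , 1e-12)
    w_case = 1.0 / np.clip(g_case, floor, None)
    w_ctrl = np.full(int(control.sum()), 1.0 / max(g_ctrl, floor))

    uniq = np.unique(s)[::-1]
    thresholds = np.concatenate(([np.inf], uniq, [-np.inf]))
    sc, wc = s[case], w_case
    sk, wk = s[control], w_ctrl
    sens = np.array([np.sum(wc[sc > c]) for c in thresholds]) / wc.sum()
    spec = np.array([np.sum(wk[sk <= c]) for c in thresholds]) / wk.sum()
    auc = float(np.trapezoid(sens, 1.0 - spec))
    return TimeDependentROC(horizon, thresholds, sens, spec, auc)


def roc_at_years(
    scores: pd.Series, surv: SurvivalData, years=(1, 3, 5)
) -> dict[int, TimeDependentROC]:
    """Convenience: ROC at 1/3/5-year horizons expressed in days."""
    return {y: time_dependent_roc(scores, surv, y * DAYS_PER_YEAR) for y in years}


def choose_cutoff(
    scores: pd.Series,
    surv: SurvivalData,
    roc: TimeDependentROC | None = None,
) -> tuple[float, pd.DataFrame]:
    """Risk-score dichotomization threshold minimizing Cox-model AIC.

    Every midpoint between consecutive sorted unique scores is a candidate;
    for each, a one-covariate Cox model on the binary high/low split is fit
    and its AIC = 2 - 2 logPL recorded. For splits with a monotone partial
    likelihood (perfect separation, where the MLE does not exist but the
    likelihood has a finite supremum) the AIC is evaluated at that supremum.
    The AIC-minimizing threshold is returned (ties resolved to the
    smallest), together with the full AIC-vs-threshold profile; when a ROC
    object is passed, the profile is attached to it.
    """
    s = scores.loc[list(surv.sample_ids)].to_numpy(dtype=float)
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("all scores identical; no cutoff exists")
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    aics = np.empty(len(cands))
    for i, c in enumerate(cands):
        fit = cox_fit_single((s > c).astype(float), surv.time, surv.event)
        aics[i] = fit.aic
    profile = pd.DataFrame({"threshold": cands, "aic": aics})
    cutoff = float(cands[int(np.argmin(aics))])  # first minimum = smallest c
    if roc is not None:
        roc.aic_profile = profile
    return cutoff, profile


def assign_groups(scores: pd.Series, cutoff: float) -> RiskProfile:
    """High-risk iff score > cutoff; scores equal to the cutoff are low."""
    return RiskProfile(scores=scores.astype(float), cutoff=float(cutoff))
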