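"""Validation of a fitted signature: survival curves and tests, clinical
associations, independence Cox models, decision-curve analysis, a nomogram,
and risk-group gene-panel comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .cox import breslow_baseline, cox_fit_single, km_eval, km_step
from .screening import bh_adjust
from .types import (
    CLINICAL_COVARIATES,
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    RiskProfile,
    SurvivalData,
    UNKNOWN,
)

log = logging.getLogger("ferropair")


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(surv: SurvivalData, groups: pd.Series) -> dict[str, KMCurve]:
    """Kaplan-Meier curve per group (right censoring; ties: events first)."""
    groups = groups.loc[list(surv.sample_ids)]
    out = {}
    for label in pd.unique(groups):
        mask = (groups == label).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {label!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[mask], surv.event[mask])
        times = kmf.survival_function_.index.to_numpy()
        s = kmf.survival_function_["KM_estimate"].to_numpy()
        keep = times > 0
        at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy()
        out[str(label)] = KMCurve(times[keep], s[keep], at_risk[keep], str(label))
    return out


def logrank_test(surv: SurvivalData, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-squared statistic, p), 1 df."""
    groups = groups.loc[list(surv.sample_ids)]
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    m = (groups == labels[0]).to_numpy()
    res = _ll_logrank(surv.time[m], surv.time[~m], surv.event[m], surv.event[~m])
    return float(res.test_statistic), float(res.p_value)


def clinical_association(
    profile: RiskProfile, clinical: ClinicalTable, age_split: float = 65.0
) -> pd.DataFrame:
    """Association between the risk signature and clinical features.

    Per feature: a chi-squared test (no Yates correction) of the high/low
    group against the feature's categories, and a two-sided rank-sum of the
    risk score across binary strata (Kruskal-Wallis for multi-level).
    Unknown categories are excluded per feature; age is dichotomized at
    ``age_split`` years. Survival status (event) is included as a feature.
    Features left with one category are skipped with a warning.
    """
    shared = clinical.sample_ids.intersection(profile.sample_ids)
    if len(shared) < 10:
        raise ValueError("need >= 10 shared samples")
    data = clinical.data.loc[shared].copy()
    group = profile.group.loc[shared]
    score = profile.scores.loc[shared]

    feats: dict[str, pd.Series] = {}
    if "age" in data.columns:
        feats["age"] = pd.Series(
            np.where(data["age"].astype(float) <= age_split,
                     f"<={age_split:g}", f">{age_split:g}"),
            index=shared,
        )
    for col in CLINICAL_COVARIATES[1:]:
        if col in data.columns:
            feats[col] = data[col].astype(str)
    feats["survival_status"] = data["event"].map({0: "alive", 1: "dead"})

    rows = []
    for name, values in feats.items():
        known = values != UNKNOWN
        v = values[known]
        cats = pd.unique(v)
        if len(cats) < 2:
            log.warning("feature %s has one category after unknown-removal; skipped", name)
            continue
        table = pd.crosstab(group[known], v)
        chi2, chi_p, _, expected = stats.chi2_contingency(table, correction=False)
        if (expected < 1).any():
            log.warning("feature %s: expected counts < 1 in the chi-squared table", name)
        rows.append((name, "chi2", float(chi2), float(chi_p)))
        strata = [score[known][v == c].to_numpy() for c in cats]
        if len(cats) == 2:
            stat, p = stats.mannwhitneyu(strata[0], strata[1], alternative="two-sided")
            rows.append((name, "ranksum", float(stat), float(p)))
        else:
            stat, p = stats.kruskal(*strata)
            rows.append((name, "kruskal", float(stat), float(p)))
    return pd.DataFrame(rows, columns=["feature", "test", "statistic", "p"])


@dataclass
class IndependenceCoxResult:
    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    collinear: bool = False


def clinical_design(
    profile: RiskProfile, clinical: ClinicalTable, min_level_count: int = 5
) -> pd.DataFrame:
    """Public alias for the numeric score+clinical design matrix used by the
    independence Cox models and the nomogram."""
    return _design(profile, clinical, min_level_count)


def _design(
    profile: RiskProfile, clinical: ClinicalTable, min_level_count: int = 5
) -> pd.DataFrame:
    """Numeric design matrix: continuous score and age, dummy-coded
    categoricals (reference = first observed level; unknown rows carry 0 on
    every dummy, i.e. pool with the reference). Levels observed fewer than
    ``min_level_count`` times are pooled with the reference as well — a
    near-empty level makes the partial likelihood unidentifiable."""
    shared = clinical.sample_ids.intersection(profile.sample_ids)
    data = clinical.data.loc[shared]
    X = pd.DataFrame(index=shared)
    X["score"] = profile.scores.loc[shared].astype(float)
    if "age" in data.columns:
        X["age"] = data["age"].astype(float)
    for col in CLINICAL_COVARIATES[1:]:
        if col not in data.columns:
            continue
        v = data[col].astype(str)
        counts = v.value_counts()
        levels = sorted(set(v) - {UNKNOWN})
        if len(levels) < 2:
            log.warning("covariate %s has < 2 known levels; dropped", col)
            continue
        for lev in levels[1:]:
            if counts.get(lev, 0) < min_level_count:
                log.warning(
                    "covariate %s level %s has %d samples; pooled with reference",
                    col, lev, counts.get(lev, 0),
                )
                continue
            X[f"{col}[{lev}]"] = (v == lev).astype(float)
    return X


def independence_cox(
    profile: RiskProfile, clinical: ClinicalTable
) -> IndependenceCoxResult:
    """Univariate and multivariate Cox models testing whether the risk score
    is prognostic independently of the clinical covariates.

    The score enters continuously alongside age (continuous) and the
    dummy-coded categorical covariates. Returns HR with 95% CI and p per
    term for both analyses; a rank-deficient multivariate design is flagged
    as collinear.
    """
    X = _design(profile, clinical)
    surv = clinical.subset(list(X.index)).survival
    if surv.n_events <= X.shape[1]:
        log.warning(
            "events (%d) do not exceed covariates (%d)", surv.n_events, X.shape[1]
        )

    def fit(cols: list[str]) -> pd.DataFrame:
        df = X[cols].copy()
        df["time"] = surv.time
        df["event"] = surv.event
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="event")
            except Exception:
                # separation or near-singular design: stabilize with a
                # light ridge penalty
                log.warning("Cox fit on %s unstable; refitting with ridge", cols)
                cph = CoxPHFitter(penalizer=0.1, l1_ratio=0.0)
                cph.fit(df, duration_col="time", event_col="event")
        s = cph.summary
        return pd.DataFrame(
            {
                "covariate": s.index,
                "hr": s["exp(coef)"].to_numpy(),
                "ci_low": s["exp(coef) lower 95%"].to_numpy(),
                "ci_high": s["exp(coef) upper 95%"].to_numpy(),
                "p": s["p"].to_numpy(),
            }
        )

    blocks: dict[str, list[str]] = {}
    for c in X.columns:
        blocks.setdefault(c.split("[")[0], []).append(c)
    uni = pd.concat(
        [fit(cols).assign(feature=feat) for feat, cols in blocks.items()],
        ignore_index=True,
    )

    collinear = np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]
    cols = list(X.columns)
    if collinear:
        log.warning("multivariate design is rank-deficient (collinear covariates)")
        # keep a maximal independent prefix so the joint model is estimable
        kept: list[str] = []
        for c in cols:
            trial = kept + [c]
            if np.linalg.matrix_rank(X[trial].to_numpy()) == len(trial):
                kept.append(c)
            else:
                log.warning("dropping collinear covariate %s from the joint model", c)
        cols = kept
    multi = fit(cols).assign(feature=[c.split("[")[0] for c in cols])
    return IndependenceCoxResult(uni, multi, collinear)


def decision_curve(
    scores: pd.Series,
    surv: SurvivalData,
    horizon: float,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Decision-curve analysis of the risk score at a survival horizon.

    Predicted event risk by the horizon comes from a one-covariate Cox fit
    on the score (Breslow baseline): risk_i = 1 - S0(t)^exp(beta*score_i).
    Net benefit at threshold probability p_t is TP/n - FP/n * p_t/(1-p_t),
    with the event fraction among treated subjects estimated by the group
    Kaplan-Meier at the horizon (handles censoring). Treat-all and
    treat-none reference curves are included; treat-none is identically 0.
    """
    if grid is None:
        grid = np.arange(0.01, 1.0, 0.01)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if horizon <= 0 or horizon > surv.time.max():
        raise ValueError("horizon must lie within the follow-up range")

    s = scores.loc[list(surv.sample_ids)].to_numpy(dtype=float)
    fit = cox_fit_single(s, surv.time, surv.event)
    risk = _cox_risk_at_horizon(fit.beta * s, surv.time, surv.event, horizon)

    n = len(s)

    def net_benefit(treated: np.ndarray, p_t: float) -> float:
        m = int(treated.sum())
        if m == 0:
            return 0.0
        g_t, g_s = km_step(surv.time[treated], surv.event[treated])
        s_at = km_eval(g_t, g_s, np.array([horizon]))[0]
        event_frac = 1.0 - s_at
        tp = event_frac * m / n
        fp = (1.0 - event_frac) * m / n
        return tp - fp * p_t / (1.0 - p_t)

    nb_model = np.array([net_benefit(risk >= p, p) for p in grid])
    all_mask = np.ones(n, dtype=bool)
    nb_all = np.array([net_benefit(all_mask, p) for p in grid])
    return pd.DataFrame(
        {"p_t": grid, "nb_model": nb_model, "nb_all": nb_all, "nb_none": 0.0}
    )


def _cox_risk_at_horizon(eta, time, event, horizon) -> np.ndarray:
    """Per-subject predicted event probability by ``horizon`` under a fitted
    Cox linear predictor ``eta``: 1 - S0(t)^exp(eta), with the Breslow
    baseline evaluated entirely in log space (stable under extreme eta,
    e.g. separated fits)."""
    eta = np.asarray(eta, dtype=float)
    order = np.argsort(time, kind="stable")
    t_s, e_s, eta_s = np.asarray(time)[order], np.asarray(event)[order], eta[order]
    # log of risk-set sums: logsumexp of eta over subjects with time >= t
    rev = eta_s[::-1]
    log_rs = np.logaddexp.accumulate(rev)[::-1]
    terms = []  # log(d_j) - log(sum_{risk set} e^eta) per event time <= horizon
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        if t_s[i] > horizon:
            break
        d = int(e_s[i:j].sum())
        if d:
            terms.append(np.log(d) - log_rs[i])
        i = j
    if not terms:
        return np.zeros_like(eta)
    from scipy.special import logsumexp

    log_h0 = logsumexp(terms)
    log_h = log_h0 + eta  # per-subject log cumulative hazard at the horizon
    with np.errstate(over="ignore"):
        return -np.expm1(-np.exp(log_h))


@dataclass
class Nomogram:
    """Point-scale representation of a multivariate Cox fit.

    Per-covariate points are linear in beta * (value - reference), scaled so
    the covariate with the widest contribution spans 100 points; predicted
    survival at a horizon is S0(t)^exp(lp) with the Breslow baseline.
    """

    betas: pd.Series
    reference: pd.Series  # observed value minimizing beta*x per covariate
    scale: float  # points per unit of linear predictor
    baseline_times: np.ndarray = field(repr=False)
    baseline_cumhaz: np.ndarray = field(repr=False)
    horizons: tuple = ()

    def linear_predictor(self, profile: pd.Series) -> float:
        return float(sum(self.betas[c] * profile[c] for c in self.betas.index))

    def points(self, profile: pd.Series) -> pd.Series:
        pts = {
            c: self.scale * self.betas[c] * (profile[c] - self.reference[c])
            for c in self.betas.index
        }
        return pd.Series(pts)

    def predict_survival(self, profile: pd.Series, horizon: float) -> float:
        if (self.baseline_times > horizon).all() and horizon < self.baseline_times[0]:
            h0 = 0.0
        elif horizon > self.baseline_times[-1]:
            log.warning("horizon %.0f beyond the last event time", horizon)
            raise ValueError("extrapolation beyond follow-up refused")
        else:
            idx = np.searchsorted(self.baseline_times, horizon, side="right") - 1
            h0 = self.baseline_cumhaz[idx] if idx >= 0 else 0.0
        return float(np.exp(-h0 * np.exp(self.linear_predictor(profile))))


def build_nomogram(
    X: pd.DataFrame, surv: SurvivalData, horizons=(365.25, 3 * 365.25, 5 * 365.25)
) -> Nomogram:
    """Fit a multivariate Cox model on the numeric design ``X`` and express
    it as a nomogram with a 0-100 point scale and Breslow baseline survival
    at the requested horizons."""
    df = X.copy().astype(float)
    df["time"] = surv.time
    df["event"] = surv.event
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    betas = cph.params_
    last_event = surv.time[surv.event == 1].max()
    for h in horizons:
        if h > last_event:
            log.warning("horizon %.0f is beyond the last event time %.0f", h, last_event)
    contrib = X.astype(float).mul(betas, axis=1)
    reference = pd.Series(
        {c: X[c].to_numpy()[np.argmin(contrib[c].to_numpy())] for c in X.columns}
    )
    spans = contrib.max() - contrib.min()
    max_span = float(spans.max())
    if max_span <= 0:
        raise ValueError("all covariates are constant; nomogram undefined")
    eta = (X.astype(float) @ betas).to_numpy()
    times, h0 = breslow_baseline(surv.time, surv.event, eta)
    return Nomogram(
        betas=betas,
        reference=reference,
        scale=100.0 / max_span,
        baseline_times=times,
        baseline_cumhaz=h0,
        horizons=tuple(horizons),
    )


def panel_group_compare(
    expr: ExpressionMatrix, panel: GeneSet, profile: RiskProfile
) -> pd.DataFrame:
    """Two-sided rank-sum per panel gene between high- and low-risk groups,
    BH-adjusted across the panel. Panel genes absent from the expression
    matrix are reported with NaN statistics."""
    shared = expr.sample_ids.intersection(profile.sample_ids)
    group = profile.group.loc[shared]
    hi = shared[group == "high"]
    lo = shared[group == "low"]
    if len(hi) < 3 or len(lo) < 3:
        raise ValueError("need >= 3 samples per risk group")

    present = [g for g in panel if g in expr.gene_ids]
    missing = [g for g in panel if g not in expr.gene_ids]
    if missing:
        log.warning("panel %s: %d genes absent from expression", panel.name, len(missing))
    rows = []
    for g in present:
        a = expr.values.loc[g, hi].to_numpy(dtype=float)
        b = expr.values.loc[g, lo].to_numpy(dtype=float)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        direction = "up" if np.median(a) > np.median(b) else (
            "down" if np.median(a) < np.median(b) else "none"
        )
        rows.append((g, p, direction, True))
    out = pd.DataFrame(rows, columns=["gene", "p", "direction", "present"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    for g in missing:
        out.loc[len(out)] = (g, np.nan, "none", False, np.nan)
    return out[["gene", "p", "q", "direction", "present"]]
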