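"""Synthetic tumor/normal cohorts with the structure the pipeline assumes.

The generator plants exactly the three kinds of signal the analysis looks
for: (i) lncRNAs linearly coexpressed with ferroptosis-related mRNAs at a
target Pearson correlation, (ii) lncRNAs shifted in tumor samples by a
fixed log2 fold change, and (iii) survival times for tumor samples drawn
from an exponential proportional-hazards model whose linear predictor is a
sum of planted pair indicators, with independent exponential censoring
calibrated to a target censoring fraction.

Expression is exp2 of a Gaussian model on the log2 scale; there are no
shared library-size or batch effects, so genes that are not tied to an FRG
are independent of every FRG (a clean null for the coexpression screen).
Members of a planted pair share their baseline mean, which centres the
pair's indicator frequency near 1/2 — inside the 20-80% band the frequency
filter keeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ClinicalTable,
    ExpressionMatrix,
    GeneAnnotation,
    GeneSet,
    NORMAL,
    TUMOR,
)

DAYS_PER_YEAR = 365.25

#: categorical distributions for the clinical covariates, following the
#: published HNSCC cohort composition (counts over 497 patients)
_CLINICAL_CATEGORIES = {
    "gender": (("female", "male"), (133, 364)),
    "grade": (("G1", "G2", "G3", "G4", "unknown"), (61, 297, 118, 2, 19)),
    "stage": (("I", "II", "III", "IV", "unknown"), (25, 69, 78, 258, 67)),
    "T": (("T1", "T2", "T3", "T4", "unknown"), (45, 131, 96, 170, 55)),
    "M": (("M0", "M1", "unknown"), (183, 1, 313)),
    "N": (("N0", "N1", "N2", "N3", "unknown"), (168, 65, 164, 7, 93)),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults are the desk-scale study conditions used throughout the test
    suite: a 300-tumor / 30-normal cohort, 300 lncRNAs of which 30% are
    coexpressed with an FRG at r ~ 0.75 and 15% carry a 2-unit log2 shift
    in tumor, and an exponential survival model with a 6-year baseline
    median (so follow-up spans the 5-year evaluation horizon even under the
    planted hazards) and ~30% censoring. ``planted_pairs`` lists
    (gene_a, gene_b, beta) triples; beta is the log hazard ratio of the
    within-sample indicator expression(gene_a) >= expression(gene_b).
    """

    n_tumor: int = 300
    n_normal: int = 30
    n_lnc: int = 300
    n_mrna: int = 200
    n_frg: int = 50
    coexpressed_fraction: float = 0.30
    target_r: float = 0.75
    de_fraction: float = 0.15
    de_log2fc: float = 2.0
    planted_pairs: list = field(default_factory=list)
    baseline_hazard: float = np.log(2) / (6 * DAYS_PER_YEAR)  # per day
    censoring_rate: float = 0.30
    seed: int = 0
    # log2-scale distributional knobs (rarely worth touching)
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_lnc", "n_mrna", "n_frg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_frg > self.n_mrna:
            raise ValueError("n_frg cannot exceed n_mrna")
        for name in ("coexpressed_fraction", "de_fraction", "censoring_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.target_r < 1.0:
            raise ValueError("target_r must lie in (0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth of the planted structure, for recovery experiments."""

    coexpressed_partner: dict  # lncRNA id -> FRG id
    de_ids: list
    planted_pairs: list  # (gene_a, gene_b, beta)
    linear_predictor: pd.Series  # per tumor sample
    censoring_hazard: float


@dataclass
class SimulatedCohort:
    expression: ExpressionMatrix
    annotation: GeneAnnotation
    frg_set: GeneSet
    clinical: ClinicalTable
    truth: SimulationTruth
    config: SimulationConfig

    def __iter__(self):
        """Unpack as the (expression, annotation, frg_set, clinical) tuple."""
        return iter((self.expression, self.annotation, self.frg_set, self.clinical))


def _stream(seed: int, stage: int) -> np.random.Generator:
    """Independent, deterministic sub-stream per simulation stage, so adding
    a stage never perturbs draws of earlier ones."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort with the configured planted structure.

    Fixed seed implies bit-identical output. Normal samples carry no
    survival data; the clinical table covers tumor samples only.
    """
    cfg = config
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(cfg.n_lnc)]
    mrna_ids = [f"MRNA{i + 1:04d}" for i in range(cfg.n_mrna)]
    frg_ids = mrna_ids[: cfg.n_frg]
    tumor_ids = [f"TUM{i + 1:04d}" for i in range(cfg.n_tumor)]
    normal_ids = [f"NRM{i + 1:04d}" for i in range(cfg.n_normal)]
    samples = tumor_ids + normal_ids
    n_samples = len(samples)

    all_genes = set(lnc_ids) | set(mrna_ids)
    for a, b, _ in cfg.planted_pairs:
        for g in (a, b):
            if g not in all_genes:
                raise KeyError(f"planted pair references unknown gene {g!r}")

    # stage 0: gene baselines on the log2 scale
    rng = _stream(cfg.seed, 0)
    mu_lnc = cfg.baseline_mean + cfg.baseline_sd * rng.standard_normal(cfg.n_lnc)
    mu_mrna = cfg.baseline_mean + cfg.baseline_sd * rng.standard_normal(cfg.n_mrna)
    mu = dict(zip(lnc_ids, mu_lnc)) | dict(zip(mrna_ids, mu_mrna))
    # planted pair members share a baseline so the pair stays frequency-informative
    for a, b, _ in cfg.planted_pairs:
        mu[b] = mu[a]

    # stage 1: mRNA log2 expression
    rng = _stream(cfg.seed, 1)
    u_mrna = rng.standard_normal((cfg.n_mrna, n_samples))
    log_mrna = np.array([mu[g] for g in mrna_ids])[:, None] + cfg.noise_sd * u_mrna

    # stage 2: lncRNA log2 expression, first block tied to FRGs
    rng = _stream(cfg.seed, 2)
    v_lnc = rng.standard_normal((cfg.n_lnc, n_samples))
    n_coex = int(round(cfg.coexpressed_fraction * cfg.n_lnc))
    r = cfg.target_r
    coexpressed_partner: dict[str, str] = {}
    z = v_lnc.copy()
    for i in range(n_coex):
        f_idx = i % cfg.n_frg
        coexpressed_partner[lnc_ids[i]] = frg_ids[f_idx]
        z[i] = r * u_mrna[f_idx] + np.sqrt(1.0 - r * r) * v_lnc[i]
    log_lnc = np.array([mu[g] for g in lnc_ids])[:, None] + cfg.noise_sd * z

    # stage 3: tumor shift for the DE block
    n_de = int(round(cfg.de_fraction * cfg.n_lnc))
    de_ids = lnc_ids[:n_de]
    log_lnc[:n_de, : cfg.n_tumor] += cfg.de_log2fc

    values = pd.DataFrame(
        np.exp2(np.vstack([log_lnc, log_mrna])),
        index=pd.Index(lnc_ids + mrna_ids, name="gene_id"),
        columns=pd.Index(samples, name="sample_id"),
    )
    condition = pd.Series(
        [TUMOR] * cfg.n_tumor + [NORMAL] * cfg.n_normal, index=values.columns
    )
    expression = ExpressionMatrix(values, condition)

    annotation = GeneAnnotation(
        biotype=pd.Series(
            ["lncRNA"] * cfg.n_lnc + ["protein_coding"] * cfg.n_mrna,
            index=pd.Index(lnc_ids + mrna_ids, name="gene_id"),
            name="biotype",
        )
    )
    frg_set = GeneSet.from_iterable("FRG", frg_ids)

    # stage 4: survival for tumor samples from the planted-pair hazards
    rng = _stream(cfg.seed, 4)
    lp = np.zeros(cfg.n_tumor)
    tum_values = values[tumor_ids]
    for a, b, beta in cfg.planted_pairs:
        ind = (tum_values.loc[a].to_numpy() >= tum_values.loc[b].to_numpy()).astype(float)
        lp += beta * ind
    hazards = cfg.baseline_hazard * np.exp(lp)
    event_times = rng.exponential(1.0 / hazards)
    if cfg.censoring_rate > 0:
        c_hazard = _calibrate_censoring(hazards, cfg.censoring_rate)
        censor_times = rng.exponential(1.0 / c_hazard, size=cfg.n_tumor)
    else:
        c_hazard = 0.0
        censor_times = np.full(cfg.n_tumor, np.inf)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)

    # stage 5: clinical covariates, independent of survival
    rng = _stream(cfg.seed, 5)
    clin = pd.DataFrame(index=pd.Index(tumor_ids, name="sample_id"))
    clin["time"] = time
    clin["event"] = event
    clin["age"] = np.clip(np.round(rng.normal(60.0, 12.0, cfg.n_tumor)), 20, 90).astype(int)
    for col, (levels, counts) in _CLINICAL_CATEGORIES.items():
        p = np.asarray(counts, dtype=float)
        clin[col] = rng.choice(levels, size=cfg.n_tumor, p=p / p.sum())

    truth = SimulationTruth(
        coexpressed_partner=coexpressed_partner,
        de_ids=list(de_ids),
        planted_pairs=list(cfg.planted_pairs),
        linear_predictor=pd.Series(lp, index=pd.Index(tumor_ids, name="sample_id")),
        censoring_hazard=float(c_hazard),
    )
    return SimulatedCohort(expression, annotation, frg_set, ClinicalTable(clin), truth, cfg)


def _calibrate_censoring(hazards: np.ndarray, rate: float) -> float:
    """Censoring hazard c with mean_i c / (c + lambda_i) = rate (bisection).

    With exponential event and censoring times, a subject with event hazard
    lambda is censored with probability c / (c + lambda).
    """
    lo, hi = 1e-12, float(hazards.max()) * 1e6

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards)))

    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def default_recovery_config(seed: int = 0, beta: float = 1.0) -> SimulationConfig:
    """The default parameter-recovery conditions used by the test suite:
    300 tumor / 30 normal samples, 300 lncRNAs, three planted pairs with
    log hazard ratio ``beta`` among the coexpressed+DE block."""
    return SimulationConfig(
        planted_pairs=[
            ("LNC0001", "LNC0002", beta),
            ("LNC0003", "LNC0004", beta),
            ("LNC0005", "LNC0006", beta),
        ],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Fixed worked toy: 8 genes x 10 samples, hand-checkable at every stage.
# ---------------------------------------------------------------------------

_TOY_SAMPLES = ["T01", "T02", "T03", "T04", "T05", "T06", "N01", "N02", "N03", "N04"]

#: linear-scale toy expression. LNC01 satisfies log2(LNC01+1) = log2(FRG1+1)+1
#: (exact r = 1 with FRG1 on the log scale); LNC03 equals FRG2 (r = 1);
#: LNC02 is deliberately unrelated to both FRGs; LNC04 is strongly tumor-up
#: (every tumor value exceeds every normal value).
_TOY_VALUES = {
    "LNC01": [3, 7, 15, 31, 63, 127, 15, 7, 3, 31],
    "LNC02": [10, 2, 50, 4, 30, 6, 20, 8, 40, 12],
    "LNC03": [63, 31, 15, 7, 3, 1, 15, 31, 63, 7],
    "LNC04": [40, 44, 48, 52, 56, 60, 2, 4, 6, 8],
    "FRG1": [1, 3, 7, 15, 31, 63, 7, 3, 1, 15],
    "FRG2": [63, 31, 15, 7, 3, 1, 15, 31, 63, 7],
    "MRNA1": [5, 10, 15, 20, 25, 30, 35, 40, 45, 50],
    "MRNA2": [9, 8, 7, 6, 5, 4, 3, 2, 1, 1],
}

_TOY_CLINICAL = {
    "time": [100.0, 200.0, 300.0, 400.0, 500.0, 600.0],
    "event": [1, 1, 1, 0, 1, 0],
    "age": [55, 70, 60, 65, 50, 75],
    "gender": ["female", "male", "female", "male", "male", "female"],
    "grade": ["G2", "G3", "G2", "G1", "G2", "unknown"],
    "stage": ["II", "III", "IV", "I", "IV", "III"],
    "T": ["T2", "T3", "T4", "T1", "T4", "T2"],
    "N": ["N0", "N1", "N2", "N0", "N2", "N1"],
    "M": ["M0", "M0", "unknown", "M0", "M1", "unknown"],
}


def worked_toy() -> SimulatedCohort:
    """A fixed 8-gene x 10-sample cohort with hand-computable answers.

    Six tumor and four normal samples; the test suite enumerates its pair
    indicators, correlations and fold changes by brute force and freezes
    the expected values.
    """
    values = pd.DataFrame(
        _TOY_VALUES, index=pd.Index(_TOY_SAMPLES, name="sample_id"), dtype=float
    ).T
    values.index.name = "gene_id"
    condition = pd.Series(
        [TUMOR] * 6 + [NORMAL] * 4, index=values.columns
    )
    expression = ExpressionMatrix(values, condition)
    annotation = GeneAnnotation(
        biotype=pd.Series(
            {
                "LNC01": "lncRNA", "LNC02": "lncRNA", "LNC03": "lncRNA",
                "LNC04": "lncRNA", "FRG1": "protein_coding", "FRG2": "protein_coding",
                "MRNA1": "protein_coding", "MRNA2": "protein_coding",
            },
            name="biotype",
        )
    )
    frg_set = GeneSet.from_iterable("FRG", ["FRG1", "FRG2"])
    clinical = ClinicalTable(
        pd.DataFrame(_TOY_CLINICAL, index=pd.Index(_TOY_SAMPLES[:6], name="sample_id"))
    )
    truth = SimulationTruth(
        coexpressed_partner={"LNC01": "FRG1", "LNC03": "FRG2"},
        de_ids=["LNC04"],
        planted_pairs=[],
        linear_predictor=pd.Series(np.zeros(6), index=clinical.sample_ids),
        censoring_hazard=0.0,
    )
    return SimulatedCohort(
        expression, annotation, frg_set, clinical, truth,
        SimulationConfig(n_tumor=6, n_normal=4, n_lnc=4, n_mrna=4, n_frg=2, seed=0),
    )
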