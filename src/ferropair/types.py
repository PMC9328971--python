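"""Shared domain types for the pair-based prognostic-signature pipeline.

All containers wrap pandas objects so they interoperate with the I/O layer
and with the statistical libraries used downstream. Validation happens at
construction; downstream code may assume the invariants hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"

#: columns a clinical table must provide (Table-1 style covariates)
CLINICAL_REQUIRED = ("time", "event")
CLINICAL_COVARIATES = ("age", "gender", "grade", "stage", "T", "N", "M")

UNKNOWN = "unknown"


class FerropairError(Exception):
    """Base class for pipeline errors."""


class EmptySignatureError(FerropairError):
    """Raised when model selection retains no pair (empty-model path)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression on a linear scale.

    ``values`` is indexed by gene id with sample ids as columns;
    ``condition`` maps every sample id to ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.rename_axis(index="gene_id", columns=None)
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be >= 0")
        cond = self.condition.reindex(v.columns)
        if cond.isna().any():
            missing = cond.index[cond.isna()].tolist()
            raise ValueError(f"samples without condition label: {missing[:5]}")
        bad = set(cond.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        self.condition = cond

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, condition: str) -> pd.Index:
        return self.condition.index[self.condition == condition]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.condition)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.condition.loc[ids])

    def log2p1(self) -> pd.DataFrame:
        return np.log2(self.values + 1.0)


@dataclass
class GeneAnnotation:
    """gene_id -> biotype mapping (lncRNA vs protein_coding at minimum)."""

    biotype: pd.Series
    symbol: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.biotype.index.has_duplicates:
            raise ValueError("annotation maps a gene id to more than one biotype")

    def genes_with_biotype(self, biotype: str) -> pd.Index:
        return self.biotype.index[self.biotype == biotype]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name: str, members) -> "GeneSet":
        members = list(members)
        fs = frozenset(members)
        if len(fs) != len(members):
            raise ValueError(f"gene set {name!r} has duplicate members")
        return cls(name, fs)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))


@dataclass
class SurvivalData:
    """Right-censored follow-up: time in days (>0) and event in {0,1}."""

    sample_ids: pd.Index
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.sample_ids) != len(self.time) or len(self.time) != len(self.event):
            raise ValueError("sample_ids, time, event must have equal length")
        if (self.time <= 0).any():
            raise ValueError("follow-up times must be > 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalData":
        pos = pd.Index(self.sample_ids).get_indexer(list(sample_ids))
        if (pos < 0).any():
            missing = [s for s, p in zip(sample_ids, pos) if p < 0]
            raise KeyError(f"samples without survival data: {missing[:5]}")
        return SurvivalData(pd.Index(list(sample_ids)), self.time[pos], self.event[pos])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates plus survival fields.

    The table is indexed by sample id; unknown categories are stored as the
    literal string ``"unknown"``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in CLINICAL_REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"clinical table lacks required column {col!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        t = self.data["time"].astype(float)
        if (t <= 0).any() or t.isna().any():
            raise ValueError("clinical times must be > 0 (filter before construction)")
        ev = self.data["event"]
        if ev.isna().any() or not ev.isin((0, 1)).all():
            raise ValueError("event must be 0/1 with no missing values")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    @property
    def survival(self) -> SurvivalData:
        return SurvivalData(
            self.data.index,
            self.data["time"].to_numpy(dtype=float),
            self.data["event"].to_numpy(dtype=int),
        )

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())


PAIR_SEP = "|"


def pair_id(gene_a: str, gene_b: str) -> str:
    """Canonical id of an unordered pair: lexicographically smaller gene first."""
    if gene_a == gene_b:
        raise ValueError(f"a pair needs two distinct genes, got {gene_a!r} twice")
    a, b = sorted((gene_a, gene_b))
    return f"{a}{PAIR_SEP}{b}"


def split_pair_id(pid: str) -> tuple[str, str]:
    a, _, b = pid.partition(PAIR_SEP)
    if not a or not b:
        raise ValueError(f"malformed pair id {pid!r}")
    return a, b


@dataclass
class PairIndicatorMatrix:
    """Pairs x samples binary matrix from the within-sample rank rule.

    Row index holds canonical pair ids ``A|B`` with ``A < B``; the entry for
    (pair, sample) is 1 iff expression(A, sample) >= expression(B, sample).
    """

    indicators: pd.DataFrame

    def __post_init__(self) -> None:
        self.indicators = self.indicators.rename_axis(index="pair_id", columns=None)
        ind = self.indicators
        if ind.index.has_duplicates:
            raise ValueError("duplicate pair ids")
        arr = ind.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("indicators must be 0/1")
        for pid in ind.index:
            a, b = split_pair_id(pid)
            if not a < b:
                raise ValueError(f"pair id {pid!r} not in canonical orientation")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [split_pair_id(p) for p in self.indicators.index]

    @property
    def pair_ids(self) -> pd.Index:
        return self.indicators.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.indicators.columns

    @property
    def frequency(self) -> pd.Series:
        """Per-pair mean indicator across samples."""
        return self.indicators.mean(axis=1)

    def subset_samples(self, sample_ids: Sequence[str]) -> "PairIndicatorMatrix":
        return PairIndicatorMatrix(self.indicators[list(sample_ids)])

    def subset_pairs(self, pair_ids: Sequence[str]) -> "PairIndicatorMatrix":
        return PairIndicatorMatrix(self.indicators.loc[list(pair_ids)])


@dataclass
class SignatureModel:
    """Selected pairs with final multivariate Cox coefficients.

    The risk score of a sample is the Cox linear predictor
    sum_i beta_i * indicator_i(sample).
    """

    pairs: list[str]
    coefficients: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.pairs) != len(self.coefficients):
            raise ValueError("pairs and coefficients length mismatch")
        if len(self.pairs) < 1:
            raise EmptySignatureError("a signature needs at least one pair")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("coefficients must be finite")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        genes = [split_pair_id(p) for p in self.pairs]
        return pd.DataFrame(
            {
                "pair_id": self.pairs,
                "gene_a": [g[0] for g in genes],
                "gene_b": [g[1] for g in genes],
                "coefficient": self.coefficients,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "SignatureModel":
        return cls(
            pairs=df["pair_id"].tolist(),
            coefficients=df["coefficient"].to_numpy(dtype=float),
            metadata=metadata or {},
        )


HIGH, LOW = "high", "low"


@dataclass
class RiskProfile:
    """Per-sample risk score with the dichotomizing cutoff and group label."""

    scores: pd.Series
    cutoff: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("risk scores must be finite")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    @property
    def group(self) -> pd.Series:
        """'high' iff score > cutoff (scores equal to the cutoff are low)."""
        return pd.Series(
            np.where(self.scores.to_numpy() > self.cutoff, HIGH, LOW),
            index=self.scores.index,
            name="group",
        )

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "group": self.group, "cutoff": self.cutoff},
        ).rename_axis("sample_id")
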