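"""The 0-or-1 pair encoding and the pair-frequency filter.

For an unordered gene pair stored in canonical orientation (A, B) with
A < B lexicographically, a sample scores 1 when expression(A) >= expression(B)
and 0 when expression(A) < expression(B) — ties fall to 1, the non-"lower"
branch. The encoding depends only on the within-sample ordering of the two
genes, so any strictly increasing per-sample transform of expression leaves
it unchanged; that invariance is the point of the representation.

Pairs whose indicator is nearly constant across the cohort carry no class
information; the frequency filter keeps only pairs whose indicator mean
lies strictly inside a (low, high) band, 20-80% by default.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, PairIndicatorMatrix, pair_id

log = logging.getLogger("ferropair")


def build_pair_matrix(expr: ExpressionMatrix, gene_ids) -> PairIndicatorMatrix:
    """Encode all C(n,2) unordered pairs of ``gene_ids`` as 0/1 indicators.

    Pairs are stored in canonical lexicographic orientation and emitted in
    deterministic (sorted) order; the indicator for pair (A, B) in a sample
    is 1 iff expression(A) >= expression(B) there.
    """
    genes = sorted(dict.fromkeys(gene_ids))
    if len(genes) != len(list(gene_ids)):
        raise ValueError("gene_ids contains duplicates")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    missing = [g for g in genes if g not in expr.gene_ids]
    if missing:
        raise KeyError(f"genes absent from the expression matrix: {missing[:5]}")

    E = expr.values.loc[genes].to_numpy()
    pairs = list(combinations(range(len(genes)), 2))
    ia = np.fromiter((a for a, _ in pairs), dtype=int)
    ib = np.fromiter((b for _, b in pairs), dtype=int)
    indicators = (E[ia] >= E[ib]).astype(np.int8)
    index = pd.Index(
        [pair_id(genes[a], genes[b]) for a, b in pairs], name="pair_id"
    )
    return PairIndicatorMatrix(
        pd.DataFrame(indicators, index=index, columns=expr.sample_ids)
    )


def filter_pairs(
    pm: PairIndicatorMatrix, low: float = 0.20, high: float = 0.80
) -> PairIndicatorMatrix:
    """Keep pairs with indicator frequency strictly inside (low, high).

    Frequencies <= low or >= high mark pairs with "no certain class"
    (nearly always 0 or nearly always 1); those are removed. Strict
    boundaries, so a frequency of exactly ``low`` or ``high`` is dropped.
    """
    if low >= high:
        raise ValueError(f"low ({low}) must be < high ({high})")
    freq = pm.frequency
    keep = (freq > low) & (freq < high)
    kept = PairIndicatorMatrix(pm.indicators.loc[keep[keep].index])
    n_removed = int((~keep).sum())
    log.info(
        "pair-frequency filter: retained %d, removed %d of %d pairs",
        len(kept.pair_ids), n_removed, len(pm.pair_ids),
    )
    kept.n_removed = n_removed  # type: ignore[attr-defined]
    return kept
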