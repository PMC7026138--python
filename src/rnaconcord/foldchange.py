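"""Inter-pipeline disagreement in fold-change estimates.

Even when absolute abundances disagree, the *ratio* of a gene's
expression between two samples might be expected to agree across
pipelines — a constant per-pipeline scaling factor cancels exactly in
every ratio.  This module measures how far that expectation fails: for
each gene and each sample pair it computes the log2 fold change in every
source and records the largest spread between sources.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MultiSourceDataset, Unit
from .normalize import DEFAULT_PSEUDOCOUNT

__all__ = ["FCCriteria", "FCDiscordance", "sample_pair_log2fc",
           "foldchange_discordance"]

#: above this many samples, all-pairs evaluation is replaced by seeded sampling
DEFAULT_EXHAUSTIVE_LIMIT = 500


@dataclass(frozen=True)
class FCCriteria:
    """Fold-change discordance thresholds.

    A gene is flagged when two sources disagree on some sample pair's
    log2 fold change by more than ``log2_difference_threshold`` (default
    1, i.e. a 2-fold difference in fold-change estimates).  When
    ``max_sample_pairs`` is set, at most that many pairs are drawn
    uniformly without replacement using ``seed``; otherwise all pairs are
    used up to ``exhaustive_limit`` samples.
    """

    log2_difference_threshold: float = 1.0
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    max_sample_pairs: int | None = None
    seed: int = 0
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT

    def __post_init__(self) -> None:
        if self.log2_difference_threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class FCDiscordance:
    """Per-gene extremes of inter-source fold-change disagreement.

    ``table`` has one row per gene with columns ``max_fc`` / ``min_fc``
    (extreme log2 FC estimates among sources over evaluated pairs, in the
    fixed i<j pair orientation), ``max_gap`` (largest inter-source spread
    |Δ log2 FC| for one sample pair) and ``flag``.
    """

    table: pd.DataFrame
    criteria: FCCriteria
    sample_pairs: list[tuple[str, str]]
    exhaustive: bool

    @property
    def flagged_genes(self) -> set[str]:
        return set(self.table.index[self.table["flag"]])


def sample_pair_log2fc(matrix: ExpressionMatrix, gene: str, sample_i: str,
                       sample_j: str,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((v_i + c) / (v_j + c)) for one gene in one source.

    Antisymmetric under swapping the two samples.
    """
    try:
        v_i = matrix.data.at[gene, sample_i]
        v_j = matrix.data.at[gene, sample_j]
    except KeyError as exc:
        raise KeyError(f"unknown gene or sample: {exc}") from exc
    return float(np.log2((v_i + pseudocount) / (v_j + pseudocount)))


def _select_pairs(n_samples: int, criteria: FCCriteria) -> tuple[list[tuple[int, int]], bool]:
    all_pairs = list(combinations(range(n_samples), 2))
    cap = criteria.max_sample_pairs
    if cap is None and n_samples > criteria.exhaustive_limit:
        # implicit cap keeps the quadratic enumeration bounded
        cap = criteria.exhaustive_limit * (criteria.exhaustive_limit - 1) // 2
    if cap is None or cap >= len(all_pairs):
        return all_pairs, True
    rng = np.random.default_rng(criteria.seed)
    idx = rng.choice(len(all_pairs), size=cap, replace=False)
    return [all_pairs[k] for k in sorted(idx)], False


def foldchange_discordance(dataset: MultiSourceDataset, genes: Iterable[str],
                           criteria: FCCriteria = FCCriteria()) -> FCDiscordance:
    """Compare per-sample-pair log2 fold changes across all sources.

    ``genes`` is typically the DQ gene set.  For each gene the spread
    between the largest and smallest source estimate of the same sample
    pair's log2 FC is maximized over pairs; a gene whose worst spread
    exceeds the threshold is fold-change discordant.
    """
    if dataset.unit is not Unit.TPM:
        raise ValueError(f"fold-change discordance expects TPM, got {dataset.unit.value}")
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    sub = dataset.subset_genes(genes)
    log_vals = np.log2(sub.stack() + criteria.pseudocount)  # (S, G, N)
    n_genes = log_vals.shape[1]

    pairs, exhaustive = _select_pairs(log_vals.shape[2], criteria)
    max_fc = np.full(n_genes, -np.inf)
    min_fc = np.full(n_genes, np.inf)
    max_gap = np.zeros(n_genes)
    for i, j in pairs:
        delta = log_vals[:, :, i] - log_vals[:, :, j]  # (S, G)
        hi = delta.max(axis=0)
        lo = delta.min(axis=0)
        np.maximum(max_gap, hi - lo, out=max_gap)
        np.maximum(max_fc, hi, out=max_fc)
        np.minimum(min_fc, lo, out=min_fc)

    table = pd.DataFrame(
        {"max_fc": max_fc, "min_fc": min_fc, "max_gap": max_gap,
         "flag": max_gap > criteria.log2_difference_threshold},
        index=sub.gene_ids)
    sample_ids = sub.sample_ids
    named_pairs = [(sample_ids[i], sample_ids[j]) for i, j in pairs]
    return FCDiscordance(table=table, criteria=criteria,
                         sample_pairs=named_pairs, exhaustive=exhaustive)
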