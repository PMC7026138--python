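"""Discordantly quantified (DQ) gene detection.

A gene is *discordantly quantified* when, for the same sample and the
same reads, one pipeline calls it highly expressed (> 32 TPM) while
another calls it at least 4-fold lower (< 8 TPM), and this happens in at
least 1% of all samples.  The rule is deterministic thresholding — no
statistical test is involved — so the implementation is pure set/count
bookkeeping over (gene, source-pair, sample) triples, vectorized with
numpy.

Two published phrasings of the per-sample rule exist and they differ
when the lower value lies in [high/fold, high):

* ``mode="results"`` (default): max(a, b) > high AND min(a, b) < high/fold,
  both strict.
* ``mode="methods"``: max(a, b) > high AND
  |log2((a + c)/(b + c))| > log2(fold) on pseudocounted values.

Both are available; neither is silently merged into the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import MultiSourceDataset, Unit
from .normalize import DEFAULT_PSEUDOCOUNT

__all__ = [
    "DQCriteria",
    "DQResult",
    "min_discordant_samples",
    "pair_discordant",
    "find_dq_genes",
    "dq_threshold_sweep",
    "set_summary",
]


@dataclass(frozen=True)
class DQCriteria:
    """Thresholds of the DQ rule.

    ``high_tpm`` is the high-expression cut (default 32 TPM), ``fold``
    the required disagreement (default 4, giving a low cut of
    high_tpm/fold = 8 TPM), ``min_sample_fraction`` the fraction of
    samples that must be discordant (default 1%).  The pseudocount is
    only used by ``mode="methods"``.
    """

    high_tpm: float = 32.0
    fold: float = 4.0
    min_sample_fraction: float = 0.01
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    mode: str = "results"

    def __post_init__(self) -> None:
        if self.high_tpm <= 0:
            raise ValueError("high_tpm must be positive")
        if self.fold <= 1:
            raise ValueError("fold must exceed 1")
        if not 0 < self.min_sample_fraction <= 1:
            raise ValueError("min_sample_fraction must lie in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.mode not in ("results", "methods"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def low_tpm(self) -> float:
        return self.high_tpm / self.fold


@dataclass
class DQResult:
    """Per-gene discordance counts and DQ calls.

    ``pair_counts`` is genes × source-pairs (columns labelled
    ``"A|B"``): the number of samples discordant for that pair.
    ``union_counts`` counts each sample once per gene if *any* pair is
    discordant there; a gene is DQ when its union count reaches
    ``min_samples``.  ``per_source_membership`` maps each source to the
    DQ genes whose discordance involves that source.
    """

    pair_counts: pd.DataFrame
    union_counts: pd.Series
    dq_flags: pd.Series
    per_source_membership: dict[str, set[str]]
    criteria: DQCriteria
    min_samples: int

    @property
    def dq_genes(self) -> set[str]:
        return set(self.dq_flags.index[self.dq_flags])


def min_discordant_samples(n_samples: int, fraction: float) -> int:
    """Smallest number of samples meeting a fractional requirement.

    ceiling(fraction × n_samples), but at least 1 — with 4,800 samples at
    1% this is 48, with 1,890 it is 19 (ceiling of 18.9).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return max(1, math.ceil(fraction * n_samples))


def pair_discordant(a: float, b: float, criteria: DQCriteria = DQCriteria()) -> bool:
    """Is a single (sample, source-pair) abundance pair discordant?

    Symmetric in (a, b); inequalities are strict, so (32, 8) is *not*
    discordant under the defaults.
    """
    if a < 0 or b < 0:
        raise ValueError("abundances must be non-negative")
    hi, lo = max(a, b), min(a, b)
    if criteria.mode == "results":
        return hi > criteria.high_tpm and lo < criteria.low_tpm
    c = criteria.pseudocount
    lfc = abs(math.log2((a + c) / (b + c)))
    return hi > criteria.high_tpm and lfc > math.log2(criteria.fold)


def _pair_mask(a: np.ndarray, b: np.ndarray, criteria: DQCriteria) -> np.ndarray:
    """Boolean genes × samples discordance mask for one source pair."""
    hi = np.maximum(a, b)
    if criteria.mode == "results":
        return (hi > criteria.high_tpm) & (np.minimum(a, b) < criteria.low_tpm)
    c = criteria.pseudocount
    lfc = np.abs(np.log2((a + c) / (b + c)))
    return (hi > criteria.high_tpm) & (lfc > math.log2(criteria.fold))


def find_dq_genes(dataset: MultiSourceDataset,
                  criteria: DQCriteria = DQCriteria()) -> DQResult:
    """Evaluate the DQ rule over every (gene, source-pair, sample) triple."""
    if dataset.unit is not Unit.TPM:
        raise ValueError(f"DQ detection expects TPM, got {dataset.unit.value}")
    values = dataset.stack()  # (S, G, N)
    n_sources, n_genes, n_samples = values.shape
    labels = dataset.source_labels

    pair_labels = []
    pair_cols = []
    union = np.zeros((n_genes, n_samples), dtype=bool)
    involved = np.zeros((n_sources, n_genes), dtype=bool)
    for i, j in combinations(range(n_sources), 2):
        mask = _pair_mask(values[i], values[j], criteria)
        pair_labels.append(f"{labels[i]}|{labels[j]}")
        pair_cols.append(mask.sum(axis=1))
        union |= mask
        hit = mask.any(axis=1)
        involved[i] |= hit
        involved[j] |= hit

    pair_counts = pd.DataFrame(
        np.column_stack(pair_cols), index=dataset.gene_ids, columns=pair_labels)
    union_counts = pd.Series(union.sum(axis=1), index=dataset.gene_ids,
                             name="discordant_samples")
    min_samples = min_discordant_samples(n_samples, criteria.min_sample_fraction)
    dq_flags = union_counts >= min_samples
    membership = {
        labels[s]: set(dataset.gene_ids[dq_flags.to_numpy() & involved[s]])
        for s in range(n_sources)
    }
    return DQResult(pair_counts=pair_counts, union_counts=union_counts,
                    dq_flags=dq_flags, per_source_membership=membership,
                    criteria=criteria, min_samples=min_samples)


def dq_threshold_sweep(dataset: MultiSourceDataset, folds: Sequence[float],
                       criteria_base: DQCriteria = DQCriteria()) -> dict[float, DQResult]:
    """Re-run DQ detection at several fold cuts (low threshold = high/fold).

    Lower folds are strictly weaker criteria, so the DQ gene sets nest:
    DQ(4) ⊆ DQ(3) ⊆ DQ(2).
    """
    if any(f <= 1 for f in folds):
        raise ValueError("all folds must exceed 1")
    return {float(f): find_dq_genes(dataset, replace(criteria_base, fold=float(f)))
            for f in folds}


def set_summary(membership: Mapping[str, Iterable[str]]) -> dict:
    """Exclusive-intersection (UpSet) counts over per-source gene sets.

    For every non-empty subset S of sources, counts the genes belonging
    to *exactly* the sources in S, plus plain per-source totals.
    Exclusive counts are keyed by the sorted tuple of source labels.
    """
    if not membership:
        raise ValueError("need at least one set")
    sets = {k: set(v) for k, v in membership.items()}
    exclusive: dict[tuple[str, ...], int] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(sorted(sets), r):
            inside = set.intersection(*(sets[k] for k in combo))
            outside = set.union(set(), *(sets[k] for k in sets if k not in combo))
            exclusive[combo] = len(inside - outside)
    return {
        "totals": {k: len(v) for k, v in sets.items()},
        "exclusive": exclusive,
        "union_size": len(set.union(*sets.values())),
    }
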