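"""Core containers for multi-pipeline expression data.

An :class:`ExpressionMatrix` is one pipeline's genes × samples abundance
table tagged with a unit (FPKM, TPM or log2-TPM) and a source label.  A
:class:`MultiSourceDataset` holds several such matrices for *the same*
genes and samples in identical order, which is the precondition for every
cross-pipeline comparison in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = ["Unit", "ExpressionMatrix", "MultiSourceDataset"]

#: Relative tolerance for the "TPM columns sum to one million" contract.
TPM_SUM_RTOL = 1e-6
TPM_SCALE = 1e6


class Unit(str, Enum):
    """Abundance unit of an expression matrix."""

    FPKM = "FPKM"
    TPM = "TPM"
    LOG2TPM = "LOG2TPM"


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes × samples abundance matrix from one processing pipeline.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as index and sample identifiers as
        columns.  Values must be finite; for linear units (FPKM/TPM) they
        must also be non-negative.
    unit
        Abundance unit of ``data``.
    source
        Short pipeline label, e.g. ``"GDC"`` or ``"Recount2"``.
    """

    data: pd.DataFrame
    unit: Unit
    source: str

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy(dtype=float, copy=False)
        if np.isnan(values).any():
            raise ValueError("missing values are not allowed")
        if not np.isfinite(values).all():
            raise ValueError("non-finite abundance values")
        if self.unit in (Unit.FPKM, Unit.TPM) and (values < 0).any():
            raise ValueError("negative abundance values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def is_normalized_tpm(self, rtol: float = TPM_SUM_RTOL) -> bool:
        """True if every sample column sums to 10^6 within ``rtol``.

        Holds for TPM matrices produced by
        :func:`rnaconcord.normalize.fpkm_to_tpm`; small hand-built TPM
        tables used for threshold examples need not satisfy it.
        """
        if self.unit is not Unit.TPM:
            return False
        sums = self.values.sum(axis=0)
        return bool(np.allclose(sums, TPM_SCALE, rtol=rtol, atol=0.0))

    def with_data(self, data: pd.DataFrame, unit: Unit | None = None) -> "ExpressionMatrix":
        """Copy of this matrix with new values (and optionally a new unit)."""
        return ExpressionMatrix(data=data, unit=self.unit if unit is None else unit,
                                source=self.source)


@dataclass
class MultiSourceDataset:
    """Several pipelines' matrices aligned to one gene/sample universe."""

    sources: list[ExpressionMatrix]
    #: per-source counts of genes/samples dropped during harmonization
    drop_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sources) < 2:
            raise ValueError("a MultiSourceDataset needs at least 2 sources")
        first = self.sources[0]
        labels = [m.source for m in self.sources]
        _check_unique(labels, "source")
        for m in self.sources[1:]:
            if not m.gene_ids.equals(first.gene_ids):
                raise ValueError("sources have different gene indices")
            if not m.sample_ids.equals(first.sample_ids):
                raise ValueError("sources have different sample indices")
            if m.unit is not first.unit:
                raise ValueError(
                    f"unit mismatch: {m.source}={m.unit.value} vs {first.source}={first.unit.value}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.sources[0].gene_ids

    @property
    def sample_ids(self) -> pd.Index:
        return self.sources[0].sample_ids

    @property
    def unit(self) -> Unit:
        return self.sources[0].unit

    @property
    def source_labels(self) -> list[str]:
        return [m.source for m in self.sources]

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    def __getitem__(self, label: str) -> ExpressionMatrix:
        for m in self.sources:
            if m.source == label:
                return m
        raise KeyError(f"unknown source {label!r}")

    def stack(self) -> np.ndarray:
        """All sources as one array of shape (n_sources, n_genes, n_samples)."""
        return np.stack([m.values for m in self.sources])

    def subset_genes(self, genes) -> "MultiSourceDataset":
        genes = [g for g in self.gene_ids if g in set(genes)]
        if not genes:
            raise ValueError("empty gene subset")
        subs = [m.with_data(m.data.loc[genes]) for m in self.sources]
        return MultiSourceDataset(subs, drop_report=self.drop_report)
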