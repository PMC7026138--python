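"""FPKM → TPM conversion and the log2 pseudocount transform.

FPKM normalizes within a sample by library size and transcript length but
its column totals vary between samples and annotations, so FPKM values
are not directly comparable across pipelines.  TPM rescales each sample
column to a fixed total of one million over the chosen gene universe:

    TPM_g = FPKM_g / sum_{genes} FPKM * 1e6

Because TPM is a fractional measure, the gene universe must be fixed
*before* conversion — convert after harmonization, never on per-source
universes.  Dropping a gene after conversion silently breaks the
sum-to-a-million contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MultiSourceDataset, TPM_SCALE, Unit

__all__ = ["TransformParams", "fpkm_to_tpm", "log_transform", "dataset_to_tpm",
           "dataset_to_log2tpm"]

DEFAULT_PSEUDOCOUNT = 0.001


@dataclass(frozen=True)
class TransformParams:
    """Parameters of the log2 transform: log2(TPM + pseudocount)."""

    pseudocount: float = DEFAULT_PSEUDOCOUNT
    scale_factor: float = TPM_SCALE

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample column so it sums to 10^6; unit becomes TPM.

    The input must already be restricted to the common gene universe.
    A column summing to zero has no defined fractional abundances and is
    an error naming the offending sample.
    """
    if matrix.unit is not Unit.FPKM:
        raise ValueError(f"expected FPKM input, got {matrix.unit.value}")
    values = matrix.values
    colsums = values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        bad = matrix.sample_ids[zero].tolist()
        raise ValueError(f"zero library sum in sample(s): {bad[:5]}")
    tpm = values / colsums * TPM_SCALE
    out = pd.DataFrame(tpm, index=matrix.gene_ids, columns=matrix.sample_ids)
    return matrix.with_data(out, unit=Unit.TPM)


def log_transform(matrix: ExpressionMatrix,
                  params: TransformParams = TransformParams()) -> ExpressionMatrix:
    """Elementwise log2(TPM + pseudocount)."""
    if matrix.unit is not Unit.TPM:
        raise ValueError(f"expected TPM input, got {matrix.unit.value}")
    logged = np.log2(matrix.values + params.pseudocount)
    out = pd.DataFrame(logged, index=matrix.gene_ids, columns=matrix.sample_ids)
    return matrix.with_data(out, unit=Unit.LOG2TPM)


def dataset_to_tpm(dataset: MultiSourceDataset) -> MultiSourceDataset:
    """Convert every source of a harmonized FPKM dataset to TPM.

    Sources that are natively TPM on a different universe are rescaled
    too, so that every column sums to 10^6 over the shared genes.
    """
    if dataset.unit is Unit.TPM:
        sources = [fpkm_to_tpm(m.with_data(m.data, unit=Unit.FPKM)) for m in dataset.sources]
    else:
        sources = [fpkm_to_tpm(m) for m in dataset.sources]
    return MultiSourceDataset(sources, drop_report=dataset.drop_report)


def dataset_to_log2tpm(dataset: MultiSourceDataset,
                       params: TransformParams = TransformParams()) -> MultiSourceDataset:
    """log2(TPM + pseudocount) for every source of a TPM dataset."""
    sources = [log_transform(m, params) for m in dataset.sources]
    return MultiSourceDataset(sources, drop_report=dataset.drop_report)
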