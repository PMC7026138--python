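"""Reading, writing and harmonizing expression matrices and gene lists.

Pipelines quantify overlapping but non-identical gene and sample sets
(different annotation releases, different portal exports), so every
cross-pipeline analysis starts by intersecting the universes.
:func:`harmonize` restricts all sources to the shared genes and samples
and puts them in one fixed lexicographic order so that downstream results
are byte-stable.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .matrix import ExpressionMatrix, MultiSourceDataset, Unit

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_list",
    "strip_gene_version",
    "harmonize",
    "write_drop_report",
]

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(65536)
    if not sample.strip():
        raise ValueError(f"{path}: empty file")
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        # single-column files defeat the sniffer; default to tab
        return "\t"


def read_expression_matrix(path, unit: Unit | str, source: str,
                           delimiter: str | None = None) -> ExpressionMatrix:
    """Read a delimited genes × samples table into an :class:`ExpressionMatrix`.

    First column holds gene identifiers, header row holds sample
    identifiers.  The delimiter is auto-detected among tab and comma
    unless forced.  Duplicate gene IDs, missing cells and negative values
    are errors, matching the complete-matrix assumption of the analysis.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene id(s): {dups[:5]}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values (ragged rows or empty cells)")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric abundance value: {exc}") from exc
    if Unit(unit) in (Unit.FPKM, Unit.TPM) and (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative abundance values")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(data=df, unit=Unit(unit), source=source)


def write_expression_matrix(matrix: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write a matrix as delimited text (genes in rows, header of samples)."""
    matrix.data.to_csv(path, sep=delimiter, index_label="gene_id")


def read_gene_list(path) -> list[str]:
    """Read a one-identifier-per-line gene list.

    Blank lines are ignored, identifiers are whitespace-trimmed, and the
    result is order-preserving deduplicated.  An empty file yields an
    empty list with a warning rather than an error.
    """
    seen: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            gid = line.strip()
            if gid:
                seen.setdefault(gid, None)
    if not seen:
        warnings.warn(f"{path}: empty gene list", stacklevel=2)
    return list(seen)


def strip_gene_version(gene_id: str) -> str:
    """Drop a trailing Ensembl-style version suffix (``ENSG…​.12`` → ``ENSG…``)."""
    return _VERSION_SUFFIX.sub("", gene_id)


def harmonize(matrices: Sequence[ExpressionMatrix],
              gene_whitelist: Iterable[str] | None = None,
              strip_versions: bool = True) -> MultiSourceDataset:
    """Restrict all sources to their shared gene and sample universe.

    Pipelines built on different annotation releases carry different
    Ensembl version suffixes; with ``strip_versions`` (default) IDs are
    matched after dropping the ``.N`` suffix, otherwise by exact string.
    The shared genes (optionally intersected with ``gene_whitelist``) and
    samples are placed in lexicographic order, identically in every
    source, and the per-source dropped counts are recorded in
    ``drop_report``.
    """
    if len(matrices) < 2:
        raise ValueError("harmonize needs at least 2 matrices")
    unit = matrices[0].unit
    if any(m.unit is not unit for m in matrices):
        raise ValueError("all matrices must share one unit")

    renamed = []
    for m in matrices:
        if strip_versions:
            new_index = m.data.index.map(strip_gene_version)
            if pd.Index(new_index).has_duplicates:
                raise ValueError(
                    f"{m.source}: version-stripping produced duplicate gene ids")
            df = m.data.set_axis(new_index, axis=0)
        else:
            df = m.data
        renamed.append(m.with_data(df))

    shared_genes = renamed[0].gene_ids
    for m in renamed[1:]:
        shared_genes = shared_genes.intersection(m.gene_ids)
    if gene_whitelist is not None:
        wl = {strip_gene_version(g) if strip_versions else g for g in gene_whitelist}
        shared_genes = shared_genes.intersection(pd.Index(sorted(wl)))
    shared_samples = renamed[0].sample_ids
    for m in renamed[1:]:
        shared_samples = shared_samples.intersection(m.sample_ids)

    if len(shared_genes) == 0:
        raise ValueError("empty gene intersection across sources")
    if len(shared_samples) == 0:
        raise ValueError("empty sample intersection across sources")

    shared_genes = shared_genes.sort_values()
    shared_samples = shared_samples.sort_values()

    report = {}
    aligned = []
    for m in renamed:
        report[m.source] = {
            "genes_dropped": int(len(m.gene_ids) - len(shared_genes)),
            "samples_dropped": int(len(m.sample_ids) - len(shared_samples)),
        }
        aligned.append(m.with_data(m.data.loc[shared_genes, shared_samples]))
    return MultiSourceDataset(aligned, drop_report=report)


def write_drop_report(dataset: MultiSourceDataset, path) -> None:
    """Dump the harmonization drop report as JSON."""
    with open(path, "w") as fh:
        json.dump(dataset.drop_report, fh, indent=2, sort_keys=True)
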