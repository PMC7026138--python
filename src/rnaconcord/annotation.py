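"""Gene-model comparison across annotation releases.

Pipelines built on different GENCODE releases assign different exon sets
to the same gene, which changes per-gene read counts and hence abundance
estimates.  This module summarizes each annotation's gene models (exon
count after strand-aware deduplication, union exon length) and reports,
gene by gene, whether the exon count agrees across releases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
import pyranges as pr

__all__ = ["GeneModelSummary", "summarize_annotation", "merged_interval_length",
           "cross_annotation_agreement"]


@dataclass
class GeneModelSummary:
    """Per-gene exon structure of one annotation.

    ``table`` has one row per gene: ``exon_count`` (distinct exon
    intervals, deduplicated on chromosome/start/end/strand within the
    gene), ``exon_records`` (raw exon rows before deduplication, logged
    because the two conventions give different counts when several
    transcripts share exons) and ``union_exon_length`` (bases covered by
    the union of the gene's exon intervals).
    """

    table: pd.DataFrame
    source: str

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index


def merged_interval_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bases covered by a union of 1-based closed intervals.

    Touching intervals ([1,10] and [11,20]) merge, so splitting an exon
    into adjacent pieces never changes the union length.
    """
    ivs = sorted(intervals)
    total = 0
    cur_start = cur_end = None
    for start, end in ivs:
        if end < start:
            raise ValueError(f"malformed interval: end {end} < start {start}")
        if cur_end is None or start > cur_end + 1:
            if cur_end is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def summarize_annotation(gtf_path, source: str | None = None) -> GeneModelSummary:
    """Summarize per-gene exon structure from a GTF/GFF file.

    Exon features must carry ``gene_id`` attributes.  Coordinates follow
    the GTF convention (1-based, inclusive); pyranges' half-open
    representation is converted back at this boundary.
    """
    gr = pr.read_gtf(str(gtf_path))
    df = gr.df
    exons = df[df["Feature"] == "exon"].copy()
    if exons.empty:
        raise ValueError(f"{gtf_path}: no exon features found")
    if "gene_id" not in exons.columns or exons["gene_id"].isna().any():
        raise ValueError(f"{gtf_path}: exon features missing gene_id attributes")
    # pyranges: Start 0-based half-open → back to 1-based inclusive
    exons["start1"] = exons["Start"].astype(int) + 1
    exons["end1"] = exons["End"].astype(int)
    if (exons["end1"] < exons["start1"]).any():
        raise ValueError(f"{gtf_path}: malformed coordinates (end < start)")

    rows = {}
    for gene, grp in exons.groupby("gene_id", sort=True):
        n_records = len(grp)
        distinct = grp.drop_duplicates(
            subset=["Chromosome", "start1", "end1", "Strand"])
        union = sum(
            merged_interval_length(zip(part["start1"], part["end1"]))
            for _, part in distinct.groupby(["Chromosome", "Strand"], observed=True)
        )
        rows[gene] = (len(distinct), n_records, union)
    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["exon_count", "exon_records", "union_exon_length"])
    table.index.name = "gene_id"
    label = source if source is not None else str(gtf_path)
    return GeneModelSummary(table=table, source=label)


def cross_annotation_agreement(summaries: Sequence[GeneModelSummary],
                               genes: Iterable[str] | None = None,
                               decimals: int = 2) -> dict:
    """Per-gene exon-count agreement across annotation releases.

    A gene present in all summaries *disagrees* when its exon counts are
    not identical everywhere; genes absent from at least one annotation
    are counted separately, not as disagreement.  When ``genes`` is
    given (e.g. the DQ set), the same breakdown is also reported inside
    that subset.
    """
    from .report import percentage

    if len(summaries) < 2:
        raise ValueError("need at least 2 annotation summaries")
    universe: set[str] = set()
    for s in summaries:
        universe |= set(s.gene_ids)
    if genes is not None:
        universe &= set(genes)
    if not universe:
        raise ValueError("empty gene overlap between annotations and gene set")

    shared = set(universe)
    for s in summaries:
        shared &= set(s.gene_ids)
    absent = universe - shared

    disagreeing = {
        g for g in shared
        if len({int(s.table.at[g, "exon_count"]) for s in summaries}) > 1
    }
    per_gene = pd.DataFrame(
        {s.source: s.table["exon_count"].reindex(sorted(universe)) for s in summaries})
    per_gene["agrees"] = [
        g in shared and g not in disagreeing for g in per_gene.index]

    n_shared = len(shared)
    return {
        "n_genes": len(universe),
        "n_shared": n_shared,
        "n_absent_somewhere": len(absent),
        "n_disagreeing": len(disagreeing),
        "percent_disagreeing": percentage(len(disagreeing), n_shared, decimals)
        if n_shared else float("nan"),
        "disagreeing_genes": sorted(disagreeing),
        "per_gene": per_gene,
    }
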