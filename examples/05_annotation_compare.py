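"""Compare gene models across two annotation releases.

Writes two toy GTFs that disagree on one gene's exon count, summarizes
per-gene exon structure (deduplicated exon intervals, union exon
length), and reports the disagreement percentage.
"""

import tempfile
from pathlib import Path

from rnaconcord import cross_annotation_agreement, summarize_annotation

V1 = """\
chr1\thavana\texon\t1\t100\t.\t+\t.\tgene_id "TP53"; transcript_id "t1";
chr1\thavana\texon\t200\t300\t.\t+\t.\tgene_id "TP53"; transcript_id "t1";
chr1\thavana\texon\t200\t300\t.\t+\t.\tgene_id "TP53"; transcript_id "t2";
chr2\thavana\texon\t50\t150\t.\t-\t.\tgene_id "KRAS"; transcript_id "t3";
"""
# v2 adds a third exon to TP53 and keeps KRAS unchanged
V2 = V1 + 'chr1\thavana\texon\t400\t450\t.\t+\t.\tgene_id "TP53"; transcript_id "t4";\n'

with tempfile.TemporaryDirectory() as tmp:
    p1, p2 = Path(tmp, "v1.gtf"), Path(tmp, "v2.gtf")
    p1.write_text(V1)
    p2.write_text(V2)
    s1 = summarize_annotation(p1, source="gencode_v1")
    s2 = summarize_annotation(p2, source="gencode_v2")

print("per-gene summary (v1):")
print(s1.table)
# TP53: 2 distinct exons from 3 records (duplicate exon counted once),
# union length 201 bases; KRAS: 1 exon, 101 bases.

rep = cross_annotation_agreement([s1, s2])
print(f"\n{rep['n_disagreeing']} of {rep['n_shared']} shared genes disagree "
      f"on exon count ({rep['percent_disagreeing']}%): {rep['disagreeing_genes']}")
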