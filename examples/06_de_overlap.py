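"""Summarize agreement of per-pipeline differential-expression gene lists.

DE lists are produced by external tools; this package only measures how
much they overlap: genes found by all pipelines versus genes missed by
at least one.
"""

from rnaconcord import de_overlap, percentage

lists = {
    "GDC":      {"TP53", "KRAS", "MYC", "EGFR", "CEBPA"},
    "Toil":     {"TP53", "KRAS", "MYC", "EGFR", "NPM1"},
    "Piccolo":  {"TP53", "KRAS", "MYC", "CEBPA", "NPM1"},
    "Recount2": {"TP53", "KRAS", "MYC", "EGFR", "U2AF1"},
}

out = de_overlap(lists)
print("per-pipeline DE list sizes:", out["sizes"])
print(f"found by all pipelines: {out['found_by_all']} genes")
print(f"not found by all: {out['not_found_by_all']} of {out['union_size']} "
      f"({out['percent_not_found_by_all']}%)")
# Genes in the union but not the intersection would be called
# differentially expressed by some pipelines and missed by others.
print("\nreporting convention check: percentage(2068, 16738) =",
      percentage(2068, 16738), "%")
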