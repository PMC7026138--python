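"""Independent brute-force reference implementations.

Deliberately naive (nested Python loops, scipy per-gene calls) so they
share no code path with the vectorized package implementations they
check.
"""

import math
from itertools import combinations

import numpy as np
from scipy import stats


def brute_dq(values, source_labels, criteria):
    """Triple-loop DQ evaluation over (gene, source-pair, sample).

    Returns (pair_counts dict keyed "A|B" -> list per gene,
    union_counts list, involved dict source -> set of gene indices).
    """
    n_sources, n_genes, n_samples = values.shape
    low = criteria.high_tpm / criteria.fold
    pair_counts = {}
    union_sets = [set() for _ in range(n_genes)]
    involved = {lab: set() for lab in source_labels}
    for i, j in combinations(range(n_sources), 2):
        key = f"{source_labels[i]}|{source_labels[j]}"
        counts = []
        for g in range(n_genes):
            c = 0
            for n in range(n_samples):
                a, b = values[i, g, n], values[j, g, n]
                hi, lo_v = max(a, b), min(a, b)
                if criteria.mode == "results":
                    disc = hi > criteria.high_tpm and lo_v < low
                else:
                    pc = criteria.pseudocount
                    disc = (hi > criteria.high_tpm and
                            abs(math.log2((a + pc) / (b + pc))) > math.log2(criteria.fold))
                if disc:
                    c += 1
                    union_sets[g].add(n)
                    involved[source_labels[i]].add(g)
                    involved[source_labels[j]].add(g)
            counts.append(c)
        pair_counts[key] = counts
    union_counts = [len(s) for s in union_sets]
    return pair_counts, union_counts, involved


def brute_fc_max_gap(values, pseudocount):
    """Exhaustive per-gene max inter-source spread of sample-pair log2 FCs."""
    n_sources, n_genes, n_samples = values.shape
    gaps = []
    for g in range(n_genes):
        worst = 0.0
        for i, j in combinations(range(n_samples), 2):
            fcs = [
                math.log2((values[s, g, i] + pseudocount) /
                          (values[s, g, j] + pseudocount))
                for s in range(n_sources)
            ]
            worst = max(worst, max(fcs) - min(fcs))
        gaps.append(worst)
    return gaps


def brute_set_summary(membership):
    """Exhaustive exclusive-subset partition of set members."""
    sets = {k: set(v) for k, v in membership.items()}
    names = sorted(sets)
    exclusive = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            exclusive[combo] = 0
    for g in set.union(*sets.values()):
        sig = tuple(k for k in names if g in sets[k])
        exclusive[sig] += 1
    return exclusive


def scipy_per_gene_corr(a, b, method):
    """Per-row correlation via scipy's scalar routines."""
    out = []
    for row_a, row_b in zip(a, b):
        if np.std(row_a) == 0 or np.std(row_b) == 0:
            out.append(np.nan)
        elif method == "pearson":
            out.append(stats.pearsonr(row_a, row_b).statistic)
        else:
            out.append(stats.spearmanr(row_a, row_b).statistic)
    return np.array(out)
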