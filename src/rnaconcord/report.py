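"""Headline-number helpers and cross-pipeline set overlaps.

Percentages are rounded half-up (2068/16738 → 12.36, not banker's 12.36
vs 12.35 ambiguity), matching the convention used when such counts are
reported in print.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Iterable

__all__ = ["percentage", "de_overlap", "RunManifest"]


def percentage(numerator: int, denominator: int, decimals: int = 2) -> float:
    """100 × numerator/denominator, half-up rounded to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(frac.quantize(quantum, rounding=ROUND_HALF_UP))


def de_overlap(gene_lists: Mapping[str, Iterable[str]], decimals: int = 2) -> dict:
    """Summarize agreement of per-pipeline differentially-expressed gene lists.

    Reports per-pipeline sizes, the genes found by all pipelines
    (intersection), and the genes *not* found by all (union minus
    intersection) with their percentage of the union.
    """
    if len(gene_lists) < 2:
        raise ValueError("need at least 2 gene lists")
    sets = {k: set(v) for k, v in gene_lists.items()}
    union = set.union(*sets.values())
    inter = set.intersection(*sets.values())
    not_all = union - inter
    return {
        "sizes": {k: len(v) for k, v in sets.items()},
        "found_by_all": len(inter),
        "not_found_by_all": len(not_all),
        "union_size": len(union),
        "percent_not_found_by_all": percentage(len(not_all), len(union), decimals)
        if union else 0.0,
    }


@dataclass
class RunManifest:
    """Machine-readable record of one analysis run.

    Every table an analysis emits should be registered here so each
    number in a human-readable summary is traceable to a file.
    """

    tool_version: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)

    def register_table(self, name: str, path, n_rows: int) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest() if path.exists() else None
        self.tables[name] = {"path": str(path), "n_rows": int(n_rows),
                             "sha256": digest}

    def write(self, path) -> None:
        payload = {"tool_version": self.tool_version, "config": self.config,
                   "seeds": self.seeds, "tables": self.tables}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
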