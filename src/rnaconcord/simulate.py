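"""Multi-pipeline expression simulator with planted discordance.

Real cross-pipeline comparisons start from one set of reads quantified
by several pipelines, so the simulator draws one log-normal baseline
expression surface per (gene, sample) — the shared biology — and derives
each source from it by adding small independent log-normal noise (the
pipeline's estimation jitter) and a per-source library-size skew that
mimics FPKM-scale differences and vanishes under TPM conversion.

Discordance is planted in three modes, one distorted source per gene,
mirroring the disagreement patterns seen in practice:

* ``scaling``  — the affected source reports the gene uniformly lower by
  a constant factor (ratios between samples are preserved, so the gene
  is abundance-discordant but never fold-change-discordant);
* ``sample_specific`` — a fixed subset of samples is shifted in the
  affected source only;
* ``uncorrelated`` — the affected source's values are replaced by
  independent draws, destroying the cross-source correlation entirely.

Planted genes are assigned high baselines (default 32–64 TPM in log2
mean) because the discordance rule only concerns genes that are highly
expressed somewhere: a 1-TPM gene scaled eight-fold down can never cross
the high cut.  Distortions scale the affected source *down*; up versus
down is a pure relabeling of which source is "affected".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dq import DQResult
from .foldchange import FCDiscordance
from .matrix import ExpressionMatrix, MultiSourceDataset, Unit

__all__ = ["SyntheticConfig", "PlantedGene", "SyntheticTruth", "generate",
           "recovery_report"]

MODES = ("scaling", "sample_specific", "uncorrelated")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated multi-pipeline dataset.

    Baselines are log2-TPM-scale: gene means drawn from
    ``baseline_log2_mean_range``, per-sample biological spread
    ``baseline_log2_sd`` around the gene mean, per-source estimation
    noise ``noise_sd`` (all in log2 units).  ``library_skew`` multiplies
    each source's linear values before emission (defaults to powers of
    two); it models library-size differences and cancels under TPM.
    """

    n_genes: int = 1000
    n_samples: int = 200
    n_sources: int = 4
    baseline_log2_mean_range: tuple[float, float] = (0.0, 8.0)
    baseline_log2_sd: float = 0.5
    noise_sd: float = 0.1
    n_scaling: int = 10
    scaling_factor: float = 8.0
    n_sample_specific: int = 10
    affected_fraction: float = 0.1
    sample_shift_log2: float = 3.0
    n_uncorrelated: int = 10
    planted_baseline_log2_range: tuple[float, float] = (5.0, 6.0)
    library_skew: tuple[float, ...] | None = None
    seed: int = 17

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.n_sources) < 1 or self.n_sources < 2:
            raise ValueError("need positive sizes and at least 2 sources")
        if self.n_planted > self.n_genes:
            raise ValueError("planted counts exceed n_genes")
        if self.baseline_log2_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.scaling_factor < 1:
            raise ValueError("scaling_factor must be at least 1")
        if not 0 < self.affected_fraction <= 1:
            raise ValueError("affected_fraction must lie in (0, 1]")
        if self.library_skew is not None and len(self.library_skew) != self.n_sources:
            raise ValueError("library_skew must have one entry per source")

    @property
    def n_planted(self) -> int:
        return self.n_scaling + self.n_sample_specific + self.n_uncorrelated

    def skews(self) -> np.ndarray:
        if self.library_skew is not None:
            return np.asarray(self.library_skew, dtype=float)
        return 2.0 ** np.arange(self.n_sources)


@dataclass(frozen=True)
class PlantedGene:
    """Ground truth for one planted gene."""

    gene_id: str
    mode: str
    affected_source: str
    #: linear fold effect; None for uncorrelated redraws (no scalar effect)
    effect_size: float | None
    affected_samples: tuple[str, ...] = ()


@dataclass
class SyntheticTruth:
    """All planted labels for one simulated dataset."""

    planted: list[PlantedGene]
    config: SyntheticConfig
    gene_ids: list[str] = field(default_factory=list)

    @property
    def planted_genes(self) -> set[str]:
        return {p.gene_id for p in self.planted}

    def genes_by_mode(self, mode: str) -> set[str]:
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        return {p.gene_id for p in self.planted if p.mode == mode}


def generate(config: SyntheticConfig = SyntheticConfig()
             ) -> tuple[MultiSourceDataset, SyntheticTruth]:
    """Simulate FPKM-like matrices for several pipelines plus truth labels.

    Deterministic given ``config.seed``.  Draw order: gene means →
    planted gene/source/sample assignments → shared baseline surface →
    per-source noise → uncorrelated redraws.
    """
    rng = np.random.default_rng(config.seed)
    n_g, n_s, n_src = config.n_genes, config.n_samples, config.n_sources
    gene_ids = [f"G{i:05d}" for i in range(n_g)]
    sample_ids = [f"S{i:04d}" for i in range(n_s)]
    source_ids = [f"P{i + 1}" for i in range(n_src)]

    lo, hi = config.baseline_log2_mean_range
    means = rng.uniform(lo, hi, size=n_g)

    planted_idx = rng.choice(n_g, size=config.n_planted, replace=False)
    p_lo, p_hi = config.planted_baseline_log2_range
    means[planted_idx] = rng.uniform(p_lo, p_hi, size=config.n_planted)
    mode_of = {}
    cursor = 0
    for mode, count in zip(MODES, (config.n_scaling, config.n_sample_specific,
                                   config.n_uncorrelated)):
        for g in planted_idx[cursor:cursor + count]:
            mode_of[int(g)] = mode
        cursor += count
    affected_source = rng.integers(0, n_src, size=config.n_planted)

    n_affected = max(1, math.ceil(config.affected_fraction * n_s))
    affected_samples = {}
    for g, m in mode_of.items():
        if m == "sample_specific":
            affected_samples[g] = np.sort(rng.choice(n_s, size=n_affected,
                                                     replace=False))

    base = rng.normal(means[:, None], config.baseline_log2_sd, size=(n_g, n_s))
    # anchor the shared biology on the TPM scale: planted rows keep their
    # drawn absolute values (so they interact with the DQ thresholds as
    # configured) while the unplanted background is rescaled so every
    # baseline column sums to exactly 1e6
    base_lin = 2.0 ** base
    unplanted = np.ones(n_g, dtype=bool)
    unplanted[planted_idx] = False
    planted_mass = base_lin[~unplanted].sum(axis=0) if config.n_planted else 0.0
    rest_mass = base_lin[unplanted].sum(axis=0)
    base_lin[unplanted] *= (1e6 - planted_mass) / rest_mass
    base = np.log2(base_lin)
    noise = rng.normal(0.0, config.noise_sd, size=(n_src, n_g, n_s))
    log_vals = base[None, :, :] + noise  # (S, G, N) in log2 TPM units

    planted: list[PlantedGene] = []
    for k, g in enumerate(planted_idx):
        g = int(g)
        src = int(affected_source[k])
        mode = mode_of[g]
        if mode == "scaling":
            log_vals[src, g, :] -= math.log2(config.scaling_factor)
            effect, samples = config.scaling_factor, ()
        elif mode == "sample_specific":
            sel = affected_samples[g]
            log_vals[src, g, sel] -= config.sample_shift_log2
            effect = 2.0 ** config.sample_shift_log2
            samples = tuple(sample_ids[i] for i in sel)
        else:  # uncorrelated: independent redraw of the whole profile
            log_vals[src, g, :] = rng.uniform(lo, hi, size=n_s)
            effect, samples = None, ()
        planted.append(PlantedGene(gene_id=gene_ids[g], mode=mode,
                                   affected_source=source_ids[src],
                                   effect_size=effect, affected_samples=samples))

    skews = config.skews()
    sources = []
    for s in range(n_src):
        values = (2.0 ** log_vals[s]) * skews[s]
        df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
        sources.append(ExpressionMatrix(data=df, unit=Unit.FPKM,
                                        source=source_ids[s]))
    dataset = MultiSourceDataset(sources)
    truth = SyntheticTruth(planted=planted, config=config, gene_ids=gene_ids)
    return dataset, truth


def recovery_report(truth: SyntheticTruth, dq: DQResult,
                    fc: FCDiscordance | None = None) -> dict:
    """Confusion summary of DQ calls (and FC flags) against planted labels.

    Sensitivity is reported overall and per mode; specificity is over
    the unplanted genes.  When ``fc`` is given, the fraction of each
    mode's genes flagged fold-change-discordant is added.
    """
    universe = set(dq.dq_flags.index)
    if truth.gene_ids and universe != set(truth.gene_ids):
        raise ValueError("truth and DQ result cover different gene universes")
    positives = truth.planted_genes
    negatives = universe - positives
    called = dq.dq_genes

    def _rate(num: int, den: int) -> float:
        return num / den if den else float("nan")

    out = {
        "sensitivity": _rate(len(called & positives), len(positives)),
        "specificity": _rate(len(negatives - called), len(negatives)),
        "n_planted": len(positives),
        "n_called": len(called),
        "per_mode_sensitivity": {
            m: _rate(len(called & truth.genes_by_mode(m)),
                     len(truth.genes_by_mode(m)))
            for m in MODES
        },
    }
    if fc is not None:
        flagged = fc.flagged_genes
        covered = set(fc.table.index)
        out["per_mode_fc_rate"] = {
            m: _rate(len(flagged & truth.genes_by_mode(m)),
                     len(covered & truth.genes_by_mode(m)))
            for m in MODES
        }
    return out
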