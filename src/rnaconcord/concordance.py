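"""Genome-wide concordance summaries.

Three views of cross-pipeline agreement:

* per-gene correlation between two sources across the shared samples
  (Pearson or Spearman, on log2(TPM + 0.001) by default, with the count
  of genes at or above a reporting threshold, conventionally 0.8);
* per-gene Spearman correlation between mRNA abundance and a matched
  protein-abundance table;
* PCA of samples (gene-wise mean centering, no variance scaling, as in
  R's ``prcomp`` default) with per-component variance-explained
  fractions, used to ask whether samples cluster by pipeline or by
  biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from .matrix import ExpressionMatrix, MultiSourceDataset, Unit
from .normalize import DEFAULT_PSEUDOCOUNT

__all__ = ["CorrelationResult", "PCAResult", "per_gene_correlation",
           "protein_mrna_correlation", "pca", "pc1_source_separation",
           "classify_discordance_mode"]


@dataclass
class CorrelationResult:
    """Per-gene correlation coefficients for one source comparison.

    Genes whose vector is constant in either input have no defined
    coefficient; they are reported as NaN and excluded from ``n_above``
    (not coerced to 0, which would silently shift the threshold counts).
    """

    coefficients: pd.Series
    method: str
    comparison: str
    n_samples: int
    threshold: float = 0.8

    @property
    def n_above(self) -> int:
        return int((self.coefficients >= self.threshold).sum())

    @property
    def n_defined(self) -> int:
        return int(self.coefficients.notna().sum())


@dataclass
class PCAResult:
    """Sample coordinates and variance-explained fractions."""

    coordinates: pd.DataFrame  # samples × components
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        ve = np.asarray(self.variance_explained, dtype=float)
        if (ve < -1e-12).any() or ve.sum() > 1 + 1e-9:
            raise ValueError("variance_explained must be fractions summing to at most 1")


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r of matching rows of two genes × samples arrays.

    Rows where either side has zero variance get NaN.
    """
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    ss_a = (a_c ** 2).sum(axis=1)
    ss_b = (b_c ** 2).sum(axis=1)
    denom = np.sqrt(ss_a * ss_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a_c * b_c).sum(axis=1) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def _corr_frames(df_a: pd.DataFrame, df_b: pd.DataFrame, method: str) -> pd.Series:
    a = df_a.to_numpy(dtype=float)
    b = df_b.to_numpy(dtype=float)
    if method == "spearman":
        a = rankdata(a, axis=1)
        b = rankdata(b, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(_rowwise_pearson(a, b), index=df_a.index, name=method)


def per_gene_correlation(dataset: MultiSourceDataset, source_a: str, source_b: str,
                         method: str = "pearson", on_log: bool = True,
                         pseudocount: float = DEFAULT_PSEUDOCOUNT,
                         threshold: float = 0.8) -> CorrelationResult:
    """Correlate each gene's profile between two sources over shared samples.

    With ``on_log`` (default) linear-unit inputs are transformed to
    log2(value + pseudocount) first; LOG2TPM inputs are used as-is.
    """
    mat_a = dataset[source_a]
    mat_b = dataset[source_b]
    n = len(dataset.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 shared samples")
    df_a, df_b = mat_a.data, mat_b.data
    if on_log and dataset.unit is not Unit.LOG2TPM:
        df_a = np.log2(df_a + pseudocount)
        df_b = np.log2(df_b + pseudocount)
    coeff = _corr_frames(df_a, df_b, method)
    return CorrelationResult(coefficients=coeff, method=method,
                             comparison=f"{source_a}-{source_b}",
                             n_samples=n, threshold=threshold)


def protein_mrna_correlation(expr: ExpressionMatrix, protein: ExpressionMatrix,
                             method: str = "spearman",
                             threshold: float = 0.8) -> CorrelationResult:
    """Per-gene correlation of mRNA and protein abundance on matched samples.

    Restricted to genes and samples present in both inputs; Spearman by
    default since protein (e.g. RPPA) and mRNA scales are not comparable.
    Ties are handled by average ranks.
    """
    genes = expr.gene_ids.intersection(protein.gene_ids).sort_values()
    samples = expr.sample_ids.intersection(protein.sample_ids).sort_values()
    if len(genes) == 0:
        raise ValueError("no genes shared between expression and protein tables")
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")
    coeff = _corr_frames(expr.data.loc[genes, samples],
                         protein.data.loc[genes, samples], method)
    return CorrelationResult(coefficients=coeff, method=method,
                             comparison=f"{expr.source}-protein",
                             n_samples=len(samples), threshold=threshold)


def pca(matrix: ExpressionMatrix, k: int = 2) -> PCAResult:
    """PCA of samples in gene space (genes mean-centered, not scaled)."""
    n_genes, n_samples = matrix.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if k > min(n_genes, n_samples):
        raise ValueError(f"k={k} exceeds min(n_genes, n_samples)")
    model = PCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(matrix.values.T)  # samples × k
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=matrix.sample_ids, columns=cols),
        variance_explained=model.explained_variance_ratio_,
    )


def pc1_source_separation(result: PCAResult, labels) -> float:
    """Fraction of PC1 variance explained by a sample grouping (eta squared).

    Used to quantify how strongly the leading component separates
    pipelines: near 1 means PC1 is essentially a pipeline axis, near 0
    means pipelines are mixed along it.
    """
    pc1 = result.coordinates.iloc[:, 0].to_numpy()
    labels = np.asarray(labels)
    if labels.shape[0] != pc1.shape[0]:
        raise ValueError("one label per sample required")
    grand = pc1.mean()
    ss_total = ((pc1 - grand) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_between = sum(
        (pc1[labels == g].mean() - grand) ** 2 * (labels == g).sum()
        for g in np.unique(labels)
    )
    return float(ss_between / ss_total)


def classify_discordance_mode(dataset: MultiSourceDataset, gene: str,
                              source_a: str, source_b: str,
                              pseudocount: float = DEFAULT_PSEUDOCOUNT,
                              r_uncorrelated: float = 0.3,
                              offset_sd_max: float = 0.3,
                              offset_log2_min: float = 1.0) -> str:
    """Heuristic label for *how* two sources disagree on one gene.

    This is a descriptive heuristic invented for this package, not an
    established method: it inspects the per-sample log2 offsets
    d_s = log2(a_s + c) − log2(b_s + c) and the cross-source Pearson r
    and returns one of

    * ``"uncorrelated"``    — r < ``r_uncorrelated``: the two profiles
      carry essentially unrelated information;
    * ``"scaling"``         — offsets are near-constant (sd ≤
      ``offset_sd_max``) with |median| > ``offset_log2_min``: a simple
      multiplicative factor separates the sources;
    * ``"sample_specific"`` — correlated overall but with heterogeneous
      offsets: the disagreement is confined to a subset of samples;
    * ``"concordant"``      — near-constant offsets of negligible size.

    The thresholds are conventions, tuned for log2-TPM data; treat the
    labels as triage, not ground truth.
    """
    u = np.log2(dataset[source_a].data.loc[gene].to_numpy(dtype=float) + pseudocount)
    v = np.log2(dataset[source_b].data.loc[gene].to_numpy(dtype=float) + pseudocount)
    if np.std(u) == 0 or np.std(v) == 0:
        return "concordant" if np.allclose(u, v) else "scaling"
    r = float(np.corrcoef(u, v)[0, 1])
    if abs(r) < r_uncorrelated:
        return "uncorrelated"
    d = u - v
    if np.std(d) <= offset_sd_max:
        return "scaling" if abs(float(np.median(d))) > offset_log2_min else "concordant"
    return "sample_specific"
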