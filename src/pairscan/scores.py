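"""Single-sample gene-set and phenotype scoring.

Covers the rank-weighted ECDF-difference ssGSEA statistic, bounded
AR/neuroendocrine phenotype scores (correlation to a signed template),
4-subtype transcription-factor scores with change-PCA outlier detection,
and per-gene isoform fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GeneSet",
    "ssgsea",
    "ssgsea_matrix",
    "ar_ne_scores",
    "subtype_scores",
    "change_pca_outliers",
    "isoform_fractions",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set, optionally with per-gene direction (+1/-1)."""

    name: str
    genes: tuple[str, ...]
    directions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")
        if self.directions is not None:
            dirs = tuple(int(d) for d in self.directions)
            object.__setattr__(self, "directions", dirs)
            if len(dirs) != len(genes):
                raise ValueError("directions length mismatch")
            if not set(dirs) <= {-1, 1}:
                raise ValueError("directions must be +1/-1")

    def __len__(self) -> int:
        return len(self.genes)


def ssgsea(
    expr: pd.Series,
    gene_set: GeneSet,
    tau: float = 0.25,
) -> float:
    """Single-sample gene-set enrichment score of one expression column.

    Genes are ranked by decreasing expression (ties mid-ranked); the in-set
    empirical CDF is weighted by rank^tau, the out-set ECDF is unweighted;
    the score is the sum over all ranked positions of (ECDF_in - ECDF_out).
    Rank-based, hence invariant under strictly increasing transforms of the
    expression values.
    """
    genes = pd.Index(expr.index)
    members = set(gene_set.genes) & set(genes)
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the matrix")
    if len(members) == len(genes):
        raise ValueError(f"gene set {gene_set.name!r} covers every gene (empty out-set)")
    vals = expr.to_numpy(dtype=float)
    n = vals.size
    ranks = sps.rankdata(vals)  # mid-ranks; highest expression -> largest rank
    order = np.argsort(-vals, kind="mergesort")  # decreasing, stable for ties
    in_set = np.asarray([g in members for g in genes])

    ranked_in = in_set[order]
    weights = ranks[order] ** tau
    in_weights = np.where(ranked_in, weights, 0.0)
    total_in = in_weights.sum()
    cdf_in = np.cumsum(in_weights) / total_in
    cdf_out = np.cumsum(~ranked_in) / (n - len(members))
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_matrix(
    expr: pd.DataFrame,
    gene_sets: list[GeneSet],
    tau: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA scores for every (sample, gene set) combination.

    ``normalize=True`` divides all scores by (max - min) across the whole
    score matrix, putting sets and samples on a shared unit scale.
    """
    out = pd.DataFrame(
        {
            gs.name: [ssgsea(expr[c], gs, tau) for c in expr.columns]
            for gs in gene_sets
        },
        index=expr.columns,
    )
    if normalize:
        span = out.to_numpy().max() - out.to_numpy().min()
        if span > 0:
            out = out / span
    return out


def _zscore_rows(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("gene with zero variance across samples")
    return (mat - mu) / sd


def _template_scores(expr: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Cosine similarity of each sample's z-scored set expression with the
    set's +1/-1 direction template. Bounded in [-1, 1] and defined even for
    one-directional templates (where centered correlation would degenerate)."""
    idx = [g for g in gene_set.genes if g in expr.index]
    if len(idx) < 3:
        raise ValueError(
            f"gene set {gene_set.name!r}: fewer than 3 usable genes in matrix"
        )
    template = np.asarray(
        [d for g, d in zip(gene_set.genes, gene_set.directions or
                           (1,) * len(gene_set.genes)) if g in expr.index],
        dtype=float,
    )
    z = _zscore_rows(expr.loc[idx].to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        sim = (z.T @ template) / (np.linalg.norm(z, axis=0) * np.linalg.norm(template))
    return pd.Series(sim, index=expr.columns)


def ar_ne_scores(
    expr: pd.DataFrame,
    ar_set: GeneSet,
    ne_set: GeneSet,
    ne_high_threshold: float = 0.4,
) -> pd.DataFrame:
    """Bounded AR-program and neuroendocrine-program scores per sample.

    Each score is the cosine similarity between the sample's z-scored
    expression over the set genes and the set's signed template; range
    [-1, 1], so a fixed threshold (e.g. NE > 0.4) is meaningful.
    ``ne_high`` flags NE score > threshold (default 0.4).
    """
    ar = _template_scores(expr, ar_set)
    ne = _template_scores(expr, ne_set)
    return pd.DataFrame(
        {"ar_score": ar, "ne_score": ne, "ne_high": ne > ne_high_threshold}
    )


def subtype_scores(expr: pd.DataFrame, tf_sets: list[GeneSet]) -> pd.DataFrame:
    """Per-sample subtype scores: mean z-scored expression of each set's TFs."""
    cols = {}
    for gs in tf_sets:
        idx = [g for g in gs.genes if g in expr.index]
        if not idx:
            raise ValueError(f"subtype set {gs.name!r} has no genes in the matrix")
        z = _zscore_rows(expr.loc[idx].to_numpy(dtype=float))
        cols[gs.name] = z.mean(axis=0)
    return pd.DataFrame(cols, index=expr.columns)


@dataclass
class ChangePcaResult:
    deltas: pd.DataFrame  # pairs x scores
    pc_scores: pd.DataFrame  # pairs x components
    mahalanobis_sq: pd.Series
    outliers: list[str]
    dropped_columns: list[str]
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.array([]))


def change_pca_outliers(
    deltas: pd.DataFrame,
    n_components: int = 2,
    quantile: float = 0.95,
) -> ChangePcaResult:
    """PCA on per-pair score changes; flag pairs with exceptional transitions.

    Columns are centered and unit-scaled (constant columns dropped with a
    warning via the result), then the squared Mahalanobis distance in the
    leading-PC space is compared with the chi-square quantile
    (default 0.95, df = number of components kept).
    """
    if len(deltas) < 4:
        raise ValueError("need >= 4 pairs for the change PCA")
    sd = deltas.std(axis=0, ddof=0)
    dropped = list(deltas.columns[sd == 0])
    use = deltas.loc[:, sd > 0]
    if use.shape[1] == 0:
        zero = pd.Series(np.zeros(len(deltas)), index=deltas.index)
        return ChangePcaResult(deltas, pd.DataFrame(index=deltas.index), zero, [], dropped)
    z = (use - use.mean(axis=0)) / use.std(axis=0, ddof=0)
    u, s, _ = np.linalg.svd(z.to_numpy(), full_matrices=False)
    k = min(n_components, int(np.sum(s > 1e-12)))
    scores = u[:, :k] * s[:k]
    var = s**2 / len(deltas)
    sd_pc = np.std(scores, axis=0, ddof=0)
    d2 = ((scores / sd_pc) ** 2).sum(axis=1) if k else np.zeros(len(deltas))
    thresh = sps.chi2.ppf(quantile, df=max(k, 1))
    d2 = pd.Series(d2, index=deltas.index, name="mahalanobis_sq")
    outliers = list(d2.index[d2 > thresh])
    return ChangePcaResult(
        deltas,
        pd.DataFrame(scores, index=deltas.index,
                     columns=[f"PC{i+1}" for i in range(k)]),
        d2,
        outliers,
        dropped,
        var[:k] / var.sum() if var.sum() > 0 else np.array([]),
    )


def isoform_fractions(
    transcript_table: pd.DataFrame,
    gene: str,
) -> pd.DataFrame:
    """Per-sample transcript fractions of one gene.

    ``transcript_table`` columns: transcript_id, gene, then one abundance
    column per sample. Fractions are each transcript's abundance over the
    summed abundance of all the gene's transcripts; samples where that sum
    is zero are undefined (NaN, flagged via the ``defined`` row attribute).
    """
    sub = transcript_table[transcript_table["gene"] == gene]
    if sub.empty:
        raise ValueError(f"no transcripts for gene {gene!r}")
    sample_cols = [c for c in sub.columns if c not in ("transcript_id", "gene")]
    ab = sub[sample_cols].to_numpy(dtype=float)
    if np.any(ab < 0):
        raise ValueError("negative abundance")
    totals = ab.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, ab / totals, np.nan)
    out = pd.DataFrame(frac, index=sub["transcript_id"].tolist(), columns=sample_cols)
    out.attrs["defined"] = dict(zip(sample_cols, totals > 0))
    return out
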