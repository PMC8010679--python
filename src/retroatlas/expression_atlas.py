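"""Transcriptome-atlas statistics over a gene x (sample, replicate) count table.

The raw expression measure is the total number of reads mapped to a gene
(TGR). Libraries are normalised with the median-of-ratios ("DESeq median")
size-factor method; downstream statistics are

* expressed-gene calls: normalised TGR >= threshold (default 5, inclusive)
  in *both* biological replicates of a sample;
* expression breadth: Shannon entropy (bits) of the replicate-averaged
  normalised profile across samples — low entropy marks tissue-specific
  genes;
* expression stability: SD/mean (coefficient of variation) of the
  replicate-averaged profile, for reference-gene selection;
* sample relatedness: distance 1 - r^2 on replicate-averaged profiles,
  clustered agglomeratively (UPGMA by default) into a newick dendrogram.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

DEFAULT_EXPRESSION_THRESHOLD = 5.0
DEFAULT_STABILITY_THRESHOLDS = (0.2, 0.25, 0.3)

_COLUMN_RE = re.compile(r"^(?P<sample>.+)\.(?P<rep>\d+)$")


def split_columns(columns) -> pd.DataFrame:
    """Parse ``SAMPLE.REP`` column labels into (sample, replicate) pairs."""
    rows = []
    for col in columns:
        m = _COLUMN_RE.match(str(col))
        if not m:
            raise ValueError(f"column {col!r} is not of the form SAMPLE.REP")
        rows.append({"column": col, "sample": m.group("sample"),
                     "replicate": int(m.group("rep"))})
    return pd.DataFrame(rows)


def _check_two_replicates(columns) -> dict[str, list]:
    meta = split_columns(columns)
    groups = {s: list(g["column"]) for s, g in meta.groupby("sample", sort=False)}
    bad = {s: cols for s, cols in groups.items() if len(cols) != 2}
    if bad:
        raise ValueError(
            f"every sample needs exactly 2 replicate columns; offending samples: {sorted(bad)}")
    return groups


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    The per-gene reference is the geometric mean across columns, computed
    over genes with strictly positive counts everywhere; each column's
    factor is the median over those genes of count/reference.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every column; cannot form the "
            "geometric-mean reference (pseudo-reference fallback is disabled)")
    sub = mat[allpos]
    logref = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - logref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each column by its size factor."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or not (factors > 0).all():
        raise ValueError("size factors must be positive and cover every column")
    return counts / factors


def call_expressed(normalized: pd.DataFrame,
                   threshold: float = DEFAULT_EXPRESSION_THRESHOLD
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Expressed-gene calls: >= threshold in both replicates of a sample.

    Returns a genes x samples boolean frame and a summary tallying genes
    expressed in at least one sample, in all samples, and in none.
    """
    groups = _check_two_replicates(normalized.columns)
    calls = pd.DataFrame(
        {s: (normalized[cols] >= threshold).all(axis=1) for s, cols in groups.items()},
        index=normalized.index)
    any_ = calls.any(axis=1)
    summary = {
        "n_genes": int(len(calls)),
        "expressed_any_sample": int(any_.sum()),
        "expressed_all_samples": int(calls.all(axis=1).sum()),
        "expressed_none": int((~any_).sum()),
    }
    return calls, summary


def sample_means(normalized: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged normalised expression, genes x samples."""
    groups = _check_two_replicates(normalized.columns)
    return pd.DataFrame(
        {s: normalized[cols].mean(axis=1) for s, cols in groups.items()},
        index=normalized.index)


def expression_breadth(normalized: pd.DataFrame,
                       calls: pd.DataFrame | None = None) -> pd.DataFrame:
    """Shannon-entropy expression breadth per gene.

    Each gene's replicate-averaged profile is renormalised to a probability
    distribution over samples; H = -sum p_s log2 p_s (0 log 0 := 0), so H
    ranges from 0 (single-sample specialists) to log2(S) (perfectly broad).
    All-zero genes get NaN entropy. If ``calls`` is supplied the per-gene
    expressed-sample count is included.
    """
    means = sample_means(normalized)
    mat = means.to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = mat / totals[:, None]
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -plogp.sum(axis=1)
    entropy[totals == 0] = np.nan
    out = pd.DataFrame({"entropy_bits": entropy}, index=means.index)
    if calls is not None:
        out["n_samples_expressed"] = calls.reindex(means.index).sum(axis=1).astype(int)
    return out


def stability_ranking(normalized: pd.DataFrame,
                      thresholds=DEFAULT_STABILITY_THRESHOLDS,
                      ddof: int = 0,
                      replicate_averaged: bool = True
                      ) -> tuple[pd.DataFrame, dict[float, int]]:
    """SD/mean expression stability per gene, ranked most-stable first.

    By default the dispersion is the population SD (``ddof=0``) over the
    replicate-averaged per-sample values; both choices are configurable.
    Genes with zero mean are excluded (flagged in the returned frame's
    ``excluded_zero_mean`` attr) since SD/mean is undefined for them.
    Threshold counts report how many genes fall under each cutoff.
    """
    values = sample_means(normalized) if replicate_averaged else normalized
    mat = values.to_numpy(dtype=float)
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=ddof)
    keep = mean > 0
    ranking = pd.DataFrame({
        "mean": mean[keep],
        "sd": sd[keep],
        "sd_over_mean": sd[keep] / mean[keep],
    }, index=values.index[keep]).sort_values("sd_over_mean", kind="mergesort")
    ranking.attrs["excluded_zero_mean"] = [str(g) for g in values.index[~keep]]
    counts = {float(t): int((ranking["sd_over_mean"] < t).sum()) for t in thresholds}
    return ranking, counts


def sample_distance(normalized: pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample distance 1 - r^2 on replicate-averaged profiles."""
    means = sample_means(normalized)
    if means.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = means.to_numpy(dtype=float)
    sd = mat.std(axis=0)
    flat = [means.columns[j] for j in np.nonzero(sd == 0)[0]]
    if flat:
        raise ValueError(f"zero-variance sample(s) {flat}: correlation undefined")
    r = np.corrcoef(mat.T)
    d = 1.0 - r ** 2
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)  # symmetrise against float noise
    return pd.DataFrame(d, index=means.columns, columns=means.columns)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative sample tree with its linkage matrix and newick form."""

    newick: str
    linkage_matrix: np.ndarray
    labels: tuple[str, ...]


def cluster_samples(distance: pd.DataFrame, method: str = "average") -> Dendrogram:
    """Agglomeratively cluster samples from a distance matrix.

    Default linkage is UPGMA ("average"), under which node heights are
    ultrametric. Returns the newick string (with branch lengths) alongside
    the scipy linkage matrix.
    """
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or list(distance.index) != list(distance.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix diagonal must be zero")
    labels = tuple(str(c) for c in distance.columns)
    if len(labels) < 2:
        raise ValueError("need at least 2 samples to cluster")
    condensed = squareform(d, checks=False)
    z = linkage(condensed, method=method)
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(z, list(labels))
    newick = str(tree).strip()
    return Dendrogram(newick=newick, linkage_matrix=z, labels=labels)
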