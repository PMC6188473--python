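"""Count normalization, expression units, and sample-level exploration.

Expression units are computed over whole-gene lengths (UTRs included):
FPKM = count / ((length/1e3) * (library/1e6)), and TPM renormalizes the
per-kilobase rate so each sample sums to one million.  Size factors use
the median-of-ratios estimator.  The variance-stabilizing transform is
log2(normalized count + 1): downstream uses (clustering, correlation,
PCA) only require a monotone variance-stabilizing transform.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.decomposition import PCA

from .io import CountMatrix


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, CountMatrix):
        return counts.to_frame()
    return counts


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples; genes with a
    zero in any sample are excluded from the reference.  Each sample's
    factor is the median over reference genes of count / reference.
    """
    df = _as_frame(counts)
    arr = df.to_numpy(dtype=float)
    if arr.shape[1] == 1:
        return pd.Series([1.0], index=df.columns, name="size_factor")
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has nonzero counts in every sample; "
                         "cannot form the median-of-ratios reference")
    ref = np.exp(np.mean(np.log(arr[allpos]), axis=1))
    factors = np.median(arr[allpos] / ref[:, None], axis=0)
    if (factors <= 0).any():
        raise ValueError("non-positive size factor (degenerate library)")
    return pd.Series(factors, index=df.columns, name="size_factor")


def fpkm(counts, lengths_bp: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million, over whole-gene lengths."""
    df = _as_frame(counts)
    lengths = lengths_bp.reindex(df.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:5].tolist()
        raise KeyError(f"gene lengths missing for {missing}")
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 bp")
    totals = df.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = df.columns[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    return df.div(lengths.to_numpy() / 1e3, axis=0).div(totals / 1e6, axis=1)


def tpm(counts, lengths_bp: pd.Series) -> pd.DataFrame:
    """Transcripts per million over whole-gene lengths; columns sum to 1e6."""
    df = _as_frame(counts)
    lengths = lengths_bp.reindex(df.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:5].tolist()
        raise KeyError(f"gene lengths missing for {missing}")
    rate = df.div(lengths.to_numpy(), axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = denom.index[denom == 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    return rate.div(denom, axis=1) * 1e6


def variance_stabilize(counts, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(size-factor-normalized count + 1)."""
    df = _as_frame(counts)
    if factors is None:
        factors = size_factors(df)
    return np.log2(df.div(factors.reindex(df.columns).to_numpy(), axis=1) + 1.0)


def top_variable_genes(stabilized: pd.DataFrame, n: int = 250) -> list[str]:
    """The n genes with largest across-sample variance; ties break by gene id."""
    if n > stabilized.shape[0]:
        raise ValueError(f"n={n} exceeds number of genes {stabilized.shape[0]}")
    var = stabilized.var(axis=1, ddof=1)
    order = sorted(stabilized.index, key=lambda g: (-var[g], g))
    return order[:n]


def correlation_and_clustering(stabilized: pd.DataFrame,
                               genes: Sequence[str] | None = None
                               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Pairwise Pearson correlation between samples plus a complete-linkage
    Euclidean dendrogram (linkage matrix) over samples."""
    mat = stabilized.loc[list(genes)] if genes is not None else stabilized
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sds = mat.std(axis=0, ddof=0)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise ValueError(f"sample {bad!r} has zero variance; correlation undefined")
    corr = mat.corr(method="pearson")
    linkage = sch.linkage(mat.T.to_numpy(), method="complete", metric="euclidean")
    return corr, linkage


def pca_scores_loadings(stabilized: pd.DataFrame,
                        genes: Sequence[str] | None = None,
                        n_components: int | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """PCA over samples with genes centered (not scaled).

    Returns (scores per sample, loadings per gene, proportion of variance
    per component).  Loadings let the highest-|loading| genes per component
    be listed.
    """
    mat = stabilized.loc[list(genes)] if genes is not None else stabilized
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = mat.T.to_numpy(dtype=float)  # samples x genes
    k = n_components or min(X.shape[0], X.shape[1])
    pca = PCA(n_components=min(k, min(X.shape)))
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=mat.columns, columns=comp_names),
            pd.DataFrame(pca.components_.T, index=mat.index, columns=comp_names),
            pd.Series(pca.explained_variance_ratio_, index=comp_names,
                      name="proportion_variance"))
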