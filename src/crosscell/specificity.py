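"""Replicate-aware specificity index (SI) ranking.

The SI asks, for each gene and cell type, how enriched the gene is in
that cell type relative to every other profiled cell type.  Inputs are
floored log10(FPKM) values summarized per cell type as a mean and a
standard deviation across replicates.  For a target cell type A, the
gene's expression difference against each other cell type B is ranked
across genes (rank 1 = largest enrichment, average ranks on ties); the
SI value is the mean of those ranks over all B, and the specificity rank
orders genes by ascending SI (rank 1 = most specific).

Replicate uncertainty enters by resampling: each iteration draws one
value per (gene, cell type) from Normal(mean, sd), re-floors negative
draws at 0, computes specificity ranks, and the final table averages the
specificity rank across iterations.  Draws below zero are re-floored so
sampled values stay in the same support as the inputs.  With all sd = 0
the resampled ranking collapses exactly to the deterministic one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix
from .normalize import fpkm as _fpkm

MIN_GENE_LENGTH = 1000


@dataclass
class SpecificityInput:
    """Per-gene per-cell-type mean and sd of floored log10(FPKM)."""

    means: pd.DataFrame  # genes x cell types
    sds: pd.DataFrame    # genes x cell types

    def __post_init__(self) -> None:
        if not self.means.index.equals(self.sds.index) or \
                not self.means.columns.equals(self.sds.columns):
            raise ValueError("means and sds must share index and columns")
        if (self.sds.to_numpy() < 0).any():
            raise ValueError("standard deviations must be >= 0")
        if self.means.shape[1] < 2:
            raise ValueError("need at least 2 cell types")

    @property
    def cell_types(self) -> list[str]:
        return list(self.means.columns)


def si_preprocess(counts, sample_table: pd.DataFrame,
                  lengths_bp: pd.Series,
                  min_length: int = MIN_GENE_LENGTH) -> SpecificityInput:
    """FPKM -> log10 -> floor at 0 -> per-cell-type mean/sd across replicates.

    Genes shorter than ``min_length`` (default 1 kb) are excluded to avoid
    biases from extremely short genes; the log10 floor avoids biases from
    long, non-expressed genes.
    """
    df = counts.to_frame() if isinstance(counts, CountMatrix) else counts
    cell_types = sample_table.set_index("sample_id")["cell_type"]
    if cell_types.reindex(df.columns).isna().any():
        raise KeyError("every sample column needs a cell_type in the sample table")
    if cell_types.reindex(df.columns).nunique() < 2:
        raise ValueError("need at least 2 cell types")
    lengths = lengths_bp.reindex(df.index)
    keep = lengths >= min_length
    df = df.loc[keep]
    vals = _fpkm(df, lengths[keep])
    with np.errstate(divide="ignore"):
        logged = np.log10(vals.to_numpy())
    logged = np.maximum(logged, 0.0)
    logged = pd.DataFrame(logged, index=vals.index, columns=vals.columns)
    ct = cell_types.reindex(df.columns)
    means = logged.T.groupby(ct).mean().T
    sds = logged.T.groupby(ct).std(ddof=1).fillna(0.0).T
    return SpecificityInput(means=means, sds=sds)


def _rank_avg(values: np.ndarray) -> np.ndarray:
    """Ascending rank along axis 0 with average ranks on ties.

    Equivalent to ``scipy.stats.rankdata(values, axis=0)`` but an order of
    magnitude faster on wide arrays (one argsort plus vectorized tie-group
    averaging), which matters at 1000 resampling iterations.
    """
    v = np.asarray(values, dtype=float)
    squeeze = v.ndim == 1
    if squeeze:
        v = v[:, None]
    G = v.shape[0]
    # rank along the last axis of the transposed copy: contiguous memory
    # makes the elementwise passes ~10x faster than axis-0 operations
    vt = np.ascontiguousarray(np.moveaxis(v, 0, -1))
    order = np.argsort(vt, axis=-1, kind="stable")
    sv = np.take_along_axis(vt, order, axis=-1)
    idx = np.broadcast_to(np.arange(G), sv.shape)
    is_new = np.empty(sv.shape, dtype=bool)
    is_new[..., 0] = True
    is_new[..., 1:] = sv[..., 1:] != sv[..., :-1]
    start = np.maximum.accumulate(np.where(is_new, idx, -1), axis=-1)
    is_last = np.empty(sv.shape, dtype=bool)
    is_last[..., -1] = True
    is_last[..., :-1] = is_new[..., 1:]
    end = np.flip(np.minimum.accumulate(
        np.flip(np.where(is_last, idx, G), axis=-1), axis=-1), axis=-1)
    avg = (start + end) / 2.0 + 1.0
    ranks_t = np.empty(sv.shape, dtype=float)
    np.put_along_axis(ranks_t, order, avg, axis=-1)
    ranks = np.moveaxis(ranks_t, -1, 0)
    return ranks[:, 0] if squeeze else ranks


def _rank_desc(values: np.ndarray) -> np.ndarray:
    """Descending rank along axis 0, average ranks on ties."""
    return _rank_avg(-np.asarray(values, dtype=float))


def _specificity_from_values(values: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """SI values and specificity ranks from a genes x cell types (x draws)
    array of expression values."""
    G, C = values.shape[0], values.shape[1]
    acc = np.zeros_like(values, dtype=values.dtype)
    # rank each unordered pair once: with average ties the descending rank
    # of (B - A) is exactly G + 1 - the descending rank of (A - B)
    for a in range(C):
        for b in range(a + 1, C):
            r = _rank_desc(values[:, a] - values[:, b])
            acc[:, a] += r
            acc[:, b] += (G + 1) - r
    si = acc / (C - 1)
    ranks = _rank_avg(si)
    return si, ranks


def si_deterministic(means: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SI values and specificity ranks from per-cell-type means alone."""
    if means.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    si, ranks = _specificity_from_values(means.to_numpy(dtype=float))
    return (pd.DataFrame(si, index=means.index, columns=means.columns),
            pd.DataFrame(ranks, index=means.index, columns=means.columns))


@dataclass
class SpecificityTable:
    """Specificity ranks averaged over resampling iterations."""

    ranks: pd.DataFrame  # genes x cell types, averaged rank in [1, G]
    iterations: int
    seed: int | None

    @property
    def cell_types(self) -> list[str]:
        return list(self.ranks.columns)


def si_sampled(inp: SpecificityInput, iterations: int = 1000,
               seed: int | None = 0, chunk: int = 250) -> SpecificityTable:
    """Average specificity ranks over normal-resampled expression draws.

    Each iteration draws Normal(mean, sd) independently per (gene, cell
    type), re-floored at 0, and ranks as in :func:`si_deterministic`.
    Deterministic for a fixed seed; iterations are drawn from one named
    generator in a fixed order.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    means = inp.means.to_numpy(dtype=float)
    sds = inp.sds.to_numpy(dtype=float)
    G, C = means.shape
    total = np.zeros((G, C), dtype=float)
    done = 0
    while done < iterations:
        t = min(chunk, iterations - done)
        draws = rng.normal(means[:, :, None], sds[:, :, None], size=(G, C, t))
        np.maximum(draws, 0.0, out=draws)
        _, ranks = _specificity_from_values(draws)
        total += ranks.sum(axis=2)
        done += t
    avg = total / iterations
    table = pd.DataFrame(avg, index=inp.means.index, columns=inp.means.columns)
    return SpecificityTable(ranks=table, iterations=iterations, seed=seed)


def top_specific_genes(table: SpecificityTable | pd.DataFrame,
                       cell_type: str, k: int = 20) -> list[str]:
    """The k genes with smallest averaged rank for a cell type; ties by id."""
    ranks = table.ranks if isinstance(table, SpecificityTable) else table
    if k > ranks.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes {ranks.shape[0]}")
    col = ranks[cell_type]
    return sorted(ranks.index, key=lambda g: (col[g], g))[:k]


def si_rank_concordance(table_a: SpecificityTable | pd.DataFrame,
                        table_b: SpecificityTable | pd.DataFrame,
                        cell_type: str, top_n: int = 100) -> pd.DataFrame:
    """Ranks of A's top_n most specific genes looked up in B.

    Genes absent from B are flagged ``missing`` rather than dropped, so
    cross-species rank comparisons cannot silently lose genes.
    """
    ra = table_a.ranks if isinstance(table_a, SpecificityTable) else table_a
    rb = table_b.ranks if isinstance(table_b, SpecificityTable) else table_b
    if len(ra.index.intersection(rb.index)) == 0:
        raise ValueError("gene universes of the two tables are disjoint")
    top = top_specific_genes(ra, cell_type, min(top_n, ra.shape[0]))
    rows = []
    for g in top:
        in_b = g in rb.index
        rows.append((g, float(ra.loc[g, cell_type]),
                     float(rb.loc[g, cell_type]) if in_b else np.nan,
                     not in_b))
    return pd.DataFrame(rows, columns=["gene_id", "rank_a", "rank_b", "missing"])
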