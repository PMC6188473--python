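"""Peak annotation, region signal, sequence conservation, and SNP overlap.

Promoter windows span 1 kb upstream to 100 bp downstream of the TSS
(strand-aware; 1101 bp, clipped at the contig start).  A peak is a
promoter peak if it overlaps any promoter window by at least one base;
otherwise a gene-body peak if it overlaps any gene span; otherwise
"other".  Ambiguous overlaps resolve to the nearest TSS, then the
lexicographically smallest gene id.  Conservation scores are per-base
probabilities in [0, 1] stored as run-length tracks; bases not covered
by any run score 0, the usual convention for missing PhastCons values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import GeneModel

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100


def promoter_window(model: GeneModel,
                    upstream: int = PROMOTER_UPSTREAM,
                    downstream: int = PROMOTER_DOWNSTREAM) -> tuple[int, int]:
    """Strand-aware promoter interval, 0-based half-open, clipped at 0.

    Plus strand: [tss - upstream, tss + downstream + 1); minus strand
    mirrored.  The +1 converts the inclusive downstream endpoint into the
    half-open convention exactly once, here.
    """
    tss = model.tss
    if model.strand == "+":
        lo, hi = tss - upstream, tss + downstream + 1
    else:
        lo, hi = tss - downstream, tss + upstream + 1
    return max(lo, 0), hi


def promoter_windows(models, upstream: int = PROMOTER_UPSTREAM,
                     downstream: int = PROMOTER_DOWNSTREAM) -> pd.DataFrame:
    rows = []
    for m in models:
        lo, hi = promoter_window(m, upstream, downstream)
        rows.append({"gene_id": m.gene_id, "chrom": m.chrom,
                     "start": lo, "end": hi, "tss": m.tss})
    return pd.DataFrame(rows)


def _tss_distance(start: int, end: int, tss: int) -> int:
    """Distance from an interval to a TSS position (0 if contained)."""
    if start <= tss < end:
        return 0
    return min(abs(start - tss), abs(tss - (end - 1)))


def assign_peaks(peaks: pd.DataFrame, models,
                 upstream: int = PROMOTER_UPSTREAM,
                 downstream: int = PROMOTER_DOWNSTREAM) -> pd.DataFrame:
    """Annotate each peak as promoter / gene_body / other.

    Promoter assignment wins over gene body; the assigned gene is the one
    with the nearest TSS (promoter) or the largest overlap then nearest
    TSS (gene body); remaining ties break by gene id.  Peaks on contigs
    absent from the gene models raise a warning and stay category
    "other".
    """
    models = list(models)
    known_chroms = {m.chrom for m in models}
    windows = promoter_windows(models, upstream, downstream)
    out = peaks.copy()
    out["category"] = "other"
    out["gene_id"] = pd.NA
    by_chrom_models: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom_models.setdefault(m.chrom, []).append(m)
    win_by_chrom = dict(tuple(windows.groupby("chrom")))
    for i in out.index:
        chrom, start, end = out.at[i, "chrom"], out.at[i, "start"], out.at[i, "end"]
        if chrom not in known_chroms:
            warnings.warn(f"peak {out.at[i, 'peak_id']!r}: unknown contig "
                          f"{chrom!r}; categorized as other")
            continue
        w = win_by_chrom.get(chrom)
        best = None  # (tss_distance, gene_id)
        if w is not None:
            hit = w[(w["start"] < end) & (start < w["end"])]
            for r in hit.itertuples():
                cand = (_tss_distance(start, end, r.tss), r.gene_id)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            out.at[i, "category"] = "promoter"
            out.at[i, "gene_id"] = best[1]
            continue
        bestb = None  # (-overlap, tss_distance, gene_id)
        for m in by_chrom_models.get(chrom, []):
            overlap = min(end, m.end) - max(start, m.start)
            if overlap >= 1:
                cand = (-overlap, _tss_distance(start, end, m.tss), m.gene_id)
                if bestb is None or cand < bestb:
                    bestb = cand
        if bestb is not None:
            out.at[i, "category"] = "gene_body"
            out.at[i, "gene_id"] = bestb[2]
    return out


def _region_track_sums(track: pd.DataFrame, regions: pd.DataFrame
                       ) -> np.ndarray:
    """Sum of per-base track values over each region (missing bases = 0)."""
    sums = np.zeros(len(regions))
    track_by_chrom = dict(tuple(track.groupby("chrom")))
    for j, r in enumerate(regions.itertuples()):
        runs = track_by_chrom.get(r.chrom)
        if runs is None:
            continue
        lo = np.maximum(runs["start"].to_numpy(), r.start)
        hi = np.minimum(runs["end"].to_numpy(), r.end)
        ov = np.maximum(hi - lo, 0)
        sums[j] = float(np.sum(ov * runs["score"].to_numpy()))
    return sums


def region_signal_fpkm(coverage: pd.DataFrame, regions: pd.DataFrame
                       ) -> pd.Series:
    """log2(FPKM + 1) of read-equivalents over each region.

    ``coverage`` is a per-base read-depth bedGraph; the region signal is
    the summed coverage, normalized by region length (kb) and total track
    coverage (millions).
    """
    if (coverage["score"] < 0).any():
        raise ValueError("coverage must be non-negative")
    total = float(((coverage["end"] - coverage["start"])
                   * coverage["score"]).sum())
    if total == 0:
        raise ValueError("coverage track has zero total signal")
    sums = _region_track_sums(coverage, regions)
    lengths = (regions["end"] - regions["start"]).to_numpy(dtype=float)
    fpkm = sums / ((lengths / 1e3) * (total / 1e6))
    return pd.Series(np.log2(fpkm + 1.0), index=regions.index,
                     name="log2_fpkm")


def peak_conservation(track: pd.DataFrame, peaks: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of per-base conservation scores over each peak."""
    sums = _region_track_sums(track, peaks)
    lengths = (peaks["end"] - peaks["start"]).to_numpy(dtype=float)
    return pd.Series(sums / lengths, index=peaks.index, name="mean_conservation")


@dataclass
class GroupComparison:
    """Welch one-sided t comparison of per-peak mean conservation."""

    statistic: float
    pvalue: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    alternative: str


def compare_groups(values_a, values_b,
                   alternative: str = "less") -> GroupComparison:
    """Welch (unequal variance) t-test, one-sided by default (A < B)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 0.5
    else:
        res = scipy.stats.ttest_ind(a, b, equal_var=False,
                                    alternative=alternative)
        t, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(statistic=t, pvalue=p,
                           median_a=float(np.median(a)),
                           median_b=float(np.median(b)),
                           n_a=a.size, n_b=b.size, alternative=alternative)


def _per_base_scores(track_by_chrom, chrom: str, start: int, end: int
                     ) -> np.ndarray:
    scores = np.zeros(end - start)
    runs = track_by_chrom.get(chrom)
    if runs is None:
        return scores
    for r in runs.itertuples():
        lo, hi = max(r.start, start), min(r.end, end)
        if lo < hi:
            scores[lo - start:hi - start] = r.score
    return scores


def metagene_conservation(track: pd.DataFrame, peaks: pd.DataFrame,
                          n_bins: int = 100) -> np.ndarray:
    """Mean conservation per bin over length-normalized peaks.

    Each peak is rescaled to [0, 1]; base i of an L-base peak falls in bin
    floor(i * n_bins / L).  Per-bin per-base means are averaged across
    peaks; peaks shorter than n_bins leave their empty bins out of the
    average for that peak via linear base-to-bin assignment.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    track_by_chrom = dict(tuple(track.groupby("chrom")))
    profile = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for r in peaks.itertuples():
        scores = _per_base_scores(track_by_chrom, r.chrom, r.start, r.end)
        L = len(scores)
        bins = (np.arange(L) * n_bins) // L
        sums = np.bincount(bins, weights=scores, minlength=n_bins)
        per = np.bincount(bins, minlength=n_bins)
        present = per > 0
        profile[present] += sums[present] / per[present]
        counts[present] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, profile / counts, np.nan)


def filter_differential_peaks(peaks: pd.DataFrame,
                              fold_column: str = "fold_change") -> pd.DataFrame:
    """Keep peaks with |fold change| strictly greater than 2."""
    if fold_column not in peaks.columns:
        raise KeyError(f"peak table lacks column {fold_column!r}")
    return peaks.loc[peaks[fold_column].abs() > 2.0].copy()


def snp_overlap(snps: pd.DataFrame, peaks: pd.DataFrame
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP containing peaks plus summary counts per peak category.

    SNPs are 1-bp 0-based intervals; containment is half-open, so a SNP
    at position p is inside [start, end) iff start <= p < end.
    """
    assignments = []
    peaks_by_chrom = dict(tuple(peaks.groupby("chrom")))
    for s in snps.itertuples():
        pos = s.start
        sub = peaks_by_chrom.get(s.chrom)
        if sub is not None:
            hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
            for p in hit.itertuples():
                assignments.append({
                    "snp_id": s.snp_id, "chrom": s.chrom, "pos": pos,
                    "peak_id": p.peak_id, "category": p.category,
                    "gene_id": getattr(p, "gene_id", pd.NA),
                    "differential": bool(getattr(p, "differential", False))})
    per_snp = pd.DataFrame(assignments, columns=[
        "snp_id", "chrom", "pos", "peak_id", "category", "gene_id",
        "differential"])
    if len(per_snp):
        summary = (per_snp.groupby("category")["snp_id"].nunique()
                   .rename("n_snps").reset_index())
    else:
        summary = pd.DataFrame(columns=["category", "n_snps"])
    return per_snp, summary
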