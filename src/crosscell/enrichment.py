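"""Threshold cascades turning DE tables into species-enrichment calls,
the housekeeping reference set, and the exhaustive partition-resampling
null.

A gene is called enriched in species S within a cell type when it passes
every predicate of the cascade: adjusted p below a stringent cutoff
(default 1e-5), at least 4-fold change toward S, well expressed in the
contrast (base_mean > 400), and mean log2(FPKM) above 4 in the
higher-expressing species.  Genes differentially expressed between the
species in *all* cell types pooled (adjusted p below the cutoff, fold
change > 2, no expression cutoff) are pan-species differences and are
removed, so the calls isolate cell-type-specific species differences.

The printed cutoff "10e-5" literally equals 1e-4; the stringent reading
1e-5 is the default and the value is configurable.

Housekeeping genes are the conservation reference: well expressed in
both species (base_mean > 400, mean log2 FPKM > 4 in each) and showing
no evidence of a species difference (raw p > 0.2 over all samples).

The partition null guards a small-group contrast (e.g. 3 donors vs 13)
against chance structure: it reruns the DE contrast for every one of the
C(n, k) ways of splitting the donors into groups of size k and n-k and
records the number of significant genes for each.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .de import nb_wald_test
from .io import CountMatrix
from .normalize import size_factors as _size_factors


@dataclass
class EnrichmentThresholds:
    """Cascade thresholds with the study defaults."""

    alpha: float = 1e-5              # adjusted p cutoff, per-cell-type DE
    min_abs_log2fc: float = 2.0      # "at least 4-fold" (inclusive)
    min_base_mean: float = 400.0
    min_log2fpkm: float = 4.0        # in the higher-expressing species
    pan_alpha: float = 1e-5          # pan-species exclusion DE
    pan_min_abs_log2fc: float = 1.0  # "fold change > 2" (strict)
    housekeeping_p: float = 0.2      # raw p, not adjusted
    de_alpha: float = 0.01           # generic significance (partition null)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class EnrichmentCall:
    """Per (cell type, species) enriched gene sets with triggering stats."""

    calls: dict[tuple[str, str], pd.DataFrame]
    pan_species_genes: pd.Index
    thresholds: EnrichmentThresholds

    def genes(self, cell_type: str, species: str) -> list[str]:
        key = (cell_type, species)
        return list(self.calls[key].index) if key in self.calls else []


def pan_species_set(de_by_celltype: Mapping[str, pd.DataFrame],
                    de_all: pd.DataFrame,
                    thresholds: EnrichmentThresholds,
                    mode: str = "combined") -> pd.Index:
    """Genes differentially expressed between species in all cell types.

    ``combined`` (default) takes significance (adjusted p) from the
    all-samples species contrast, where evidence accumulates over every
    replicate, and requires the fold-change condition with a consistent
    sign in every cell type's own DE table — the literal "fold change > 2
    ... in all cell types".  ``intersection`` requires both padj and fold
    per cell type, which is fragile exactly when per-cell-type replication
    is thin; ``blocked`` thresholds only the pooled contrast, where a
    strong single-cell-type difference dilutes to roughly fold/n_ct and
    can sit at the fold cutoff.
    """
    def _fold(de: pd.DataFrame, sign: float) -> pd.Series:
        return (de["log2fc"] * sign > thresholds.pan_min_abs_log2fc).fillna(False)

    def _sig(de: pd.DataFrame) -> pd.Series:
        return (de["padj"] < thresholds.pan_alpha).fillna(False)

    if mode == "blocked":
        mask = _sig(de_all) & (_fold(de_all, 1.0) | _fold(de_all, -1.0))
        return de_all.index[mask]
    if mode not in ("combined", "intersection"):
        raise ValueError(f"unknown pan-species mode {mode!r}")
    tables = list(de_by_celltype.values())
    idx = de_all.index
    up = pd.Series(True, index=idx)
    down = pd.Series(True, index=idx)
    for de in tables:
        fold_ok_up = _fold(de, 1.0)
        fold_ok_down = _fold(de, -1.0)
        if mode == "intersection":
            fold_ok_up &= _sig(de)
            fold_ok_down &= _sig(de)
        up &= fold_ok_up.reindex(idx, fill_value=False)
        down &= fold_ok_down.reindex(idx, fill_value=False)
    mask = up | down
    if mode == "combined":
        mask &= _sig(de_all)
    return idx[mask]


def call_species_enriched(de_by_celltype: Mapping[str, pd.DataFrame],
                          fpkm_means: pd.DataFrame,
                          de_all_celltypes: pd.DataFrame,
                          thresholds: EnrichmentThresholds | None = None,
                          species_pair: tuple[str, str] | None = None,
                          pan_mode: str = "combined") -> EnrichmentCall:
    """Apply the enrichment cascade per cell type, then the pan-species
    exclusion.

    ``de_by_celltype`` maps cell type to a DE table whose log2fc is the
    first species of ``species_pair`` over the second.  ``fpkm_means``
    carries mean log2(FPKM) per gene with MultiIndex columns
    (species, cell_type).
    """
    thr = thresholds or EnrichmentThresholds()
    if species_pair is None:
        first = next(iter(de_by_celltype.values()))
        info = first.attrs.get("design", {})
        if "numerator" not in info:
            raise ValueError("species_pair not given and not recoverable "
                             "from the DE table design")
        species_pair = (info["numerator"], info["denominator"])
    numerator, denominator = species_pair
    pan = pan_species_set(de_by_celltype, de_all_celltypes, thr, mode=pan_mode)

    calls: dict[tuple[str, str], pd.DataFrame] = {}
    for cell_type, de in de_by_celltype.items():
        for species, sign in ((numerator, 1.0), (denominator, -1.0)):
            lfc = de["log2fc"] * sign
            mask = ((de["padj"] < thr.alpha)
                    & (lfc >= thr.min_abs_log2fc)
                    & (de["base_mean"] > thr.min_base_mean)).fillna(False)
            candidates = de.index[mask]
            try:
                high = fpkm_means[(species, cell_type)].reindex(candidates)
            except KeyError as exc:
                raise KeyError(
                    f"fpkm summary missing for ({species}, {cell_type})") from exc
            if high.isna().any():
                missing = high.index[high.isna()][0]
                raise KeyError(f"fpkm summary missing for tested gene {missing!r}")
            candidates = candidates[high.to_numpy() > thr.min_log2fpkm]
            candidates = candidates.difference(pan)
            stats = de.loc[candidates, ["base_mean", "log2fc", "padj"]].copy()
            stats["log2fpkm_higher"] = fpkm_means[(species, cell_type)] \
                .reindex(candidates)
            calls[(cell_type, species)] = stats.sort_index()
    return EnrichmentCall(calls=calls, pan_species_genes=pan, thresholds=thr)


def define_housekeeping(de_all_samples: pd.DataFrame,
                        fpkm_species_means: pd.DataFrame,
                        thresholds: EnrichmentThresholds | None = None
                        ) -> list[str]:
    """Well-expressed genes with no species difference (conservation
    reference): raw p > 0.2, base_mean > 400, mean log2 FPKM > 4 in both
    species."""
    thr = thresholds or EnrichmentThresholds()
    mask = ((de_all_samples["pvalue"] > thr.housekeeping_p)
            & (de_all_samples["base_mean"] > thr.min_base_mean)).fillna(False)
    genes = de_all_samples.index[mask]
    fp = fpkm_species_means.reindex(genes)
    genes = genes[(fp > thr.min_log2fpkm).all(axis=1).to_numpy()]
    return sorted(genes)


def enumerate_partitions(n: int, k: int) -> list[tuple[int, ...]]:
    """All C(n, k) index subsets of size k, lexicographic, no repeats."""
    if not 0 < k < n:
        raise ValueError(f"need 0 < k < n, got n={n}, k={k}")
    return list(itertools.combinations(range(n), k))


@dataclass
class PartitionNullResult:
    """DE gene counts over every size-k vs size-(n-k) donor split."""

    table: pd.DataFrame  # partition_id, members, n_de
    n: int
    k: int
    threshold: float
    histogram: pd.Series = field(default_factory=pd.Series)

    def quantile(self, q) -> float:
        return float(np.quantile(self.table["n_de"].to_numpy(), q))

    @property
    def max_partition(self) -> tuple[int, ...]:
        row = self.table.loc[self.table["n_de"].idxmax()]
        return tuple(int(i) for i in row["members"].split(","))


def partition_null(counts, metadata: pd.DataFrame, k: int,
                   thresholds: EnrichmentThresholds | None = None,
                   sample_ids: Sequence[str] | None = None
                   ) -> PartitionNullResult:
    """Exhaustive partition-resampling null for a size-k group contrast.

    For each of the C(n, k) subsets of the samples, runs the NB Wald DE of
    subset vs complement and records the number of genes with adjusted
    p below ``thresholds.de_alpha`` (default 0.01).  Size factors are
    estimated once from the full matrix; dispersions are re-estimated per
    partition from its own grouping.
    """
    thr = thresholds or EnrichmentThresholds()
    df = counts.to_frame() if isinstance(counts, CountMatrix) else counts
    if sample_ids is not None:
        df = df[list(sample_ids)]
    n = df.shape[1]
    if (df.sum(axis=0) == 0).any():
        bad = df.columns[df.sum(axis=0) == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    sf = _size_factors(df)
    subsets = enumerate_partitions(n, k)
    rows = []
    for pid, subset in enumerate(subsets):
        labels = np.full(n, "rest", dtype=object)
        labels[list(subset)] = "group"
        meta = pd.DataFrame({"sample_id": df.columns, "grp": labels})
        de = nb_wald_test(df, meta, "grp", reference="rest", size_factors=sf)
        n_de = int((de["padj"] < thr.de_alpha).sum())
        rows.append({"partition_id": pid,
                     "members": ",".join(map(str, subset)),
                     "n_de": n_de})
    table = pd.DataFrame(rows)
    assert len(table) == comb(n, k)
    hist = table["n_de"].value_counts().sort_index()
    return PartitionNullResult(table=table, n=n, k=k,
                               threshold=thr.de_alpha, histogram=hist)
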