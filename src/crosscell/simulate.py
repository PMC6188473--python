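"""Synthetic inputs with planted ground truth.

The generators emulate the statistical structure of sorted-population
RNA-seq across species: negative-binomial bulk counts over 2-3 species x
3-6 cell types x 2-16 replicates with planted cell-type markers,
species-enriched genes, pan-species genes, housekeeping genes and null
genes; transcript-level ortholog tables with planted filter violations;
sparse single-nucleus matrices with cluster structure, dropout and
planted filter-violating cells/genes; and promoter/gene-body peak sets
with conservation tracks whose scores are lowered over the peaks of
species-enriched genes by a chosen contrast.

Counts are drawn as gamma-Poisson mixtures: the mean for gene g in
sample j is rate_g x length_kb_g x depth x size_factor_j x 2^(planted
effects), so FPKM-like units recover rate_g independent of gene length.
Planted (non-null) classes are restricted to genes of 3-20 kb so that
expression-level thresholds downstream (base_mean, log2 FPKM) measure
method error rather than length artifacts.  Every generator is a pure
function of its configuration and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse

from .io import CountMatrix, GeneModel, new_peak_set, validate_track

GENE_CLASSES = ("marker", "species_enriched", "pan_species", "housekeeping",
                "age", "null")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def simulate_gene_models(n_genes: int, seed: int | None = 0,
                         min_length: int = 200, max_length: int = 50_000,
                         n_chroms: int = 3) -> list[GeneModel]:
    """Gene models with log-uniform lengths over [200 bp, 50 kb].

    Some genes deliberately fall below the 1 kb length filter used
    downstream (guaranteed when n_genes >= 2).  Each gene carries 1-4
    transcripts; the longest transcript span equals the gene span.  Both
    strands are represented (guaranteed when n_genes >= 2).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.exp(rng.uniform(np.log(min_length), np.log(max_length),
                                 n_genes)).astype(int)
    if n_genes >= 2 and not (lengths < 1000).any():
        lengths[int(np.argmin(lengths))] = 900
    strands = rng.choice(["+", "-"], n_genes)
    if n_genes >= 2 and len(set(strands)) == 1:
        strands[0] = "+" if strands[0] == "-" else "-"
    chroms = np.array([f"chr{1 + i % n_chroms}" for i in range(n_genes)])
    cursor = {f"chr{c + 1}": 2000 for c in range(n_chroms)}
    models = []
    for i in range(n_genes):
        chrom = chroms[i]
        start = cursor[chrom] + int(rng.integers(2000, 10_000))
        end = start + int(lengths[i])
        cursor[chrom] = end
        gid = f"g{i:05d}"
        n_tx = int(rng.integers(1, 5))
        transcripts = [(f"{gid}.t1", start, end)]
        for t in range(1, n_tx):
            ts = start + int(rng.integers(0, max(1, lengths[i] // 3)))
            te = end - int(rng.integers(0, max(1, lengths[i] // 3)))
            if ts < te:
                transcripts.append((f"{gid}.t{t + 1}", ts, te))
        models.append(GeneModel(gid, str(chrom), str(strands[i]), start, end,
                                tuple(transcripts)))
    return models


# ---------------------------------------------------------------------------
# ortholog tables
# ---------------------------------------------------------------------------

def simulate_ortholog_table(models_by_species: dict[str, list[GeneModel]],
                            frac_low_conf: float = 0.0,
                            frac_duplicate: float = 0.0,
                            frac_non_one_to_one: float = 0.0,
                            frac_length_divergent: float = 0.0,
                            seed: int | None = 0
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A transcript-level ortholog table with planted filter violations.

    Genes are paired across species rank-by-rank on length (so most
    tuples are length-concordant); the requested fraction of tuples is
    deliberately re-paired short-against-long to force >2-fold length
    divergence.  Low-confidence flags, exact duplicate rows and
    non-1:1 transcript mappings are planted at their stated fractions.
    Returns (table, truth); truth marks each planted violation and
    whether the tuple should survive harmonization.
    """
    for frac in (frac_low_conf, frac_duplicate, frac_non_one_to_one,
                 frac_length_divergent):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    species = list(models_by_species)
    if len(species) < 2:
        raise ValueError("need >= 2 species")
    rng = np.random.default_rng(seed)
    n = min(len(m) for m in models_by_species.values())
    ordered = {sp: sorted(models_by_species[sp], key=lambda m: m.length_bp)[:n]
               for sp in species}
    pairing = {sp: list(range(n)) for sp in species}
    n_div = int(round(frac_length_divergent * n))
    if n_div:
        chosen = rng.choice(n, size=n_div, replace=False)
        for sp in species[1:]:
            sel = sorted(chosen)
            for a, b in zip(sel, reversed(sel)):
                pairing[sp][a] = b

    import itertools
    conf_cols = [f"conf_{a}_{b}" for a, b in
                 itertools.combinations(sorted(species), 2)]
    rows = []
    for i in range(n):
        row = {}
        for sp in species:
            m = ordered[sp][pairing[sp][i]]
            row[f"{sp}_gene"] = m.gene_id
            row[f"{sp}_transcript"] = m.longest_transcript()[0]
        for c in conf_cols:
            row[c] = 1
        rows.append(row)
    table = pd.DataFrame(rows)

    def pick(frac):
        size = int(round(frac * n))
        return set(rng.choice(n, size=size, replace=False)) if size else set()

    low_conf = pick(frac_low_conf)
    for i in low_conf:
        table.loc[i, conf_cols[int(rng.integers(len(conf_cols)))]] = 0

    non11 = set()
    extra_rows = []
    for i in pick(frac_non_one_to_one):
        # map the first species' transcript to a second transcript of the
        # partner gene in another species (needs >= 2 transcript spans)
        for sp in species[1:]:
            m = ordered[sp][pairing[sp][i]]
            others = [t for t in m.transcripts
                      if t[0] != m.longest_transcript()[0]]
            if others:
                row = dict(table.loc[i])
                row[f"{sp}_transcript"] = others[0][0]
                extra_rows.append(row)
                non11.add(i)
                break

    duplicated = pick(frac_duplicate)
    for i in duplicated:
        extra_rows.append(dict(table.loc[i]))

    lengths = np.column_stack([
        [ordered[sp][pairing[sp][i]].length_bp for i in range(n)]
        for sp in species]).astype(float)
    ratio = lengths.max(axis=1) / lengths.min(axis=1)
    short = (lengths < 1000).any(axis=1)

    truth = pd.DataFrame({
        "tuple_id": table[f"{species[0]}_gene"],
        "planted_low_conf": [i in low_conf for i in range(n)],
        "planted_duplicate": [i in duplicated for i in range(n)],
        "planted_non_1to1": [i in non11 for i in range(n)],
        "length_ratio": ratio,
        "length_divergent": ratio > 2.0,
        "short_gene": short,
    })
    truth["expected_survive"] = (~truth["planted_low_conf"]
                                 & ~truth["planted_non_1to1"]
                                 & ~truth["length_divergent"]
                                 & ~truth["short_gene"])
    if extra_rows:
        table = pd.concat([table, pd.DataFrame(extra_rows)], ignore_index=True)
    return table, truth.set_index("tuple_id")


# ---------------------------------------------------------------------------
# bulk counts
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-design parameters for the bulk generator.

    Defaults mirror the profiled designs: two species, three cell types,
    eight replicates each; an 8-fold planted species effect (log2 = 3,
    comfortably above the 4-fold call threshold); 50 species-enriched
    genes per cell type out of 2000.
    """

    n_genes: int = 2000
    species: tuple[str, ...] = ("mouse", "human")
    cell_types: tuple[str, ...] = ("granule", "basket", "glia")
    replicates: int = 8
    depth_factor: float = 4.0
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    dispersion_mean: float = 0.04
    dispersion_sigma: float = 0.3
    marker_fold: float = 32.0
    species_fold: float = 8.0
    frac_marker: float = 0.03
    frac_species_enriched: float = 0.075
    frac_pan_species: float = 0.02
    frac_housekeeping: float = 0.10
    frac_age: float = 0.0
    age_log2_per_decade: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_marker + self.frac_species_enriched
                 + self.frac_pan_species + self.frac_housekeeping
                 + self.frac_age)
        if fracs > 1.0:
            raise ValueError("class fractions must sum to <= 1")
        if self.marker_fold <= 1.0 or self.species_fold <= 1.0:
            raise ValueError("planted folds must exceed 1")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate per condition")
        if self.replicates < 2:
            warnings.warn("replicates < 2: variance estimation is degenerate")


@dataclass
class SimulatedBulk:
    counts: CountMatrix
    samples: pd.DataFrame
    truth: pd.DataFrame
    models: list[GeneModel]
    size_factors: pd.Series = field(default_factory=pd.Series)


def _assign_classes(cfg: SimulationConfig, lengths: np.ndarray,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Mutually exclusive class labels; planted classes take 3-20 kb genes."""
    n = cfg.n_genes
    eligible = np.where((lengths >= 3000) & (lengths <= 20_000))[0]
    rng.shuffle(eligible)
    counts = {
        "marker": int(round(cfg.frac_marker * n)),
        "species_enriched": int(round(cfg.frac_species_enriched * n)),
        "pan_species": int(round(cfg.frac_pan_species * n)),
        "housekeeping": int(round(cfg.frac_housekeeping * n)),
        "age": int(round(cfg.frac_age * n)),
    }
    if sum(counts.values()) > len(eligible):
        raise ValueError("not enough 3-20 kb genes to plant all classes; "
                         "increase n_genes or lower the fractions")
    labels = np.array(["null"] * n, dtype=object)
    cell_type = np.array([None] * n, dtype=object)
    species = np.array([None] * n, dtype=object)
    pos = 0
    for cls, k in counts.items():
        idx = eligible[pos:pos + k]
        pos += k
        labels[idx] = cls
        if cls in ("marker", "species_enriched"):
            for j, g in enumerate(idx):
                cell_type[g] = cfg.cell_types[j % len(cfg.cell_types)]
        if cls in ("species_enriched", "pan_species"):
            for j, g in enumerate(idx):
                species[g] = cfg.species[j % len(cfg.species)]
    return pd.DataFrame({"class": labels, "cell_type": cell_type,
                         "species": species})


def simulate_bulk_counts(cfg: SimulationConfig,
                         models: list[GeneModel] | None = None
                         ) -> SimulatedBulk:
    """Negative-binomial bulk counts with planted gene classes.

    Markers are elevated in one cell type across all species;
    species-enriched genes in one species in one cell type; pan-species
    genes in one species in all cell types; housekeeping genes are
    well-expressed everywhere with no planted effect.
    """
    rng = np.random.default_rng(cfg.seed)
    if models is None:
        models = simulate_gene_models(cfg.n_genes, seed=rng.integers(2**31))
    if len(models) != cfg.n_genes:
        raise ValueError("models length must equal n_genes")
    lengths = np.array([m.length_bp for m in models], dtype=float)
    gene_ids = [m.gene_id for m in models]
    classes = _assign_classes(cfg, lengths, rng)

    base_rate = np.exp(rng.normal(np.log(3.0), 1.2, cfg.n_genes))
    cls = classes["class"].to_numpy()
    base_rate[cls == "marker"] = np.exp(
        rng.normal(np.log(10.0), 0.4, (cls == "marker").sum()))
    base_rate[cls == "species_enriched"] = np.exp(
        rng.normal(np.log(15.0), 0.2, (cls == "species_enriched").sum()))
    base_rate[cls == "pan_species"] = np.exp(
        rng.normal(np.log(15.0), 0.2, (cls == "pan_species").sum()))
    base_rate[cls == "housekeeping"] = np.exp(
        rng.normal(np.log(40.0), 0.15, (cls == "housekeeping").sum()))
    base_rate[cls == "age"] = np.exp(
        rng.normal(np.log(15.0), 0.3, (cls == "age").sum()))
    dispersion = np.clip(
        np.exp(rng.normal(np.log(cfg.dispersion_mean), cfg.dispersion_sigma,
                          cfg.n_genes)), 1e-6, 0.5)
    age_sign = rng.choice([-1.0, 1.0], cfg.n_genes)

    # samples
    rows = []
    for sp in cfg.species:
        for ct in cfg.cell_types:
            for r in range(1, cfg.replicates + 1):
                age = (float(rng.uniform(25, 85)) if sp == "human"
                       else float(rng.uniform(0.2, 2.0)))
                rows.append({
                    "sample_id": f"{sp}_{ct}_r{r}", "species": sp,
                    "cell_type": ct, "donor_id": f"{sp}_d{r}",
                    "sex": "M" if r % 2 else "F", "age": round(age, 1),
                    "pmd": round(float(rng.uniform(4, 30)), 1),
                    "replicate": r})
    samples = pd.DataFrame(rows)
    S = len(samples)
    sf = rng.uniform(*cfg.size_factor_range, S)

    log2eff = np.zeros((cfg.n_genes, S))
    sp_arr = samples["species"].to_numpy()
    ct_arr = samples["cell_type"].to_numpy()
    age_arr = samples["age"].to_numpy(dtype=float)
    for g in range(cfg.n_genes):
        c = cls[g]
        if c == "marker":
            log2eff[g, ct_arr == classes.at[g, "cell_type"]] += \
                np.log2(cfg.marker_fold)
        elif c == "species_enriched":
            mask = ((sp_arr == classes.at[g, "species"])
                    & (ct_arr == classes.at[g, "cell_type"]))
            log2eff[g, mask] += np.log2(cfg.species_fold)
        elif c == "pan_species":
            log2eff[g, sp_arr == classes.at[g, "species"]] += \
                np.log2(cfg.species_fold)
        elif c == "age":
            log2eff[g] += (cfg.age_log2_per_decade * age_sign[g]
                           * (age_arr - age_arr.mean()) / 10.0)

    mu = (base_rate[:, None] * (lengths[:, None] / 1e3) * cfg.depth_factor
          * sf[None, :] * 2.0 ** log2eff)
    counts = _nb_draw(mu, dispersion, rng)

    log2_effect = np.zeros(cfg.n_genes)
    log2_effect[cls == "marker"] = np.log2(cfg.marker_fold)
    log2_effect[np.isin(cls, ["species_enriched", "pan_species"])] = \
        np.log2(cfg.species_fold)
    truth = pd.DataFrame({
        "class": cls, "cell_type": classes["cell_type"].to_numpy(),
        "species": classes["species"].to_numpy(),
        "log2_effect": log2_effect, "baseline_rate": base_rate,
        "dispersion": dispersion, "length_bp": lengths.astype(int),
    }, index=pd.Index(gene_ids, name="gene_id"))
    return SimulatedBulk(
        counts=CountMatrix(counts, gene_ids, samples["sample_id"].tolist()),
        samples=samples, truth=truth, models=models,
        size_factors=pd.Series(sf, index=samples["sample_id"], name="size_factor"))


def _nb_draw(mu: np.ndarray, dispersion: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with per-gene dispersion; Poisson when alpha ~ 0."""
    alpha = np.asarray(dispersion, dtype=float)
    lam = np.array(mu, dtype=float)
    nb = alpha > 1e-8
    if nb.any():
        a = alpha[nb][:, None] if lam.ndim == 2 else alpha[nb]
        lam_nb = rng.gamma(shape=1.0 / a, scale=a * lam[nb])
        lam[nb] = lam_nb
    return rng.poisson(lam).astype(np.int64)


def simulate_partition_cohort(n_samples: int = 16, n_genes: int = 2000,
                              affected_samples: tuple[int, ...] = (),
                              n_affected_genes: int = 0,
                              effect_log2: float = 0.0,
                              dispersion_mean: float = 0.04,
                              seed: int | None = 0
                              ) -> tuple[CountMatrix, pd.DataFrame, list[str]]:
    """One-cell-type cohort for the partition-resampling null.

    Homogeneous by default; optionally plants an ``effect_log2`` shift on
    ``n_affected_genes`` genes in the chosen donor subset.  Returns
    (counts, metadata, affected gene ids).
    """
    rng = np.random.default_rng(seed)
    rate = np.exp(rng.normal(np.log(8.0), 1.0, n_genes))
    dispersion = np.clip(np.exp(rng.normal(np.log(dispersion_mean), 0.3,
                                           n_genes)), 1e-6, 0.5)
    sf = rng.uniform(0.8, 1.25, n_samples)
    mu = rate[:, None] * 50.0 * sf[None, :]
    affected_genes: list[str] = []
    if affected_samples and n_affected_genes:
        idx = rng.choice(n_genes, size=n_affected_genes, replace=False)
        mu[np.ix_(idx, list(affected_samples))] *= 2.0 ** effect_log2
        affected_genes = [f"g{i:05d}" for i in sorted(idx)]
    counts = _nb_draw(mu, dispersion, rng)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    sample_ids = [f"s{j:02d}" for j in range(n_samples)]
    meta = pd.DataFrame({"sample_id": sample_ids,
                         "donor_id": [f"d{j:02d}" for j in range(n_samples)]})
    return CountMatrix(counts, gene_ids, sample_ids), meta, affected_genes


# ---------------------------------------------------------------------------
# single-cell matrices
# ---------------------------------------------------------------------------

@dataclass
class SingleCellConfig:
    """Design of the synthetic single-nucleus matrix.

    n_genes exceeds the 5000 upper detected-gene bound so that
    over-detection violators can be planted.  Dropout is per-gene-per-cell
    Bernoulli thinning; library sizes are log-normal.
    """

    n_genes: int = 6000
    clusters: tuple[str, ...] = ("granule", "basket", "astrocyte")
    cells_per_cluster: int = 100
    dropout: float = 0.3
    markers_per_cluster: int = 20
    marker_fold: float = 8.0
    n_low_cells: int = 3     # planted cells detecting < 300 genes
    n_high_cells: int = 2    # planted cells detecting > 5000 genes
    n_rare_genes: int = 20   # planted genes detected in < 3 cells
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.clusters) < 2:
            raise ValueError("need >= 2 clusters")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_high_cells and self.n_genes - self.n_rare_genes < 5300:
            raise ValueError("n_genes (minus rare genes) must be >= 5300 to "
                             "plant over-detection violators")


def simulate_single_cell(cfg: SingleCellConfig) -> ad.AnnData:
    """Sparse cells x genes counts with cluster labels and planted
    filter violations.

    obs["cluster"] holds the cluster label; obs["planted_filter"] is
    "low" / "high" / "ok"; var["planted_rare"] marks genes planted to be
    detected in fewer than three cells.  By construction the planted
    violators are exactly the entities the 3-cell / 300-gene / 5000-gene
    filters remove.
    """
    rng = np.random.default_rng(cfg.seed)
    n_cells = len(cfg.clusters) * cfg.cells_per_cluster
    G = cfg.n_genes
    rate = np.exp(rng.normal(np.log(0.45), 1.0, G))
    lib = np.exp(rng.normal(0.0, 0.25, n_cells))
    cluster = np.repeat(list(cfg.clusters), cfg.cells_per_cluster)

    marker_of = np.array([None] * G, dtype=object)
    pool = rng.permutation(G)
    pos = 0
    for cl in cfg.clusters:
        idx = pool[pos:pos + cfg.markers_per_cluster]
        pos += cfg.markers_per_cluster
        marker_of[idx] = cl

    mu = rate[None, :] * lib[:, None]
    for cl in cfg.clusters:
        boost = (marker_of == cl)[None, :] & (cluster == cl)[:, None]
        mu = np.where(boost, mu * cfg.marker_fold, mu)
    X = rng.poisson(mu)
    if cfg.dropout > 0:
        X = np.where(rng.random(X.shape) < cfg.dropout, 0, X)

    cell_ids = np.array([f"c{i:04d}" for i in range(n_cells)])
    gene_ids = np.array([f"g{i:05d}" for i in range(G)])
    planted = np.array(["ok"] * n_cells, dtype=object)
    special = rng.choice(n_cells, size=cfg.n_low_cells + cfg.n_high_cells,
                         replace=False)
    low_cells = special[:cfg.n_low_cells]
    high_cells = special[cfg.n_low_cells:]
    planted[low_cells] = "low"
    planted[high_cells] = "high"
    normal = np.where(planted == "ok")[0]

    rare = rng.choice(G, size=cfg.n_rare_genes, replace=False)
    is_rare = np.zeros(G, dtype=bool)
    is_rare[rare] = True
    X[:, rare] = 0
    for g in rare:
        X[rng.choice(normal, size=2, replace=False), g] = 1

    # every non-rare gene must be detected in >= 3 non-low cells
    det = (X[normal] > 0).sum(axis=0)
    for g in np.where((det < 3) & ~is_rare)[0]:
        fix = rng.choice(normal, size=3, replace=False)
        X[fix, g] = np.maximum(X[fix, g], 1)

    common = np.where(~is_rare)[0]
    for c in low_cells:
        X[c] = 0
        X[c, rng.choice(common, size=250, replace=False)] = 1
    for c in high_cells:
        force = rng.choice(common, size=5300, replace=False)
        X[c, force] = np.maximum(X[c, force], 1)

    # keep normal cells inside (300, 5000) with margin for the gene filter
    det_cells = (X[:, ~is_rare] > 0).sum(axis=1)
    for c in normal:
        if det_cells[c] < 320:
            off = np.setdiff1d(common, np.where(X[c] > 0)[0])
            add = rng.choice(off, size=int(330 - det_cells[c]), replace=False)
            X[c, add] = 1
        elif det_cells[c] > 4800:
            on = np.intersect1d(np.where(X[c] > 0)[0], common)
            drop = rng.choice(on, size=int(det_cells[c] - 4700), replace=False)
            X[c, drop] = 0

    adata = ad.AnnData(
        X=scipy.sparse.csr_matrix(X.astype(np.int64)),
        obs=pd.DataFrame({"cluster": cluster, "planted_filter": planted},
                         index=cell_ids),
        var=pd.DataFrame({"planted_rare": is_rare,
                          "marker_of": marker_of}, index=gene_ids))
    adata.uns["seed"] = cfg.seed
    return adata


# ---------------------------------------------------------------------------
# peaks and conservation
# ---------------------------------------------------------------------------

def simulate_peaks_and_conservation(models: list[GeneModel],
                                    truth: pd.DataFrame,
                                    contrast: float = 0.2,
                                    focal: tuple[str, str] | None = None,
                                    base_score: float = 0.6,
                                    peak_width: int = 500,
                                    seed: int | None = 0
                                    ) -> tuple[pd.DataFrame, pd.DataFrame,
                                               pd.DataFrame]:
    """Promoter/gene-body peaks whose presence tracks expression in the
    focal (species, cell type), plus a conservation track in which peaks
    of species-enriched genes score ``contrast`` lower on average than
    housekeeping-gene peaks.

    Returns (peaks, track, peak_truth).
    """
    rng = np.random.default_rng(seed)
    if focal is None:
        sp = truth["species"].dropna()
        ct = truth["cell_type"].dropna()
        focal = (sp.iloc[0] if len(sp) else "human",
                 ct.iloc[0] if len(ct) else "granule")
    f_sp, f_ct = focal
    by_id = {m.gene_id: m for m in models}
    cls = truth["class"]
    expressed = (
        ((cls == "marker") & (truth["cell_type"] == f_ct))
        | ((cls == "species_enriched") & (truth["species"] == f_sp)
           & (truth["cell_type"] == f_ct))
        | ((cls == "pan_species") & (truth["species"] == f_sp))
        | (cls == "housekeeping")
        | ((cls == "null") & (rng.random(len(truth)) < 0.3)))
    chroms, starts, ends, pids, pgene, pclass, pcat = [], [], [], [], [], [], []
    for gid in truth.index[expressed]:
        m = by_id.get(gid)
        if m is None:
            continue
        off = int(rng.integers(-500, 51))
        if m.strand == "+":
            center = m.tss + off
        else:
            center = m.tss - off
        start = max(0, center - peak_width // 2)
        chroms.append(m.chrom)
        starts.append(start)
        ends.append(start + peak_width)
        pids.append(f"pk_{gid}_prom")
        pgene.append(gid)
        pclass.append(cls[gid])
        pcat.append("promoter")
        if m.length_bp >= 3000 and rng.random() < 0.6:
            lo = m.start + 1300 if m.strand == "+" else m.start + 100
            hi = m.end - 100 if m.strand == "+" else m.end - 1300
            if hi - peak_width > lo:
                bstart = int(rng.integers(lo, hi - peak_width))
                chroms.append(m.chrom)
                starts.append(bstart)
                ends.append(bstart + peak_width)
                pids.append(f"pk_{gid}_body")
                pgene.append(gid)
                pclass.append(cls[gid])
                pcat.append("gene_body")
    peaks = new_peak_set(chroms, starts, ends, pids)
    peak_truth = pd.DataFrame({"peak_id": pids, "gene_id": pgene,
                               "gene_class": pclass, "intended": pcat})

    runs = []
    for i, (c, s, e, gcls) in enumerate(zip(chroms, starts, ends, pclass)):
        mean = base_score - (contrast if gcls == "species_enriched" else 0.0)
        edges = np.linspace(s, e, 6).astype(int)
        for lo, hi in zip(edges[:-1], edges[1:]):
            score = float(np.clip(rng.normal(mean, 0.02), 0.0, 1.0))
            runs.append({"chrom": c, "start": int(lo), "end": int(hi),
                         "score": score})
    track = validate_track(pd.DataFrame(runs), conservation=True,
                           source="simulated")
    return peaks, track, peak_truth


# ---------------------------------------------------------------------------
# fixture directories
# ---------------------------------------------------------------------------

def _rename_model(m: GeneModel, prefix: str) -> GeneModel:
    return GeneModel(f"{prefix}{m.gene_id}", m.chrom, m.strand, m.start, m.end,
                     tuple((f"{prefix}{tid}", ts, te)
                           for tid, ts, te in m.transcripts))


def write_fixture(out_dir, cfg: SimulationConfig | None = None,
                  contrast: float = 0.2) -> dict:
    """Write a complete analysis fixture directory.

    One bulk simulation provides counts for every species; each species
    gets its own gene-id namespace (``<species>_gXXXXX``) with an
    identity 1:1 ortholog table linking them, so the harmonization and
    cross-species stages run exactly as they would on real inputs.
    Returns the dict of paths written (usable as a pipeline config's
    ``inputs`` block).
    """
    from pathlib import Path

    from .io import (write_counts, write_gene_models, write_ortholog_table,
                     write_sample_table, write_intervals, write_tsv)

    cfg = cfg or SimulationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_bulk_counts(cfg)
    df = sim.counts.to_frame()
    seed = cfg.seed

    paths: dict = {"counts_by_species": {}, "gene_models_by_species": {}}
    import itertools
    table_rows = []
    for sp in cfg.species:
        prefix = f"{sp}_"
        models_sp = [_rename_model(m, prefix) for m in sim.models]
        cols = [s for s in df.columns if s.startswith(prefix)]
        sub = df[cols].copy()
        sub.index = [f"{prefix}{g}" for g in df.index]
        cpath = out / f"counts_{sp}.tsv"
        mpath = out / f"models_{sp}.tsv"
        write_counts(CountMatrix.from_frame(sub), cpath, seed=seed)
        write_gene_models(models_sp, mpath, seed=seed)
        paths["counts_by_species"][sp] = str(cpath)
        paths["gene_models_by_species"][sp] = str(mpath)
    for m in sim.models:
        row = {}
        for sp in cfg.species:
            renamed = _rename_model(m, f"{sp}_")
            row[f"{sp}_gene"] = renamed.gene_id
            row[f"{sp}_transcript"] = renamed.longest_transcript()[0]
        for a, b in itertools.combinations(sorted(cfg.species), 2):
            row[f"conf_{a}_{b}"] = 1
        table_rows.append(row)
    opath = out / "orthologs.tsv"
    write_ortholog_table(pd.DataFrame(table_rows), opath, seed=seed)
    paths["ortholog_table"] = str(opath)

    spath = out / "samples.tsv"
    write_sample_table(sim.samples, spath, seed=seed)
    paths["sample_table"] = str(spath)

    tpath = out / "truth.tsv"
    write_tsv(sim.truth, tpath, seed=seed)
    paths["truth"] = str(tpath)

    focal = (cfg.species[-1], cfg.cell_types[0])
    models_focal = [_rename_model(m, f"{focal[0]}_") for m in sim.models]
    truth_focal = sim.truth.copy()
    truth_focal.index = [f"{focal[0]}_{g}" for g in sim.truth.index]
    peaks, track, peak_truth = simulate_peaks_and_conservation(
        models_focal, truth_focal, contrast=contrast, focal=focal, seed=seed)
    ppath = out / "peaks.bed"
    gpath = out / "conservation.bedgraph"
    write_intervals(peaks, ppath, kind="bed")
    write_intervals(track, gpath, kind="bedgraph")
    write_tsv(peak_truth, out / "peak_truth.tsv", seed=seed, index=False)
    paths["peaks"] = str(ppath)
    paths["conservation"] = str(gpath)
    return paths
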