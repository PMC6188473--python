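"""Readers and writers for every external format the pipeline touches.

All interval types use BED-style 0-based half-open coordinates, both in
memory and on disk.  Count tables are genes x samples with the gene id in
the first column.  Gene models are a flat "GTF-lite" TSV with one row per
transcript (the study only needs whole-gene spans and transcript spans,
never exon structure).  Every output TSV written by :func:`write_tsv`
carries a commented header line recording the tool version and, when
supplied, the seed that produced it.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import __version__

SPECIES = ("mouse", "rat", "human")

SAMPLE_COLUMNS = ("sample_id", "species", "cell_type", "donor_id", "sex",
                  "age", "pmd", "replicate")


class FormatError(ValueError):
    """A file violated the format contract (bad value, bad coordinates...)."""


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Whole-gene span (UTRs included) plus its transcript spans.

    Coordinates are 0-based half-open.  The TSS is ``start`` on the plus
    strand and ``end - 1`` on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand {self.strand!r} not in {{+,-}}")
        if not self.start < self.end:
            raise FormatError(f"gene {self.gene_id}: start {self.start} >= end {self.end}")
        for tid, ts, te in self.transcripts:
            if not (self.start <= ts < te <= self.end):
                raise FormatError(
                    f"gene {self.gene_id}: transcript {tid} span [{ts},{te}) "
                    f"not nested in gene span [{self.start},{self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def longest_transcript(self) -> tuple[str, int, int]:
        if not self.transcripts:
            return (self.gene_id, self.start, self.end)
        return max(self.transcripts, key=lambda t: (t[2] - t[1], t[0]))


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read the flat gene-model TSV (one row per transcript)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"gene_id": str, "chrom": str, "strand": str,
                            "transcript_id": str})
    required = {"gene_id", "chrom", "strand", "start", "end",
                "transcript_id", "t_start", "t_end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"gene model table missing columns: {sorted(missing)}")
    models = []
    for gene_id, grp in df.groupby("gene_id", sort=False):
        first = grp.iloc[0]
        transcripts = tuple(
            (str(r.transcript_id), int(r.t_start), int(r.t_end))
            for r in grp.itertuples())
        models.append(GeneModel(str(gene_id), str(first.chrom), str(first.strand),
                                int(first.start), int(first.end), transcripts))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path,
                      seed: int | None = None) -> None:
    rows = []
    for m in models:
        for tid, ts, te in (m.transcripts or ((m.gene_id, m.start, m.end),)):
            rows.append((m.gene_id, m.chrom, m.strand, m.start, m.end, tid, ts, te))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start",
                                     "end", "transcript_id", "t_start", "t_end"])
    write_tsv(df, path, seed=seed, index=False)


def models_by_id(models: Iterable[GeneModel]) -> dict[str, GeneModel]:
    return {m.gene_id: m for m in models}


def gene_lengths(models: Iterable[GeneModel]) -> pd.Series:
    out = pd.Series({m.gene_id: m.length_bp for m in models}, dtype=int)
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

class CountMatrix:
    """Genes x samples matrix of raw non-negative integer counts."""

    def __init__(self, counts: np.ndarray, gene_ids: Sequence[str],
                 sample_ids: Sequence[str]) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise FormatError("counts must be 2-dimensional")
        if counts.shape != (len(gene_ids), len(sample_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise FormatError(
                    f"non-integer count at gene {gene_ids[bad[0]]!r}, "
                    f"sample {sample_ids[bad[1]]!r}")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at gene {gene_ids[bad[0]]!r}, "
                f"sample {sample_ids[bad[1]]!r}")
        genes = pd.Index(gene_ids, name="gene_id")
        samples = pd.Index(sample_ids, name="sample_id")
        if genes.has_duplicates:
            dup = genes[genes.duplicated()][0]
            raise FormatError(f"duplicated gene id {dup!r}")
        if samples.has_duplicates:
            dup = samples[samples.duplicated()][0]
            raise FormatError(f"duplicated sample id {dup!r}")
        self.counts = counts.astype(np.int64)
        self.gene_ids = genes
        self.sample_ids = samples

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), list(map(str, df.index)), list(map(str, df.columns)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids.copy(),
                            columns=self.sample_ids.copy())

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = self.gene_ids.get_indexer(genes)
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return CountMatrix(self.counts[idx], list(genes), list(self.sample_ids))

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        idx = self.sample_ids.get_indexer(samples)
        if (idx < 0).any():
            missing = [s for s, i in zip(samples, idx) if i < 0]
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return CountMatrix(self.counts[:, idx], list(self.gene_ids), list(samples))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (self.gene_ids.equals(other.gene_ids)
                and self.sample_ids.equals(other.sample_ids)
                and np.array_equal(self.counts, other.counts))


def read_counts(path: str | Path, format: str = "tsv", *,
                genes_path: str | Path | None = None,
                samples_path: str | Path | None = None) -> CountMatrix:
    """Read a count matrix from TSV or MatrixMarket triplet format.

    For ``mtx_triplet`` the row (gene) and column (sample) identifiers live
    in sidecar files ``<path>.genes.tsv`` / ``<path>.samples.tsv`` unless
    given explicitly; omitted cells are zero by the sparse convention.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        arr = df.to_numpy()
        if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
            raise FormatError(f"{path}: non-numeric entries in count table")
        return CountMatrix(arr, list(map(str, df.index)), list(map(str, df.columns)))
    if format == "mtx_triplet":
        genes_path = genes_path or path.with_suffix(path.suffix + ".genes.tsv")
        samples_path = samples_path or path.with_suffix(path.suffix + ".samples.tsv")
        mat = scipy.io.mmread(str(path))
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        samples = pd.read_csv(samples_path, sep="\t", header=None)[0].astype(str).tolist()
        return CountMatrix(np.asarray(scipy.sparse.coo_matrix(mat).todense()),
                           genes, samples)
    raise ValueError(f"unknown count format {format!r}")


def write_counts(matrix: CountMatrix, path: str | Path, format: str = "tsv", *,
                 seed: int | None = None) -> None:
    path = Path(path)
    if format == "tsv":
        write_tsv(matrix.to_frame(), path, seed=seed, index=True)
    elif format == "mtx_triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.counts))
        pd.Series(matrix.gene_ids).to_csv(
            path.with_suffix(path.suffix + ".genes.tsv"), sep="\t",
            header=False, index=False)
        pd.Series(matrix.sample_ids).to_csv(
            path.with_suffix(path.suffix + ".samples.tsv"), sep="\t",
            header=False, index=False)
    else:
        raise ValueError(f"unknown count format {format!r}")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the sample metadata contract and return a clean copy."""
    df = df.copy()
    missing = set(SAMPLE_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise FormatError(f"sample table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicated sample_id {dup!r}")
    bad_species = set(df["species"]) - set(SPECIES)
    if bad_species:
        raise FormatError(f"unknown species: {sorted(bad_species)}")
    bad_sex = set(df["sex"]) - {"M", "F"}
    if bad_sex:
        raise FormatError(f"sex must be M or F, got {sorted(bad_sex)}")
    if "replicate" in df.columns:
        key = df[["species", "cell_type", "donor_id", "replicate"]]
        if key.duplicated().any():
            raise FormatError("(species, cell_type, donor_id, replicate) not unique")
        if (df["replicate"] < 1).any():
            raise FormatError("replicate must be a positive integer")
    for col in ("age", "pmd"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if (vals.dropna() < 0).any():
                raise FormatError(f"{col} must be non-negative")
            df[col] = vals
    return df


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample_id": str, "donor_id": str, "cell_type": str})
    return validate_sample_table(df)


def write_sample_table(df: pd.DataFrame, path: str | Path,
                       seed: int | None = None) -> None:
    write_tsv(validate_sample_table(df), path, seed=seed, index=False)


# ---------------------------------------------------------------------------
# intervals: peaks, conservation tracks, SNPs
# ---------------------------------------------------------------------------

PEAK_COLUMNS = ("chrom", "start", "end", "peak_id", "score", "category", "gene_id")
PEAK_CATEGORIES = ("promoter", "gene_body", "other", "unassigned")


def new_peak_set(chrom, start, end, peak_id, score=None) -> pd.DataFrame:
    """Assemble an unannotated peak table (category=unassigned)."""
    df = pd.DataFrame({"chrom": pd.Series(chrom, dtype=str),
                       "start": pd.Series(start, dtype=np.int64),
                       "end": pd.Series(end, dtype=np.int64)})
    df["peak_id"] = pd.Series(peak_id, dtype=str)
    df["score"] = np.nan if score is None else np.asarray(score, dtype=float)
    df["category"] = "unassigned"
    df["gene_id"] = pd.NA
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"]].iloc[0]
        raise FormatError(f"peak {bad['peak_id']!r}: start >= end")
    return df


def read_intervals(path: str | Path, kind: str = "bed", *,
                   conservation: bool = False) -> pd.DataFrame:
    """Read BED4 / narrowPeak peak files or a bedGraph track.

    ``conservation=True`` additionally checks bedGraph scores lie in [0, 1].
    bedGraph runs must be sorted and non-overlapping per chromosome.
    """
    path = Path(path)
    if kind in ("bed", "narrowPeak"):
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 3:
            raise FormatError(f"{path}: BED needs at least 3 columns")
        chrom = df[0].astype(str)
        start = df[1].astype(np.int64)
        end = df[2].astype(np.int64)
        peak_id = (df[3].astype(str) if df.shape[1] > 3
                   else pd.Series([f"peak{i}" for i in range(len(df))]))
        score = df[4].astype(float) if df.shape[1] > 4 else None
        return new_peak_set(chrom, start, end, peak_id, score)
    if kind == "bedgraph":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "score"],
                         dtype={"chrom": str})
        return validate_track(df, conservation=conservation, source=str(path))
    raise ValueError(f"unknown interval kind {kind!r}")


def validate_track(df: pd.DataFrame, *, conservation: bool = False,
                   source: str = "track") -> pd.DataFrame:
    df = df[["chrom", "start", "end", "score"]].copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["score"] = df["score"].astype(float)
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{source}: run with start >= end")
    if conservation and ((df["score"] < 0) | (df["score"] > 1)).any():
        bad = df.loc[(df["score"] < 0) | (df["score"] > 1)].iloc[0]
        raise FormatError(
            f"{source}: conservation score {bad['score']} outside [0,1] "
            f"at {bad['chrom']}:{bad['start']}-{bad['end']}")
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    for chrom, grp in df.groupby("chrom", sort=False):
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise FormatError(f"{source}: overlapping runs on {chrom}")
    return df


def write_intervals(df: pd.DataFrame, path: str | Path, kind: str = "bed") -> None:
    path = Path(path)
    if kind == "bed":
        cols = [df["chrom"], df["start"], df["end"], df["peak_id"]]
        if df["score"].notna().any():
            cols.append(df["score"].fillna(0))
        pd.concat(cols, axis=1).to_csv(path, sep="\t", header=False, index=False)
    elif kind == "bedgraph":
        df[["chrom", "start", "end", "score"]].to_csv(
            path, sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown interval kind {kind!r}")


def read_snps(path: str | Path) -> pd.DataFrame:
    """Read SNP positions as 1-bp BED intervals (0-based)."""
    df = read_intervals(path, kind="bed")
    if ((df["end"] - df["start"]) != 1).any():
        raise FormatError(f"{path}: SNP intervals must be exactly 1 bp")
    return df.rename(columns={"peak_id": "snp_id"})[["chrom", "start", "end", "snp_id"]]


# ---------------------------------------------------------------------------
# ortholog tables
# ---------------------------------------------------------------------------

def ortholog_species(table: pd.DataFrame) -> list[str]:
    return [c[:-len("_gene")] for c in table.columns if c.endswith("_gene")]


def validate_ortholog_table(df: pd.DataFrame) -> pd.DataFrame:
    species = ortholog_species(df)
    if len(species) < 2:
        raise FormatError("ortholog table needs >= 2 species (<sp>_gene columns)")
    for sp in species:
        for suffix in ("_gene", "_transcript"):
            if sp + suffix not in df.columns:
                raise FormatError(f"ortholog table missing column {sp + suffix}")
    pairs = [tuple(sorted(p)) for p in
             __import__("itertools").combinations(species, 2)]
    for a, b in pairs:
        col = f"conf_{a}_{b}"
        if col not in df.columns:
            raise FormatError(f"ortholog table missing confidence column {col}")
        if not df[col].isin([0, 1]).all():
            raise FormatError(f"{col}: confidence must be 0 or 1")
    return df


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    return validate_ortholog_table(pd.read_csv(path, sep="\t", comment="#"))


def write_ortholog_table(df: pd.DataFrame, path: str | Path,
                         seed: int | None = None) -> None:
    write_tsv(validate_ortholog_table(df), path, seed=seed, index=False)


# ---------------------------------------------------------------------------
# generic TSV output with provenance header
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, *, seed: int | None = None,
              index: bool = True, extra: Mapping[str, object] | None = None) -> None:
    """Write a TSV with a commented provenance header (tool version, seed)."""
    header = f"# crosscell v{__version__}"
    if seed is not None:
        header += f" seed={seed}"
    for k, v in (extra or {}).items():
        header += f" {k}={v}"
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    Path(path).write_text(header + "\n" + buf.getvalue())


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
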