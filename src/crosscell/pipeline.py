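"""Configuration-driven orchestration of the full analysis.

A YAML/JSON config names the inputs (counts per species, sample
metadata, gene models, ortholog table, optional peaks / conservation /
single-cell inputs), the threshold block, the SI block and the output
directory.  ``run_pipeline`` executes harmonize -> normalization/DE ->
specificity index -> species enrichment -> (optional) partition null ->
(optional) single-cell validation -> (optional) peaks/conservation, and
writes a run manifest recording the tool version, seed, thresholds and
SHA-256 checksums of every input, so a rerun with the same config and
seed reproduces every output byte-identically.

Unknown config keys are rejected: a typo in a threshold name must fail
loudly, not fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .de import nb_wald_test
from .enrichment import (EnrichmentThresholds, call_species_enriched,
                         define_housekeeping, partition_null)
from .io import (gene_lengths, models_by_id, read_counts, read_gene_models,
                 read_intervals, read_ortholog_table, read_sample_table,
                 write_tsv)
from .normalize import fpkm
from .orthologs import harmonize, subset_counts_to_universe, tuple_ids
from .peaks import assign_peaks, compare_groups, peak_conservation
from .specificity import si_preprocess, si_sampled

_TOP_LEVEL_KEYS = {"inputs", "thresholds", "si", "single_cell", "promoter",
                   "partition_null", "output_dir", "seed"}
_INPUT_KEYS = {"counts_by_species", "sample_table", "gene_models_by_species",
               "ortholog_table", "peaks", "conservation"}
_SI_KEYS = {"iterations"}
_PARTITION_KEYS = {"enabled", "cell_type", "species", "k"}


class PipelineConfigError(ValueError):
    """The pipeline config failed validation before any compute ran."""


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise PipelineConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    _check_keys(cfg, _TOP_LEVEL_KEYS, "config")
    for key in ("inputs", "output_dir", "seed"):
        if key not in cfg:
            raise PipelineConfigError(f"config missing required key {key!r}")
    _check_keys(cfg["inputs"], _INPUT_KEYS, "inputs")
    for key in ("counts_by_species", "sample_table", "gene_models_by_species",
                "ortholog_table"):
        if key not in cfg["inputs"]:
            raise PipelineConfigError(f"inputs missing required key {key!r}")
    thr = cfg.get("thresholds", {})
    allowed = {f.name for f in dataclasses.fields(EnrichmentThresholds)}
    _check_keys(thr, allowed, "thresholds")
    for name, value in thr.items():
        if not (isinstance(value, (int, float)) and value > 0):
            raise PipelineConfigError(f"threshold {name!r} must be positive")
    _check_keys(cfg.get("si", {}), _SI_KEYS, "si")
    _check_keys(cfg.get("partition_null", {}), _PARTITION_KEYS, "partition_null")
    paths = [*cfg["inputs"]["counts_by_species"].values(),
             cfg["inputs"]["sample_table"],
             *cfg["inputs"]["gene_models_by_species"].values(),
             cfg["inputs"]["ortholog_table"]]
    for p in (cfg["inputs"].get("peaks"), cfg["inputs"].get("conservation")):
        if p:
            paths.append(p)
    for p in paths:
        if not Path(p).exists():
            raise PipelineConfigError(f"input path does not exist: {p}")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path) -> dict[str, Any]:
    """Run the full analysis described by a validated config.

    Returns the result bundle (in-memory objects per stage) and writes
    TSV outputs plus ``manifest.json`` and a structured JSON-lines log to
    the output directory.  Any stage error aborts with the stage name.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    cfg = config
    seed = int(cfg["seed"])
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = EnrichmentThresholds(**cfg.get("thresholds", {}))
    log_path = out_dir / "run_log.jsonl"
    log_entries: list[dict] = []

    def _log(stage: str, t0: float, **info) -> None:
        entry = {"stage": stage, "wall_s": round(time.perf_counter() - t0, 3),
                 **info}
        log_entries.append(entry)
        with open(log_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        _log(name, t0)
        return result

    log_path.write_text("")
    inputs = cfg["inputs"]
    bundle: dict[str, Any] = {}

    # --- load inputs -------------------------------------------------------
    def _load():
        counts = {sp: read_counts(p) for sp, p in
                  inputs["counts_by_species"].items()}
        models = {sp: read_gene_models(p) for sp, p in
                  inputs["gene_models_by_species"].items()}
        samples = read_sample_table(inputs["sample_table"])
        orthologs = read_ortholog_table(inputs["ortholog_table"])
        return counts, models, samples, orthologs

    counts_by_species, models_by_sp, samples, ortho_table = _stage("load", _load)
    species = sorted(counts_by_species)

    # --- ortholog harmonization -------------------------------------------
    universe = _stage("harmonize", lambda: harmonize(
        ortho_table, {sp: models_by_id(models_by_sp[sp]) for sp in models_by_sp}))
    write_tsv(universe.universe, out_dir / "universe.tsv", seed=seed, index=False)
    write_tsv(universe.audit, out_dir / "harmonize_audit.tsv", seed=seed,
              index=False)
    bundle["universe"] = universe

    # --- cross-species alignment and expression summaries ------------------
    aligned = _stage("align", lambda: subset_counts_to_universe(
        counts_by_species, universe))
    adf = aligned.to_frame()
    meta = samples.set_index("sample_id").loc[list(adf.columns)].reset_index()
    tuple_len = universe.universe[[f"{sp}_length" for sp in universe.species]] \
        .mean(axis=1)
    tuple_len.index = pd.Index(tuple_ids(universe), name="gene_id")
    fpkm_all = fpkm(adf, tuple_len)
    log2fpkm = pd.DataFrame(
        __import__("numpy").log2(fpkm_all.to_numpy() + 1.0),
        index=fpkm_all.index, columns=fpkm_all.columns)
    cols = pd.MultiIndex.from_frame(meta[["species", "cell_type"]])
    fpkm_means = log2fpkm.T.groupby(cols).mean().T
    fpkm_sp_means = log2fpkm.T.groupby(meta["species"].to_numpy()).mean().T
    bundle["fpkm_means"] = fpkm_means

    # --- differential expression per cell type and pooled -------------------
    sp_pair = tuple(sorted(set(meta["species"]), reverse=True))

    def _de():
        per_ct = {}
        for ct in sorted(set(meta["cell_type"])):
            sel = meta.loc[meta["cell_type"] == ct, "sample_id"]
            per_ct[ct] = nb_wald_test(adf[list(sel)],
                                      meta[meta["cell_type"] == ct],
                                      "species", reference=sp_pair[1])
        de_all = nb_wald_test(adf, meta, "species", blocking=("cell_type",),
                              reference=sp_pair[1])
        return per_ct, de_all

    de_by_ct, de_all = _stage("de", _de)
    for ct, de in de_by_ct.items():
        write_tsv(de, out_dir / f"de_{ct}.tsv", seed=seed)
    write_tsv(de_all, out_dir / "de_all_celltypes.tsv", seed=seed)
    bundle["de_by_celltype"] = de_by_ct
    bundle["de_all"] = de_all

    # --- specificity index per species --------------------------------------
    iterations = int(cfg.get("si", {}).get("iterations", 1000))

    def _si():
        tables = {}
        for sp in species:
            cm = counts_by_species[sp]
            sub = samples[samples["sample_id"].isin(cm.sample_ids)]
            lengths = gene_lengths(models_by_sp[sp])
            inp = si_preprocess(cm, sub, lengths)
            tables[sp] = si_sampled(inp, iterations=iterations, seed=seed)
        return tables

    si_tables = _stage("specificity_index", _si)
    for sp, table in si_tables.items():
        write_tsv(table.ranks, out_dir / f"si_{sp}.tsv", seed=seed,
                  extra={"iterations": iterations})
    bundle["si_tables"] = si_tables

    # --- species enrichment and housekeeping --------------------------------
    def _enrich():
        call = call_species_enriched(de_by_ct, fpkm_means, de_all,
                                     thresholds, species_pair=sp_pair)
        hk = define_housekeeping(de_all, fpkm_sp_means, thresholds)
        return call, hk

    call, housekeeping = _stage("species_enrichment", _enrich)
    rows = [{"cell_type": ct, "species": sp, "gene_id": g}
            for (ct, sp), df in call.calls.items() for g in df.index]
    write_tsv(pd.DataFrame(rows, columns=["cell_type", "species", "gene_id"]),
              out_dir / "species_enriched.tsv", seed=seed, index=False)
    write_tsv(pd.DataFrame({"gene_id": housekeeping}),
              out_dir / "housekeeping.tsv", seed=seed, index=False)
    (out_dir / "enrichment_audit.json").write_text(json.dumps(
        {"thresholds": thresholds.as_dict(),
         "n_pan_species": int(len(call.pan_species_genes)),
         "counts": {f"{ct}|{sp}": int(len(df))
                    for (ct, sp), df in call.calls.items()}},
        indent=2, sort_keys=True))
    bundle["enrichment"] = call
    bundle["housekeeping"] = housekeeping

    # --- optional partition null --------------------------------------------
    pn_cfg = cfg.get("partition_null", {})
    if pn_cfg.get("enabled", False):
        def _pn():
            ct = pn_cfg["cell_type"]
            sp = pn_cfg.get("species")
            sel = meta[meta["cell_type"] == ct]
            if sp:
                sel = sel[sel["species"] == sp]
            return partition_null(adf[list(sel["sample_id"])], sel,
                                  int(pn_cfg.get("k", 3)), thresholds)
        pn = _stage("partition_null", _pn)
        write_tsv(pn.table, out_dir / "partition_null.tsv", seed=seed,
                  index=False)
        bundle["partition_null"] = pn

    # --- optional peaks / conservation --------------------------------------
    if inputs.get("peaks"):
        def _peaks():
            peaks = read_intervals(inputs["peaks"], kind="bed")
            focal_sp = species[0]
            annotated = assign_peaks(peaks, models_by_sp[focal_sp])
            result = {"annotated": annotated}

            def _per_species(tuple_id: str) -> str:
                parts = dict(zip(universe.species, tuple_id.split("|")))
                return parts[focal_sp]

            if inputs.get("conservation"):
                track = read_intervals(inputs["conservation"],
                                       kind="bedgraph", conservation=True)
                annotated["mean_conservation"] = peak_conservation(
                    track, annotated)
                enriched_genes = {g for (ct, sp), df in call.calls.items()
                                  for g in df.index}
                cons = annotated.dropna(subset=["gene_id"])
                in_set = cons["gene_id"].isin(
                    {_per_species(g) for g in enriched_genes})
                hk_set = cons["gene_id"].isin(
                    {_per_species(g) for g in housekeeping})
                if in_set.sum() >= 2 and hk_set.sum() >= 2:
                    result["conservation_test"] = compare_groups(
                        cons.loc[in_set, "mean_conservation"],
                        cons.loc[hk_set, "mean_conservation"],
                        alternative="less")
            return result
        pk = _stage("peaks_conservation", _peaks)
        write_tsv(pk["annotated"], out_dir / "peaks_annotated.tsv", seed=seed,
                  index=False)
        bundle["peaks"] = pk

    # --- manifest ------------------------------------------------------------
    manifest = {
        "tool": "crosscell", "version": __version__, "seed": seed,
        "thresholds": thresholds.as_dict(),
        "si_iterations": iterations,
        "input_checksums": {
            str(p): _sha256(p) for p in _iter_input_paths(inputs)},
        "stages": [e["stage"] for e in log_entries],
    }
    manifest_json = json.dumps(manifest, indent=2, sort_keys=True)
    manifest["manifest_sha256"] = hashlib.sha256(
        manifest_json.encode()).hexdigest()
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle


def _iter_input_paths(inputs: dict):
    for p in inputs["counts_by_species"].values():
        yield p
    yield inputs["sample_table"]
    for p in inputs["gene_models_by_species"].values():
        yield p
    yield inputs["ortholog_table"]
    for key in ("peaks", "conservation"):
        if inputs.get(key):
            yield inputs[key]
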