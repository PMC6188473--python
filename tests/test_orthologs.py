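"""Ortholog harmonization against an independent set-theoretic oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crosscell.io import GeneModel, models_by_id
from crosscell.orthologs import (HarmonizedUniverse, harmonize,
                                 subset_counts_to_universe, universe_as_table)
from crosscell.simulate import simulate_gene_models, simulate_ortholog_table
from crosscell.io import CountMatrix


def harmonize_oracle(table: pd.DataFrame,
                     models: dict[str, dict[str, GeneModel]]) -> set[tuple]:
    """Row-by-row evaluation of the five filter predicates, written
    independently of the pipeline implementation."""
    species = [c[:-5] for c in table.columns if c.endswith("_gene")]
    conf_cols = [c for c in table.columns if c.startswith("conf_")]
    rows = [dict(r) for _, r in table.iterrows()]
    # predicate 1: confidence
    rows = [r for r in rows if all(r[c] != 0 for c in conf_cols)]
    # predicate 2: duplicates
    seen, dedup = set(), []
    for r in rows:
        key = tuple(sorted(r.items()))
        if key not in seen:
            seen.add(key)
            dedup.append(r)
    rows = dedup
    # predicate 3: strict 1:1 transcripts
    partners = {}
    for r in rows:
        for a in species:
            for b in species:
                if a != b:
                    partners.setdefault((a, r[f"{a}_transcript"]), set()).add(
                        (b, r[f"{b}_transcript"]))
    bad_tx = {key for key, vals in partners.items()
              if any(len({v for sp2, v in vals if sp2 == b}) > 1
                     for b in species)}
    rows = [r for r in rows
            if not any((sp, r[f"{sp}_transcript"]) in bad_tx
                       for sp in species)]
    # collapse to gene tuples, drop genes in more than one tuple
    tuples = sorted({tuple(r[f"{sp}_gene"] for sp in species) for r in rows})
    for i, sp in enumerate(species):
        counts = {}
        for t in tuples:
            counts[t[i]] = counts.get(t[i], 0) + 1
        tuples = [t for t in tuples if counts[t[i]] == 1]
    # predicates 4+5: gene-span lengths after longest-transcript selection
    out = set()
    for t in tuples:
        lengths = [models[sp][g].length_bp for sp, g in zip(species, t)]
        if min(lengths) >= 1000 and max(lengths) / min(lengths) <= 2.0:
            out.add(t)
    return out


def tiny_models(spec):
    """spec: {species: [(gene, length, [transcript lengths...]), ...]}"""
    out = {}
    for sp, genes in spec.items():
        models = {}
        start = 1000
        for gid, length, tx in genes:
            txs = tuple((f"{gid}.t{k + 1}", start, start + tl)
                        for k, tl in enumerate(tx))
            models[gid] = GeneModel(gid, "chr1", "+", start, start + length,
                                    txs or ((f"{gid}.t1", start, start + length),))
            start += length + 5000
        out[sp] = models
    return out


def simple_table(rows):
    df = pd.DataFrame(rows, columns=["mouse_gene", "mouse_transcript",
                                     "human_gene", "human_transcript"])
    df["conf_human_mouse"] = 1
    return df


class TestHarmonizeRules:
    def test_clean_table_fully_survives(self):
        models = tiny_models({
            "mouse": [("m1", 2000, [2000]), ("m2", 1500, [1500])],
            "human": [("h1", 2500, [2500]), ("h2", 1200, [1200])]})
        table = simple_table([("m1", "m1.t1", "h1", "h1.t1"),
                              ("m2", "m2.t1", "h2", "h2.t1")])
        uni = harmonize(table, models)
        assert len(uni) == 2
        assert uni.audit["rows_removed"].sum() == 0

    def test_low_confidence_row_removed(self):
        models = tiny_models({"mouse": [("m1", 2000, [2000])],
                              "human": [("h1", 2000, [2000])]})
        table = simple_table([("m1", "m1.t1", "h1", "h1.t1")])
        table["conf_human_mouse"] = 0
        assert len(harmonize(table, models)) == 0

    def test_non_one_to_one_removes_both_sides(self):
        models = tiny_models({
            "mouse": [("m1", 2000, [2000])],
            "human": [("h1", 2000, [2000, 1500])]})
        # m1.t1 maps to two human transcripts -> all its rows removed
        table = simple_table([("m1", "m1.t1", "h1", "h1.t1"),
                              ("m1", "m1.t1", "h1", "h1.t2")])
        uni = harmonize(table, models)
        assert len(uni) == 0
        step = uni.audit.set_index("step").loc["one_to_one"]
        assert step["rows_removed"] == 2

    def test_length_ratio_boundary_exactly_two_retained(self):
        models = tiny_models({
            "mouse": [("m1", 1000, [1000]), ("m2", 1000, [1000])],
            "human": [("h1", 2000, [2000]), ("h2", 2100, [2100])]})
        table = simple_table([("m1", "m1.t1", "h1", "h1.t1"),
                              ("m2", "m2.t1", "h2", "h2.t1")])
        uni = harmonize(table, models)
        # ratio exactly 2 kept; 2.1 dropped ("more than two-fold" is strict)
        assert uni.gene_tuples() == [("m1", "h1")]

    def test_length_boundary_exactly_1kb_retained(self):
        models = tiny_models({"mouse": [("m1", 1000, [1000])],
                              "human": [("h1", 1000, [1000])]})
        table = simple_table([("m1", "m1.t1", "h1", "h1.t1")])
        assert len(harmonize(table, models)) == 1

    def test_length_uses_gene_span_not_chosen_transcript(self):
        # transcripts shorter than the gene span; the 1 kb rule reads the span
        models = tiny_models({"mouse": [("m1", 1500, [1500, 800])],
                              "human": [("h1", 1500, [1500, 700])]})
        table = simple_table([("m1", "m1.t2", "h1", "h1.t2")])
        uni = harmonize(table, models)
        assert len(uni) == 1
        assert uni.universe.loc[0, "mouse_length"] == 1500
        # the longest transcript is chosen as the annotation
        assert uni.universe.loc[0, "mouse_transcript"] == "m1.t1"

    def test_unresolvable_transcript_named_in_error(self):
        models = tiny_models({"mouse": [("m1", 2000, [2000])],
                              "human": [("h1", 2000, [2000])]})
        table = simple_table([("m1", "m1.tX", "h1", "h1.t1")])
        with pytest.raises(KeyError, match="m1.tX"):
            harmonize(table, models)


class TestHarmonizeProperties:
    def _random_case(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 80))
        models = {sp: simulate_gene_models(n, seed=seed * 7 + k)
                  for k, sp in enumerate(("mouse", "human"))}
        table, _ = simulate_ortholog_table(
            models,
            frac_low_conf=float(rng.uniform(0, 0.3)),
            frac_duplicate=float(rng.uniform(0, 0.2)),
            frac_non_one_to_one=float(rng.uniform(0, 0.3)),
            frac_length_divergent=float(rng.uniform(0, 0.3)),
            seed=seed)
        return table, {sp: models_by_id(m) for sp, m in models.items()}

    @pytest.mark.parametrize("seed", range(25))
    def test_survivors_equal_set_theoretic_oracle(self, seed):
        table, models = self._random_case(seed)
        uni = harmonize(table, models)
        assert set(uni.gene_tuples()) == harmonize_oracle(table, models)

    def test_audit_removals_sum_to_input_minus_survivors(self):
        table, models = self._random_case(101)
        uni = harmonize(table, models)
        audit = uni.audit
        # within each stage, rows_in - rows_out = rows_removed
        assert (audit["rows_in"] - audit["rows_out"]
                == audit["rows_removed"]).all()

    def test_idempotence(self):
        table, models = self._random_case(55)
        uni = harmonize(table, models)
        again = harmonize(universe_as_table(uni), models)
        assert set(again.gene_tuples()) == set(uni.gene_tuples())

    def test_truth_tags_match_survivors(self):
        models = {sp: simulate_gene_models(100, seed=s)
                  for sp, s in (("mouse", 1), ("human", 2))}
        table, truth = simulate_ortholog_table(
            models, frac_low_conf=0.1, frac_duplicate=0.1,
            frac_non_one_to_one=0.1, frac_length_divergent=0.2, seed=9)
        uni = harmonize(table, {sp: models_by_id(m)
                                for sp, m in models.items()})
        assert set(uni.universe["mouse_gene"]) == \
            set(truth.index[truth["expected_survive"]])

    def test_all_violations_planted_kills_everything(self):
        models = {sp: simulate_gene_models(40, seed=s)
                  for sp, s in (("mouse", 3), ("human", 4))}
        table, _ = simulate_ortholog_table(models, frac_low_conf=1.0, seed=1)
        uni = harmonize(table, {sp: models_by_id(m)
                                for sp, m in models.items()})
        assert len(uni) == 0


class TestSubsetCounts:
    def _universe(self):
        uni = pd.DataFrame({
            "mouse_gene": ["m1", "m2", "m3"],
            "human_gene": ["h1", "h2", "h3"],
            "mouse_transcript": ["m1.t1", "m2.t1", "m3.t1"],
            "human_transcript": ["h1.t1", "h2.t1", "h3.t1"],
            "mouse_length": [2000] * 3, "human_length": [2000] * 3})
        return HarmonizedUniverse(universe=uni, species=["mouse", "human"])

    def test_shape_and_row_order(self):
        counts = {
            "mouse": CountMatrix(np.arange(8).reshape(4, 2),
                                 ["m9", "m1", "m2", "m3"], ["ms1", "ms2"]),
            "human": CountMatrix(np.arange(6).reshape(3, 2),
                                 ["h3", "h1", "h2"], ["hs1", "hs2"])}
        aligned = subset_counts_to_universe(counts, self._universe())
        assert aligned.shape == (3, 4)
        assert list(aligned.gene_ids) == ["m1|h1", "m2|h2", "m3|h3"]
        # row 0 = mouse m1 then human h1
        assert aligned.counts[0].tolist() == [2, 3, 2, 3]

    def test_missing_gene_errors(self):
        counts = {
            "mouse": CountMatrix(np.ones((2, 1), int), ["m1", "m2"], ["s"]),
            "human": CountMatrix(np.ones((3, 1), int),
                                 ["h1", "h2", "h3"], ["t"])}
        with pytest.raises(KeyError, match="m3"):
            subset_counts_to_universe(counts, self._universe())

    def test_empty_universe_errors(self):
        empty = HarmonizedUniverse(
            universe=self._universe().universe.iloc[:0],
            species=["mouse", "human"])
        with pytest.raises(ValueError, match="empty"):
            subset_counts_to_universe({}, empty)
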