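"""Predictor merging, anti-concordance screening and the bipartite network."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from mirnetppi import mir_target_integration as mti
from mirnetppi.diffexpr import DECall
from mirnetppi.io_formats import TargetPredictionTable


def table(source, pairs):
    return TargetPredictionTable(
        pd.DataFrame([(m, g, source, None) for m, g in pairs],
                     columns=["mirna_id", "gene_id", "source", "score"])
    )


class TestMergePredictions:
    def test_disjoint_tables(self):
        merged = mti.merge_predictions(
            [table("targetscan", [("m1", "A")]), table("mirdb", [("m1", "B")])], {"m1"}
        )
        assert merged.intersection_pairs == set()
        assert merged.intersection_genes == set()
        assert merged.shared_gene_percentage == 0
        assert merged.union_genes == {"A", "B"}

    def test_printed_overlap_arithmetic(self):
        # union of 4,342 target genes, 1,587 shared -> floor gives 36 %
        assert mti.shared_percentage(1587, 4342) == 36

    def test_restriction_to_called_mirnas(self):
        merged = mti.merge_predictions(
            [table("targetscan", [("m1", "A"), ("m2", "B")])], {"m1"}
        )
        assert merged.union_pairs == {("m1", "A")}

    def test_random_tables_match_bruteforce_set_algebra(self):
        rng = np.random.default_rng(13)
        mirnas = [f"m{i}" for i in range(10)]
        genes = [f"G{i}" for i in range(200)]
        pa = {(mirnas[rng.integers(10)], genes[rng.integers(200)]) for _ in range(300)}
        pb = {(mirnas[rng.integers(10)], genes[rng.integers(200)]) for _ in range(300)}
        restrict = set(mirnas[:6])
        merged = mti.merge_predictions(
            [table("targetscan", sorted(pa)), table("mirdb", sorted(pb))], restrict
        )
        fa = {p for p in pa if p[0] in restrict}
        fb = {p for p in pb if p[0] in restrict}
        assert merged.union_pairs == fa | fb
        assert merged.intersection_pairs == fa & fb
        assert merged.union_genes == {g for _, g in fa | fb}
        assert merged.intersection_genes == {g for _, g in fa} & {g for _, g in fb}
        counts = {}
        for m, g in fa | fb:
            counts.setdefault(g, set()).add(m)
        assert merged.multi_targeted_genes == {g for g, ms in counts.items() if len(ms) >= 2}
        assert merged.shared_gene_percentage == math.floor(
            100 * len(merged.intersection_genes) / len(merged.union_genes)
        )

    def test_invariants_on_synthetic_study(self, default_study):
        t = default_study.truth
        merged = mti.merge_predictions(
            [default_study.targetscan, default_study.mirdb], set(t.de_up) | set(t.de_down)
        )
        for src_pairs in merged.per_source.values():
            assert merged.intersection_pairs <= src_pairs <= merged.union_pairs

    def test_empty_restrict_rejected(self):
        with pytest.raises(ValueError):
            mti.merge_predictions([table("targetscan", [("m", "g")])], set())


def _screen_fixture(gene_slope):
    """6-sample miRNA/mRNA matrices with one predicted pair, gene = slope*mirna."""
    samples = [f"s{i}" for i in range(6)]
    labels = ["WT"] * 3 + ["KO"] * 3
    mir = np.array([[1.0, 2, 3, 7, 8, 9]])
    gene = gene_slope * mir + 20.0
    mirna = make_matrix(mir, ["m1"], samples, labels)
    mrna = make_matrix(gene, ["G1"], samples, labels, mode="fpkm")
    merged = mti.merge_predictions([table("targetscan", [("m1", "G1")])], {"m1"})
    calls = [DECall("m1", 3.0, "up", None, True)]
    return merged, calls, mirna, mrna


class TestScreenNegativePairs:
    def test_perfect_anticorrelation_passes(self):
        merged, calls, mirna, mrna = _screen_fixture(-1.0)
        res = mti.screen_negative_pairs(merged, calls, mirna, mrna)
        (pair,) = res.pairs
        assert res.method == "pearson"
        assert pair.correlation == pytest.approx(-1.0)
        assert pair.passed

    def test_positive_correlation_rejected(self):
        merged, calls, mirna, mrna = _screen_fixture(+1.0)
        res = mti.screen_negative_pairs(merged, calls, mirna, mrna)
        assert not res.pairs[0].passed

    def test_direction_opposition_on_two_samples(self):
        samples = ["WT1", "KO1"]
        labels = ["WT", "KO"]
        mirna = make_matrix([[1.0, 9.0]], ["m1"], samples, labels)
        mrna = make_matrix([[8.0, 2.0], [2.0, 8.0]], ["Gdown", "Gup"], samples, labels, mode="fpkm")
        merged = mti.merge_predictions(
            [table("targetscan", [("m1", "Gdown"), ("m1", "Gup")])], {"m1"}
        )
        calls = [DECall("m1", 2.0, "up", None, True)]
        res = mti.screen_negative_pairs(merged, calls, mirna, mrna)
        assert res.method == "direction-opposition"
        by_gene = {p.gene: p for p in res.pairs}
        assert by_gene["Gdown"].passed  # miRNA up, gene down
        assert not by_gene["Gup"].passed  # same direction -> rejected

    def test_missing_gene_reported_not_dropped_silently(self):
        merged, calls, mirna, mrna = _screen_fixture(-1.0)
        merged.union_pairs.add(("m1", "GHOST"))
        res = mti.screen_negative_pairs(merged, calls, mirna, mrna)
        assert ("m1", "GHOST", "no gene expression row") in res.missing

    def test_threshold_monotonicity(self, default_study):
        s = default_study
        merged = mti.merge_predictions(
            [s.targetscan, s.mirdb], set(s.truth.de_up) | set(s.truth.de_down)
        )
        calls = [DECall(m, 1.0, "up", None, True) for m in s.truth.de_up]
        calls += [DECall(m, -1.0, "down", None, True) for m in s.truth.de_down]
        passed = {}
        for thr in (0.0, -0.3, -0.8):
            r = mti.screen_negative_pairs(merged, calls, s.mirna_matrix, s.mrna_matrix,
                                          threshold=thr)
            passed[thr] = {(p.mirna, p.gene) for p in r.passed_pairs}
        assert passed[-0.8] <= passed[-0.3] <= passed[0.0]
        assert passed[0.0] <= merged.union_pairs

    def test_planted_truth_recovery(self, default_study):
        """True targets are coupled negatively; decoys are independent."""
        s = default_study
        calls = [DECall(m, 1.0, "up", None, True) for m in s.truth.de_up]
        calls += [DECall(m, -1.0, "down", None, True) for m in s.truth.de_down]
        merged = mti.merge_predictions(
            [s.targetscan, s.mirdb], {c.feature_id for c in calls}
        )
        res = mti.screen_negative_pairs(merged, calls, s.mirna_matrix, s.mrna_matrix)
        true = set(map(tuple, s.truth.true_pairs))
        got = {(p.mirna, p.gene) for p in res.passed_pairs}
        tp = len(got & true)
        assert tp / len(true) >= 0.8  # sensitivity
        assert tp / len(got) >= 0.8  # precision


class TestBipartiteNetwork:
    def test_empty_input_empty_network(self):
        nodes, edges = mti.build_mir_mrna_network([], [], [])
        assert len(nodes) == 0 and len(edges) == 0

    def test_star_with_red_mirna_node(self):
        pairs = [
            mti.ScreenedPair("m1", g, "up", "down", -2.0, -0.9, "pearson", True)
            for g in ("G1", "G2")
        ]
        calls = [DECall("m1", 4.0, "up", None, True)]
        gcalls = [DECall("G1", -2.0, "down", None, True), DECall("G2", -1.0, "down", None, True)]
        nodes, edges = mti.build_mir_mrna_network(pairs, calls, gcalls)
        assert len(edges) == 2
        mrow = nodes[nodes["id"] == "m1"].iloc[0]
        assert mrow["color"] == "red" and mrow["intensity"] == 1.0
        assert set(nodes[nodes["type"] == "gene"]["color"]) == {"blue"}

    def test_degree_sequence_matches_bruteforce(self):
        rng = np.random.default_rng(21)
        pairs = sorted({(f"m{rng.integers(5)}", f"G{rng.integers(20)}") for _ in range(60)})
        spairs = [mti.ScreenedPair(m, g, "up", "down", -1.0, -0.5, "pearson", True)
                  for m, g in pairs]
        nodes, edges = mti.build_mir_mrna_network(spairs, [], [])
        deg = {}
        for m, g in pairs:
            deg[m] = deg.get(m, 0) + 1
            deg[g] = deg.get(g, 0) + 1
        for node in nodes["id"]:
            assert ((edges["source"] == node) | (edges["target"] == node)).sum() == deg[node]
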