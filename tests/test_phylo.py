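"""Curation, concatenation, distances, NJ against a four-point oracle, CSI."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import four_point_quartets, quartets_from_splits, random_additive_tree
from streampop import (
    MARKER_GENES_18,
    CsiSignature,
    bootstrap_support,
    column_weights,
    concatenate_partitions,
    csi_scan,
    curate_references,
    distance_matrix,
    nj_tree,
    tree_bipartitions,
)


def test_marker_set_has_18_genes():
    assert len(MARKER_GENES_18) == 18
    assert {"pheT", "rplE", "rplO", "rpsK", "rpsM"} <= set(MARKER_GENES_18)


class TestCurateReferences:
    def test_sixteen_of_eighteen_retained(self):
        tables = {"gA": MARKER_GENES_18[:16], "gB": MARKER_GENES_18[:15]}
        assert curate_references(tables) == ["gA"]

    def test_whitelist_overrides_threshold(self):
        tables = {"gA": MARKER_GENES_18[:16], "gB": MARKER_GENES_18[:15]}
        assert curate_references(tables, whitelist=["gB"]) == ["gA", "gB"]

    def test_total_must_cover_min(self):
        with pytest.raises(ValueError):
            curate_references({}, min_genes=16, total=10)


class TestConcatenation:
    def test_partitions_tile_the_width(self):
        aln = {
            "geneB": {"A": "M" * 200, "B": "K" * 200},
            "geneA": {"A": "L" * 100, "B": "V" * 100},
        }
        concat = concatenate_partitions(aln)
        assert concat.n_columns == 300
        spans = [(p.gene, p.start, p.stop) for p in concat.partitions]
        assert spans == [("geneA", 0, 100), ("geneB", 100, 300)]

    def test_missing_taxon_padded_with_gaps(self):
        aln = {
            "g1": {"A": "MMM", "B": "MMM"},
            "g2": {"A": "KK"},
        }
        concat = concatenate_partitions(aln)
        assert concat.row("B") == "MMM--"

    def test_informative_positions_need_two_states(self):
        aln = {"g": {"A": "MKA-", "B": "MLA-", "C": "ML-A"}}
        concat = concatenate_partitions(aln)
        # col0 all M (no); col1 K/L (yes); col2 A/A/- (no); col3 -/-/A (no)
        assert concat.informative_positions == 1

    def test_conflicting_row_lengths_rejected(self):
        with pytest.raises(ValueError):
            concatenate_partitions({"g": {"A": "MK", "B": "MKL"}})


class TestColumnWeights:
    def test_conserved_gapfree_column_full_weight(self):
        assert column_weights(["M", "M", "M", "M"])[0] == 1.0

    def test_half_gapped_conserved_column(self):
        assert column_weights(["M", "M", "-", "-"])[0] == 0.5

    def test_all_distinct_residues(self):
        assert column_weights(["M", "K", "L", "V"])[0] == 0.25


class TestDistanceMatrix:
    def test_identical_rows_zero_distance(self):
        concat = concatenate_partitions({"g": {"A": "MKLV" * 30, "B": "MKLV" * 30, "C": "AAAA" * 30}})
        D = distance_matrix(concat)
        assert D[0, 1] == 0.0
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_poisson_correction_formula(self):
        # 10% observed differences -> d = -0.95 ln(1 - 0.1/0.95)
        row_a = "A" * 100
        row_b = "C" * 10 + "A" * 90
        concat = concatenate_partitions({"g": {"A": row_a, "B": row_b, "C": row_a}})
        D = distance_matrix(concat, use_weights=False)
        assert D[0, 1] == pytest.approx(-0.95 * math.log(1 - 0.1 / 0.95), abs=1e-9)
        assert D[0, 1] == pytest.approx(0.1057, abs=2e-4)

    def test_saturation_caps_at_max_distance(self):
        concat = concatenate_partitions({"g": {"A": "A" * 50, "B": "C" * 50, "C": "G" * 50}})
        D = distance_matrix(concat, use_weights=False, max_distance=7.5)
        assert D[0, 1] == 7.5


class TestNjTree:
    def test_additive_four_taxon_topology(self):
        D = pd.DataFrame(
            [[0, 2, 5, 5], [2, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        splits = tree_bipartitions(nj_tree(D))
        assert splits == {frozenset({"C", "D"})}

    def test_three_taxon_closed_form(self):
        D = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = nj_tree(D)
        lengths = {}

        def collect(node):
            for child, bl in node.children:
                if not child.children:
                    lengths[child.name] = lengths.get(child.name, 0.0) + bl
                collect(child)

        collect(tree)
        assert lengths["A"] == pytest.approx(1.0)  # (3+4-5)/2
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_relabeling_permutes_leaves_not_topology(self):
        rng = np.random.default_rng(0)
        D, taxa, true_splits = random_additive_tree(5, rng)
        perm = list(rng.permutation(5))
        D2 = D[np.ix_(perm, perm)]
        taxa2 = [taxa[i] for i in perm]
        assert tree_bipartitions(nj_tree(D, taxa)) == tree_bipartitions(nj_tree(D2, taxa2))

    def test_recovers_random_additive_trees_vs_four_point_oracle(self):
        rng = np.random.default_rng(11)
        for i in range(30):
            n = 4 if i % 2 == 0 else 5
            D, taxa, true_splits = random_additive_tree(n, rng)
            splits = tree_bipartitions(nj_tree(D, taxa))
            assert splits == true_splits
            assert quartets_from_splits(splits, taxa) == four_point_quartets(D, taxa)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(D)


class TestBootstrap:
    def _signal_alignment(self, rng, n_cols=120):
        # two clear clades with many supporting columns
        taxa_states = {"A": "M", "B": "M", "C": "K", "D": "K", "E": "K"}
        rows = {t: [] for t in taxa_states}
        for _ in range(n_cols):
            noise = rng.random() < 0.05
            for t, s in taxa_states.items():
                c = s if not noise else "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
                rows[t].append(c)
        return {"g": {t: "".join(r) for t, r in rows.items()}}

    def test_unambiguous_clade_gets_full_support(self):
        rng = np.random.default_rng(3)
        result = bootstrap_support(
            concatenate_partitions(self._signal_alignment(rng)), n_reps=50, seed=5
        )
        assert result.supports[frozenset({"C", "D", "E"})] == 100.0

    def test_supports_bounded_and_reproducible(self):
        rng = np.random.default_rng(4)
        aln = concatenate_partitions(self._signal_alignment(rng))
        r1 = bootstrap_support(aln, n_reps=30, seed=9)
        r2 = bootstrap_support(aln, n_reps=30, seed=9)
        assert r1.supports == r2.supports
        assert all(0.0 <= v <= 100.0 for v in r1.supports.values())

    def test_star_like_data_has_weak_internal_support(self):
        rng = np.random.default_rng(6)
        taxa = list("ABCDE")
        aa = "ACDEFGHIKLMNPQRSTVWY"
        rows = {t: "".join(aa[rng.integers(0, 20)] for _ in range(150)) for t in taxa}
        result = bootstrap_support(concatenate_partitions({"g": rows}), n_reps=60, seed=7)
        assert result.supports  # an NJ tree of 5 taxa always has internal edges
        assert min(result.supports.values()) < 80.0


class TestCsiScan:
    SIG = CsiSignature("secY", left_flank="MKLW", right_flank="QRPV", reference_span=3)

    def test_reference_row_scores_zero(self):
        res = csi_scan({"ref": "MKLWAAAQRPV"}, self.SIG)
        assert res["ref"] == 0

    def test_insertion_counted_between_flanks(self):
        res = csi_scan({"x": "MKLWAAA--AAAAAQRPV"}, self.SIG)
        assert res["x"] == 5

    def test_missing_flank_not_found(self):
        res = csi_scan({"x": "AAAAQRPV"}, self.SIG)
        assert res["x"] is None

    def test_duplicate_flank_is_ambiguous(self):
        with pytest.raises(ValueError):
            csi_scan({"x": "MKLWAMKLWAQRPV"}, self.SIG)


def test_nj_matches_scikit_bio_on_additive_matrix():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(21)
    D, taxa, true_splits = random_additive_tree(5, rng)
    dm = skbio.DistanceMatrix(D, ids=taxa)
    sk_tree = skbio.tree.nj(dm)
    full = frozenset(taxa)
    anchor = min(taxa)
    sk_splits = set()
    for node in sk_tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(taxa) - 2:
            sk_splits.add(side if anchor not in side else full - side)
    assert tree_bipartitions(nj_tree(D, taxa)) == sk_splits == true_splits
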