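"""Alignment engine against a brute-force DP oracle; AAI/ANI/16S recovery."""

from __future__ import annotations

import numpy as np
import pytest

from _oracles import sw_score
from streampop import (
    AlignmentHit,
    PopulationSpec,
    SeededAligner,
    diverge_pair,
    diverge_proteome,
    local_align,
    pairwise_aai,
    pairwise_ani,
    rrna_identity,
    simulate_genome,
    simulate_proteome,
)
from streampop.identity import aai_pair_retained, ani_fragment_retained, nucleotide_scoring


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestLocalAlign:
    def test_identical_sequences(self):
        hit = local_align("ACGTACGTAA", "ACGTACGTAA")
        assert hit.identity == 1.0
        assert hit.columns == hit.matches == 10

    def test_hand_derived_substitution_alignment(self):
        hit = local_align("ACGTACGT", "ACGTTCGT")
        assert (hit.columns, hit.matches) == (8, 7)
        assert hit.identity == pytest.approx(0.875)

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError):
            local_align("ACGTACGT", "MKWQRPLE")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_matches_brute_force_dp_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            a = _random_dna(rng, int(rng.integers(20, 200)))
            b = _random_dna(rng, int(rng.integers(20, 200)))
            hit = local_align(a, b)
            expected = sw_score(a, b)
            got = 0.0 if hit is None else hit.score
            assert got == expected

    def test_seeded_path_equals_full_dp_on_related_pairs(self):
        # force the seeded path by shrinking the exact-DP cutoff
        rng = np.random.default_rng(7)
        for _ in range(20):
            b = _random_dna(rng, 200)
            start = int(rng.integers(0, 60))
            a = list(b[start : start + 120])
            for pos in rng.choice(120, size=6, replace=False):
                a[pos] = "ACGT"[(("ACGT".index(a[pos])) + 1) % 4]
            a = "".join(a)
            seeded = local_align(a, b, exact_cells=1)
            assert seeded is not None
            assert seeded.score == sw_score(a, b)

    def test_seeded_aligner_reports_subject_coordinates(self):
        rng = np.random.default_rng(1)
        subject = _random_dna(rng, 5000)
        query = subject[1200:2000]
        hit = SeededAligner(subject).align(query)
        assert hit.identity == 1.0
        assert hit.subject_span == (1200, 2000)


class TestPairwiseAai:
    def test_identical_proteomes(self):
        prot = simulate_proteome(25, seed=1, len_mean=250)
        res = pairwise_aai(prot, prot)
        assert res.mean == 100.0
        assert res.sd == 0.0
        assert res.n == 25

    def test_planted_divergence_recovered(self):
        pa = simulate_proteome(60, seed=2, len_mean=300)
        pb = diverge_proteome(pa, 0.94, seed=3)
        res = pairwise_aai(pa, pb)
        assert 92.0 <= res.mean <= 96.0
        # proteins shorter than 100 aa are rightly dropped by filter (3)
        assert res.n >= 55

    def test_symmetry_under_argument_swap(self):
        pa = simulate_proteome(30, seed=4, len_mean=250)
        pb = diverge_proteome(pa, 0.90, seed=5)
        ab = pairwise_aai(pa, pb)
        ba = pairwise_aai(pb, pa)
        assert abs(ab.mean - ba.mean) < 0.5

    def test_no_retained_pairs_is_undefined_not_error(self):
        pa = simulate_proteome(5, seed=6, len_mean=250)
        pb = simulate_proteome(5, seed=7, len_mean=250, name="other")
        assert pairwise_aai(pa, pb) is None

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            pairwise_aai({}, {"p": "MKL" * 50})

    @pytest.mark.parametrize(
        "identity,columns,span,subject_len,expected",
        [
            (0.28, 200, 200, 220, False),  # below the 30% identity floor
            (0.30, 200, 200, 220, True),
            (0.50, 99, 99, 120, False),  # alignment shorter than 100 residues
            (0.50, 150, 120, 200, False),  # covers only 60% of the subject
        ],
    )
    def test_retention_filters(self, identity, columns, span, subject_len, expected):
        hit = AlignmentHit(
            score=1.0,
            columns=columns,
            matches=int(identity * columns),
            identity=identity,
            query_span=(0, span),
            subject_span=(0, span),
        )
        assert aai_pair_retained(hit, subject_len) is expected


@pytest.fixture(scope="module")
def genome():
    return simulate_genome(PopulationSpec("g", 0.45, 100_000), seed=31)


class TestPairwiseAni:

    def test_self_comparison_is_100(self, genome):
        res = pairwise_ani(genome, genome)
        assert res.mean == 100.0
        assert res.sd == 0.0
        assert res.n >= 50

    def test_planted_divergence_and_symmetry(self, genome):
        other = diverge_pair(genome, 0.96, seed=32)
        ab = pairwise_ani(genome, other)
        ba = pairwise_ani(other, genome)
        assert abs(ab.mean - 96.0) <= 1.0
        assert abs(ba.mean - 96.0) <= 1.0
        assert abs(ab.mean - ba.mean) < 0.5

    def test_undefined_when_too_few_fragments_retained(self, genome):
        unrelated = simulate_genome(PopulationSpec("x", 0.45, 100_000), seed=33)
        assert pairwise_ani(genome, unrelated) is None

    @pytest.mark.parametrize(
        "identity,columns,span,expected",
        [
            (0.65, 1000, 1000, False),  # below the 70% identity floor
            (0.75, 1000, 1000, True),
            (0.75, 650, 650, False),  # aligned length under 700
            (0.75, 700, 650, False),  # fragment coverage under 70%... span 650/1000
        ],
    )
    def test_fragment_retention_filters(self, identity, columns, span, expected):
        hit = AlignmentHit(
            score=1.0,
            columns=columns,
            matches=int(identity * columns),
            identity=identity,
            query_span=(0, span),
            subject_span=(0, span),
        )
        assert ani_fragment_retained(hit, 1000) is expected


class TestRrnaIdentity:
    def _gene(self, seed, n=1400):
        rng = np.random.default_rng(seed)
        return _random_dna(rng, n)

    def test_identical_genes(self):
        g = self._gene(1)
        assert rrna_identity(g, g) == 100.0

    def test_two_percent_divergence(self):
        g = self._gene(2)
        rng = np.random.default_rng(3)
        other = list(g)
        for pos in rng.choice(len(g), size=28, replace=False):
            other[pos] = "ACGT"[("ACGT".index(other[pos]) + 1) % 4]
        ident = rrna_identity(g, "".join(other))
        assert abs(ident - 98.0) < 0.5

    def test_symmetric(self):
        a, b = self._gene(4), self._gene(5)
        assert rrna_identity(a, b) == pytest.approx(rrna_identity(b, a), abs=1e-9)

    def test_short_sequence_warns_but_computes(self):
        with pytest.warns(UserWarning):
            ident = rrna_identity("ACGT" * 30, "ACGT" * 30)
        assert ident == 100.0
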