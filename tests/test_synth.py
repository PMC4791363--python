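"""Generator contracts: determinism, planted parameters, truth tables."""

from __future__ import annotations

import numpy as np
import pytest

from streampop import (
    PopulationSpec,
    SurveySpec,
    diverge_pair,
    diverge_proteome,
    fragment_and_cover,
    simulate_genome,
    simulate_proteome,
    simulate_reads,
    simulate_survey,
)
from streampop._seq import revcomp, seq_to_codes


def test_genome_gc_converges_to_target():
    spec = PopulationSpec("g", 0.44, 100_000)
    genome = simulate_genome(spec, seed=3)
    assert abs(genome.gc - 0.44) < 0.01  # binomial sd here is ~0.0016


def test_genome_deterministic_given_seed():
    spec = PopulationSpec("g", 0.5, 20_000)
    a = simulate_genome(spec, seed=7)
    b = simulate_genome(spec, seed=7)
    c = simulate_genome(spec, seed=8)
    assert a.sequence == b.sequence
    assert a.sequence != c.sequence


def test_genome_uniform_base_composition_at_gc_half():
    genome = simulate_genome(PopulationSpec("g", 0.5, 100_000), seed=5)
    codes = seq_to_codes(genome.sequence)
    counts = np.bincount(codes, minlength=4)
    # each base ~ L/4; 5 sd of binomial(L, 1/4)
    tol = 5 * np.sqrt(100_000 * 0.25 * 0.75)
    assert np.all(np.abs(counts - 25_000) < tol)


def test_kmer_bias_shifts_word_frequencies():
    from streampop import word_frequency

    favored = {"ACGT": 8.0, "AGCT": 8.0}  # G+C-balanced words
    plain = simulate_genome(PopulationSpec("p", 0.5, 60_000), seed=11)
    biased = simulate_genome(
        PopulationSpec("b", 0.5, 60_000, kmer_bias=favored), seed=11
    )
    f_plain = word_frequency(plain.sequence, 4).freqs
    f_biased = word_frequency(biased.sequence, 4).freqs
    for word in favored:
        assert f_biased[word] > f_plain[word] * 1.2


def test_gc_target_validation():
    with pytest.raises(ValueError):
        PopulationSpec("bad", 1.2, 50_000)
    with pytest.raises(ValueError):
        simulate_genome(PopulationSpec("small", 0.5, 5_000), seed=0)


class TestDivergePair:
    def test_identity_one_is_exact_copy(self):
        g = simulate_genome(PopulationSpec("g", 0.4, 20_000), seed=1)
        assert diverge_pair(g, 1.0, seed=2).sequence == g.sequence

    def test_realized_identity_tracks_target(self):
        g = simulate_genome(PopulationSpec("g", 0.4, 100_000), seed=1)
        d = diverge_pair(g, 0.96, seed=2)
        same = np.mean(
            np.frombuffer(g.sequence.encode(), np.uint8)
            == np.frombuffer(d.sequence.encode(), np.uint8)
        )
        sd = np.sqrt(0.96 * 0.04 / 100_000)
        assert abs(same - 0.96) < 3 * sd

    def test_invalid_target_rejected(self):
        g = simulate_genome(PopulationSpec("g", 0.4, 20_000), seed=1)
        with pytest.raises(ValueError):
            diverge_pair(g, 0.0, seed=2)


class TestFragmentAndCover:
    def test_contigs_are_disjoint_substrings(self):
        g = simulate_genome(PopulationSpec("g", 0.5, 200_000), seed=4)
        contigs = fragment_and_cover(g, 10, 3000, 3.0, seed=5)
        assert len(contigs) == 10
        spans = sorted((c.start, c.start + len(c.sequence)) for c in contigs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        for c in contigs:
            assert g.sequence[c.start : c.start + len(c.sequence)] == c.sequence
            assert len(c.sequence) >= 3000
            assert c.coverage > 0

    def test_single_contig_spans_whole_genome(self):
        g = simulate_genome(PopulationSpec("g", 0.5, 20_000), seed=4)
        (c,) = fragment_and_cover(g, 1, 20_000, 2.5, seed=5)
        assert c.sequence == g.sequence

    def test_infeasible_request_raises(self):
        g = simulate_genome(PopulationSpec("g", 0.5, 20_000), seed=4)
        with pytest.raises(ValueError):
            fragment_and_cover(g, 10, 3000, 3.0, seed=5)


@pytest.fixture(scope="module")
def community():
    g1 = simulate_genome(PopulationSpec("a", 0.45, 50_000), seed=21)
    g2 = simulate_genome(PopulationSpec("b", 0.30, 50_000), seed=22)
    return [(g1, 0.8), (g2, 0.2)]


class TestSimulateReads:

    def test_mean_length_near_target(self, community):
        reads, _ = simulate_reads(community, 4000, len_mean=820, len_sd=120, seed=1)
        mean_len = np.mean([len(r.sequence) for r in reads])
        assert abs(mean_len - 820) < 3 * 120 / np.sqrt(4000)

    def test_source_counts_follow_abundances(self, community):
        _, truth = simulate_reads(community, 10_000, seed=2)
        n_a = (truth.source == "a").sum()
        sd = np.sqrt(10_000 * 0.8 * 0.2)
        assert abs(n_a - 8000) < 3 * sd

    def test_error_free_reads_are_exact_substrings(self, community):
        reads, truth = simulate_reads(community, 50, err_rate=0.0, seed=3)
        genomes = {g.name: g.sequence for g, _ in community}
        for read, row in zip(reads, truth.itertuples()):
            seq = read.sequence if row.strand == "+" else revcomp(read.sequence)
            assert genomes[row.source][row.start : row.start + row.length] == seq

    def test_bad_inputs(self, community):
        with pytest.raises(ValueError):
            simulate_reads([], 10, seed=0)
        with pytest.raises(ValueError):
            simulate_reads(community, 10, err_rate=0.5, seed=0)


class TestSimulateSurvey:
    def test_pools_respect_niche_threshold(self):
        from streampop import rrna_identity

        spec = SurveySpec(n_sites=10, niche={"P1": ((75.0, 85.0), (7.5, 8.5))})
        sites, refs, truth = simulate_survey(spec, seed=9)
        occupancy = dict(zip(truth.site_id, truth.occupied))
        for site in sites:
            best = max(rrna_identity(refs["P1"], seq) for _, seq in site.pool)
            if occupancy[site.site_id]:
                assert best > 97.0
            else:
                assert best <= 97.0

    def test_niche_must_sit_inside_survey_ranges(self):
        with pytest.raises(ValueError):
            SurveySpec(n_sites=5, niche={"P1": ((60.0, 85.0), (7.5, 8.5))})
        with pytest.raises(ValueError):
            simulate_survey(SurveySpec(n_sites=5, niche={}), seed=0)


def test_proteome_divergence_plants_identity():
    pa = simulate_proteome(30, seed=1, len_mean=200)
    pb = diverge_proteome(pa, 0.9, seed=2)
    same = [
        np.mean(np.frombuffer(a.encode(), np.uint8) == np.frombuffer(b.encode(), np.uint8))
        for a, b in zip(pa.values(), pb.values())
    ]
    assert abs(np.mean(same) - 0.9) < 0.01
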