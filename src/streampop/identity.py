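"""Pairwise sequence identity metrics: local alignment, AAI, ANI, 16S identity.

The alignment core is optimal local dynamic programming (Smith-Waterman
style, via Biopython's C PairwiseAligner). Above a size cutoff the pair is
first seeded: exact k-mer matches locate the best diagonal band, and the DP
runs only inside a window around it. This mirrors the seed-and-extend
strategy of the BLAST-family tools the metrics are normally computed with.

AAI follows the bidirectional best-hit convention with three retention
filters (>=30% identity, alignment covering >=70% of the subject protein,
>=100 aligned residues). ANI is fragment-based: the query genome is cut
into fixed windows, each is aligned to the subject genome, and retained
fragments (>=70% identity, >=70% of the fragment alignable, alignment >=
a minimum length) are averaged. Fewer retained fragments than the minimum
alignment number yields an undefined result (None), not an error.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "RelatednessResult",
    "nucleotide_scoring",
    "protein_scoring",
    "local_align",
    "SeededAligner",
    "pairwise_aai",
    "pairwise_ani",
    "rrna_identity",
    "aai_pair_retained",
    "ani_fragment_retained",
]

_NT_ALPHABET = frozenset("ACGTNacgtn")


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring. A substitution matrix name overrides match/mismatch."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -2.0
    matrix: str | None = None


def nucleotide_scoring() -> ScoringScheme:
    return ScoringScheme(match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-2.0)


def protein_scoring() -> ScoringScheme:
    return ScoringScheme(gap_open=-11.0, gap_extend=-1.0, matrix="BLOSUM62")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment. Spans are 0-based half-open on the originals."""

    score: float
    columns: int
    matches: int
    identity: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    query_id: str | None = None
    subject_id: str | None = None


@dataclass(frozen=True)
class RelatednessResult:
    """Summary of retained pairwise identities (AAI, ANI, or 16S)."""

    metric: str
    mean: float  # percentage
    sd: float  # percentage
    n: int
    params: dict = field(default_factory=dict)


def _is_protein(seq: str) -> bool:
    return not set(seq) <= _NT_ALPHABET


def _check_alphabets(a: str, b: str) -> bool:
    pa, pb = _is_protein(a), _is_protein(b)
    if pa != pb:
        raise ValueError("alphabet mismatch: one sequence looks nucleotide, the other protein")
    return pa


def _make_aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    if scoring.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _dp_align(
    query: str,
    subject: str,
    aligner: Align.PairwiseAligner,
    subject_offset: int = 0,
    query_id: str | None = None,
    subject_id: str | None = None,
) -> AlignmentHit | None:
    results = aligner.align(query, subject)
    if results.score <= 0:
        return None
    aln = results[0]
    counts = aln.counts()
    q_blocks, s_blocks = aln.aligned
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    s_span = (int(s_blocks[0][0]) + subject_offset, int(s_blocks[-1][1]) + subject_offset)
    columns = int(aln.length)
    matches = int(counts.identities)
    return AlignmentHit(
        score=float(results.score),
        columns=columns,
        matches=matches,
        identity=matches / columns,
        query_span=q_span,
        subject_span=s_span,
        query_id=query_id,
        subject_id=subject_id,
    )


class SeededAligner:
    """Reusable seed-and-extend aligner against one fixed subject sequence.

    Building the exact k-mer index once makes aligning many queries
    (read recruitment, ANI fragments) cheap. K-mers occurring more than
    ``max_positions`` times in the subject are dropped as repeats.
    """

    def __init__(
        self,
        subject: str,
        scoring: ScoringScheme | None = None,
        k: int | None = None,
        margin: int = 100,
        band: int = 32,
        max_positions: int = 50,
        subject_id: str | None = None,
    ):
        self.subject = subject
        self.subject_id = subject_id
        self.is_protein = _is_protein(subject)
        self.scoring = scoring or (protein_scoring() if self.is_protein else nucleotide_scoring())
        self.k = k if k is not None else (5 if self.is_protein else 15)
        self.margin = margin
        self.band = band
        self._aligner = _make_aligner(self.scoring)
        index: dict[str, list[int]] = {}
        for i in range(len(subject) - self.k + 1):
            index.setdefault(subject[i : i + self.k], []).append(i)
        self._index = {w: p for w, p in index.items() if len(p) <= max_positions}

    def align(self, query: str, query_id: str | None = None, query_step: int = 1) -> AlignmentHit | None:
        k = self.k
        if len(query) < k:
            return None
        diagonals: Counter[int] = Counter()
        index = self._index
        for i in range(0, len(query) - k + 1, query_step):
            positions = index.get(query[i : i + k])
            if positions:
                for j in positions:
                    diagonals[j - i] += 1
        if not diagonals:
            return None
        # best band of diagonals (ties -> smallest diagonal, for determinism)
        diags = sorted(diagonals)
        counts = [diagonals[d] for d in diags]
        best_d, best_count = diags[0], -1
        lo = 0
        for hi, d in enumerate(diags):
            while d - diags[lo] > 2 * self.band:
                lo += 1
            c = sum(counts[lo : hi + 1])
            if c > best_count:
                best_count = c
                best_d = (diags[lo] + d) // 2
        # exact-substring shortcut (substitution-free hit, simple scoring only)
        if self.scoring.matrix is None and 0 <= best_d <= len(self.subject) - len(query):
            if self.subject[best_d : best_d + len(query)] == query:
                n = len(query)
                return AlignmentHit(
                    score=n * self.scoring.match,
                    columns=n,
                    matches=n,
                    identity=1.0,
                    query_span=(0, n),
                    subject_span=(best_d, best_d + n),
                    query_id=query_id,
                    subject_id=self.subject_id,
                )
        start = max(0, best_d - self.margin)
        end = min(len(self.subject), best_d + len(query) + self.margin)
        return _dp_align(
            query,
            self.subject[start:end],
            self._aligner,
            subject_offset=start,
            query_id=query_id,
            subject_id=self.subject_id,
        )


def local_align(
    a: str,
    b: str,
    scoring: ScoringScheme | None = None,
    exact_cells: int = 4_000_000,
    seed_k: int | None = None,
    margin: int = 100,
) -> AlignmentHit | None:
    """Optimal local alignment of ``a`` (query) against ``b`` (subject).

    Exact DP when ``len(a) * len(b) <= exact_cells``; otherwise k-mer
    seeded with exact DP extension inside the best diagonal window.
    Returns None when no positive-scoring alignment (or no seed) exists.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    is_protein = _check_alphabets(a, b)
    if scoring is None:
        scoring = protein_scoring() if is_protein else nucleotide_scoring()
    if len(a) * len(b) <= exact_cells:
        return _dp_align(a, b, _make_aligner(scoring))
    return SeededAligner(b, scoring=scoring, k=seed_k, margin=margin).align(a)


# ---------------------------------------------------------------------------
# AAI

def aai_pair_retained(
    hit: AlignmentHit,
    subject_length: int,
    min_identity: float = 0.30,
    min_subject_cov: float = 0.70,
    min_columns: int = 100,
) -> bool:
    """Retention filter for one best-hit protein pair."""
    subject_cov = (hit.subject_span[1] - hit.subject_span[0]) / subject_length
    return (
        hit.identity >= min_identity
        and subject_cov >= min_subject_cov
        and hit.columns >= min_columns
    )


def _as_protein_dict(proteome) -> dict[str, str]:
    if isinstance(proteome, Mapping):
        return dict(proteome)
    out = {}
    for item in proteome:
        if hasattr(item, "id") and hasattr(item, "seq"):
            out[str(item.id)] = str(item.seq)
        else:
            name, seq = item
            out[str(name)] = str(seq)
    return out


def _kmer_set(seq: str, k: int) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def pairwise_aai(
    proteome_a,
    proteome_b,
    min_identity: float = 0.30,
    min_subject_cov: float = 0.70,
    min_columns: int = 100,
    scoring: ScoringScheme | None = None,
    prescreen_k: int = 4,
    n_candidates: int = 5,
) -> RelatednessResult | None:
    """Average amino-acid identity over filtered bidirectional best hits.

    Candidate subjects are shortlisted by shared k-mer counts (a word-hit
    prescreen in the spirit of BLAST) before optimal local alignment.
    Best hits are by alignment score, ties broken by lexicographic subject
    id. Returns None when no pair survives the filters.
    """
    pa = _as_protein_dict(proteome_a)
    pb = _as_protein_dict(proteome_b)
    if not pa or not pb:
        raise ValueError("both proteomes must be non-empty")
    scoring = scoring or protein_scoring()
    aligner = _make_aligner(scoring)
    kmers_a = {name: _kmer_set(s, prescreen_k) for name, s in pa.items()}
    kmers_b = {name: _kmer_set(s, prescreen_k) for name, s in pb.items()}

    cache: dict[tuple[str, str], AlignmentHit | None] = {}

    def hit_for(a_id: str, b_id: str) -> AlignmentHit | None:
        key = (a_id, b_id)
        if key not in cache:
            cache[key] = _dp_align(pa[a_id], pb[b_id], aligner, query_id=a_id, subject_id=b_id)
        return cache[key]

    def best_hit(q_id, q_kmers, others_kmers, forward: bool) -> str | None:
        shared = [(len(q_kmers & kk), name) for name, kk in others_kmers.items()]
        shared = [t for t in shared if t[0] > 0]
        shared.sort(key=lambda t: (-t[0], t[1]))
        best_id, best_score = None, 0.0
        for _, cand in shared[:n_candidates]:
            h = hit_for(q_id, cand) if forward else hit_for(cand, q_id)
            if h is None:
                continue
            if h.score > best_score or (h.score == best_score and (best_id is None or cand < best_id)):
                best_id, best_score = cand, h.score
        return best_id

    best_a = {a_id: best_hit(a_id, ka, kmers_b, True) for a_id, ka in kmers_a.items()}
    best_b = {b_id: best_hit(b_id, kb, kmers_a, False) for b_id, kb in kmers_b.items()}

    identities = []
    for a_id, b_id in sorted(best_a.items()):
        if b_id is None or best_b.get(b_id) != a_id:
            continue
        hit = hit_for(a_id, b_id)
        if hit is None:
            continue
        if aai_pair_retained(hit, len(pb[b_id]), min_identity, min_subject_cov, min_columns):
            identities.append(hit.identity)
    if not identities:
        return None
    arr = 100.0 * np.asarray(identities)
    return RelatednessResult(
        metric="AAI",
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        n=len(arr),
        params={
            "min_identity": min_identity,
            "min_subject_cov": min_subject_cov,
            "min_columns": min_columns,
        },
    )


# ---------------------------------------------------------------------------
# ANI

def ani_fragment_retained(
    hit: AlignmentHit,
    fragment_length: int,
    min_aligned_length: int = 700,
    min_identity: float = 0.70,
    min_fragment_cov: float = 0.70,
) -> bool:
    """Retention filter for one genome fragment alignment."""
    frag_cov = (hit.query_span[1] - hit.query_span[0]) / fragment_length
    return (
        hit.columns >= min_aligned_length
        and hit.identity >= min_identity
        and frag_cov >= min_fragment_cov
    )


def _as_sequence(genome) -> str:
    if hasattr(genome, "sequence"):
        return genome.sequence
    if hasattr(genome, "seq"):
        return str(genome.seq)
    return str(genome)


def pairwise_ani(
    genome_a,
    genome_b,
    window: int = 1000,
    step: int = 200,
    min_aligned_length: int = 700,
    min_identity: float = 0.70,
    min_fragment_cov: float = 0.70,
    min_alignments: int = 50,
    seed_k: int = 15,
    margin: int = 100,
) -> RelatednessResult | None:
    """Fragment-based average nucleotide identity of genome_a against genome_b.

    genome_a is cut into ``window``-length fragments every ``step`` bases;
    each fragment is seed-aligned to genome_b; retained fragment identities
    are averaged. Returns None (undefined) when fewer than
    ``min_alignments`` fragments are retained.
    """
    a = _as_sequence(genome_a)
    b = _as_sequence(genome_b)
    if not a or not b:
        raise ValueError("both genomes must be non-empty")
    aligner = SeededAligner(b, k=seed_k, margin=margin)
    identities = []
    for start in range(0, len(a) - window + 1, step):
        frag = a[start : start + window]
        hit = aligner.align(frag)
        if hit is not None and ani_fragment_retained(
            hit, len(frag), min_aligned_length, min_identity, min_fragment_cov
        ):
            identities.append(hit.identity)
    if len(identities) < min_alignments:
        return None
    arr = 100.0 * np.asarray(identities)
    return RelatednessResult(
        metric="ANI",
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        n=len(arr),
        params={
            "window": window,
            "step": step,
            "min_aligned_length": min_aligned_length,
            "min_identity": min_identity,
            "min_fragment_cov": min_fragment_cov,
            "min_alignments": min_alignments,
        },
    )


# ---------------------------------------------------------------------------
# 16S identity

def rrna_identity(a, b) -> float:
    """Percent identity of the best local alignment of two 16S rRNA genes."""
    sa, sb = _as_sequence(a), _as_sequence(b)
    if min(len(sa), len(sb)) < 200:
        warnings.warn("16S sequence shorter than 200 bases; identity may be unreliable")
    hit = local_align(sa, sb, scoring=nucleotide_scoring())
    if hit is None:
        return 0.0
    return 100.0 * hit.matches / hit.columns
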