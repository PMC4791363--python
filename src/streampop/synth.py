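"""Synthetic communities with the statistical structure of hot-spring
streamer metagenomes.

The generator emulates the study conditions every downstream stage
assumes: a handful of populations with distinct G+C content (roughly
0.29-0.60) and k-mer composition, contigs longer than 3 kbp at ~2-3.5x
coverage, Sanger-like shotgun reads averaging 820 bp, conspecific genome
pairs at a planted nucleotide identity (~0.96 for a same-species pair),
marker-gene complements with controlled missingness, COG repertoires, and
site surveys whose thermophile niches span ~70-90 degrees C and pH ~7-9.

Genomes are i.i.d. base draws with a per-position G+C probability, with an
optional chunkwise rejection-sampling layer that tilts word frequencies
toward a supplied canonical k-mer weighting. Read errors are substitutions
only, which keeps planted identities analytic. Every generator is
deterministic given its seed; truth tables accompany every output so each
downstream stage has an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, canonical_kmer_table, kmer_class_counts, revcomp, seq_to_codes, codes_to_seq
from .survey import SiteRecord

__all__ = [
    "PopulationSpec",
    "SyntheticGenome",
    "SurveySpec",
    "Contig",
    "Read",
    "simulate_genome",
    "diverge_pair",
    "fragment_and_cover",
    "simulate_reads",
    "simulate_survey",
    "simulate_proteome",
    "diverge_proteome",
    "make_annotations",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PopulationSpec:
    """Blueprint for one synthetic population genome."""

    name: str
    gc_target: float
    genome_length: int
    abundance: float = 1.0
    kmer_bias: Mapping[str, float] | None = None  # canonical k-mer -> relative weight
    marker_presence: Mapping[str, float] = field(default_factory=dict)  # catalog -> fraction kept
    cog_set: frozenset = frozenset()

    def __post_init__(self):
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError(f"gc_target must be in (0, 1), got {self.gc_target}")
        for cat, frac in self.marker_presence.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"marker_presence[{cat!r}] must be in [0, 1]")


@dataclass
class SyntheticGenome:
    name: str
    sequence: str
    truth_markers: frozenset = frozenset()
    truth_cogs: frozenset = frozenset()

    @property
    def gc(self) -> float:
        codes = seq_to_codes(self.sequence)
        return float(np.mean((codes == 1) | (codes == 2)))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SurveySpec:
    """Design of a synthetic site survey.

    ``niche`` maps each phylotype to its ((t_lo, t_hi), (ph_lo, ph_hi))
    occurrence window; within-niche sites carry a 16S variant at
    ``inside_identity`` to the phylotype reference, outside sites carry
    only a distant variant at ``outside_identity``.
    """

    n_sites: int
    temp_range: tuple[float, float] = (70.0, 90.0)
    ph_range: tuple[float, float] = (7.0, 9.0)
    niche: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = field(default_factory=dict)
    inside_identity: float = 0.99
    outside_identity: float = 0.90
    gene_length: int = 1400

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name, (tw, pw) in self.niche.items():
            if not (self.temp_range[0] <= tw[0] <= tw[1] <= self.temp_range[1]):
                raise ValueError(f"temperature niche of {name!r} outside the survey range")
            if not (self.ph_range[0] <= pw[0] <= pw[1] <= self.ph_range[1]):
                raise ValueError(f"pH niche of {name!r} outside the survey range")


@dataclass
class Contig:
    contig_id: str
    sequence: str
    coverage: float
    source_genome: str | None = None
    start: int | None = None  # offset in the source genome

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Read:
    read_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.int8)


def simulate_genome(
    spec: PopulationSpec,
    seed: int,
    catalogs: Mapping[str, Iterable[str]] | None = None,
    chunk: int = 100,
    attempts: int = 5,
) -> SyntheticGenome:
    """Draw a genome matching the spec's G+C target and k-mer bias.

    With a ``kmer_bias``, candidate chunks are rejection-sampled: a chunk
    is accepted with probability proportional to the mean bias weight of
    its canonical k-mers (best of ``attempts`` kept otherwise). Bias
    weights that are not G+C-balanced will pull the realized G+C away
    from ``gc_target``.

    ``catalogs`` (catalog name -> marker labels) lets the genome carry a
    marker truth set sampled at the spec's per-catalog retention fraction.
    """
    if spec.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10^4")
    rng = np.random.default_rng(seed)
    length = spec.genome_length
    if not spec.kmer_bias:
        codes = _draw_bases(rng, length, spec.gc_target)
    else:
        k = len(next(iter(spec.kmer_bias)))
        if any(len(w) != k for w in spec.kmer_bias):
            raise ValueError("all kmer_bias keys must have equal length")
        class_index, kmers = canonical_kmer_table(k)
        weights = np.ones(len(kmers))
        pos = {w: i for i, w in enumerate(kmers)}
        for word, w in spec.kmer_bias.items():
            canon = min(word, revcomp(word))
            weights[pos[canon]] = w
        w_max = max(weights.max(), 1.0)
        pieces = []
        produced = 0
        while produced < length:
            size = min(chunk, length - produced)
            best_chunk, best_w = None, -1.0
            accepted = None
            for _ in range(attempts):
                cand = _draw_bases(rng, size, spec.gc_target)
                if size >= k:
                    counts = kmer_class_counts(codes_to_seq(cand), k)
                    w_mean = float(counts @ weights) / max(counts.sum(), 1)
                else:
                    w_mean = 1.0
                if w_mean > best_w:
                    best_chunk, best_w = cand, w_mean
                if rng.random() < w_mean / w_max:
                    accepted = cand
                    break
            pieces.append(accepted if accepted is not None else best_chunk)
            produced += size
        codes = np.concatenate(pieces)
    markers: set[str] = set()
    if catalogs:
        for cat_name, cat_markers in sorted(catalogs.items()):
            frac = spec.marker_presence.get(cat_name, 1.0)
            labels = sorted(cat_markers)
            # a uniformly random subset of exactly round(frac * n) markers,
            # so the planted completeness equals the requested fraction
            n_keep = int(round(frac * len(labels)))
            keep = rng.choice(len(labels), size=n_keep, replace=False)
            markers.update(labels[i] for i in keep)
    return SyntheticGenome(
        name=spec.name,
        sequence=codes_to_seq(codes),
        truth_markers=frozenset(markers),
        truth_cogs=frozenset(spec.cog_set),
    )


def diverge_pair(genome: SyntheticGenome, target_identity: float, seed: int, name: str | None = None) -> SyntheticGenome:
    """A copy of ``genome`` with i.i.d. substitutions at rate 1 - identity.

    Substituted positions change to one of the three other bases uniformly,
    so the realized global identity is binomial around the target.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError(f"target_identity must be in (0, 1], got {target_identity}")
    rng = np.random.default_rng(seed)
    codes = seq_to_codes(genome.sequence).copy()
    sub = rng.random(len(codes)) < (1.0 - target_identity)
    n_sub = int(sub.sum())
    if n_sub:
        codes[sub] = (codes[sub] + rng.integers(1, 4, size=n_sub)) % 4
    return SyntheticGenome(
        name=name or f"{genome.name}_div{target_identity:g}",
        sequence=codes_to_seq(codes.astype(np.int8)),
        truth_markers=genome.truth_markers,
        truth_cogs=genome.truth_cogs,
    )


def fragment_and_cover(
    genome: SyntheticGenome,
    n_contigs: int,
    min_len: int,
    cov_mean: float,
    seed: int,
    cov_sd: float | None = None,
    length_spread: float = 0.8,
) -> list[Contig]:
    """Cut non-overlapping contigs out of the genome with coverage values.

    The genome is split into ``n_contigs`` equal blocks and one contig is
    drawn inside each, so contigs are disjoint by construction. Coverage
    is drawn from a normal around ``cov_mean`` (sd defaults to 15% of the
    mean — the dispersion is a free parameter of the generator).
    """
    if n_contigs < 1 or min_len < 1:
        raise ValueError("n_contigs and min_len must be >= 1")
    length = len(genome.sequence)
    block = length // n_contigs
    if n_contigs * min_len > length or min_len > block:
        raise ValueError(
            f"cannot place {n_contigs} contigs of >= {min_len} bp in a {length} bp genome"
        )
    rng = np.random.default_rng(seed)
    sd = cov_sd if cov_sd is not None else 0.15 * cov_mean
    contigs = []
    for i in range(n_contigs):
        lo = i * block
        extra = int((block - min_len) * length_spread)
        clen = min_len + int(rng.integers(0, extra + 1))
        start = lo + int(rng.integers(0, block - clen + 1))
        cov = max(float(rng.normal(cov_mean, sd)), 0.05)
        contigs.append(
            Contig(
                contig_id=f"{genome.name}_c{i:04d}",
                sequence=genome.sequence[start : start + clen],
                coverage=cov,
                source_genome=genome.name,
                start=start,
            )
        )
    return contigs


def simulate_reads(
    community: Sequence[tuple[SyntheticGenome, float]],
    n_reads: int,
    len_mean: float = 820.0,
    len_sd: float = 120.0,
    err_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[Read], pd.DataFrame]:
    """Sanger-like shotgun reads from a community.

    Reads are drawn from genomes with probability proportional to
    abundance x genome length, from a uniform start on a uniform strand,
    with normal lengths and substitution-only errors. Returns the reads
    and a truth table (read_id, source, start, length, strand).
    """
    if not community:
        raise ValueError("community must be non-empty")
    if not 0.0 <= err_rate <= 0.3:
        raise ValueError("err_rate must be in [0, 0.3]")
    abundances = np.array([a for _, a in community], dtype=float)
    if abs(abundances.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(g.sequence) for g, _ in community], dtype=float)
    p = abundances * lengths
    p /= p.sum()
    sources = rng.choice(len(community), size=n_reads, p=p)
    read_lens = np.maximum(np.round(rng.normal(len_mean, len_sd, size=n_reads)), 50).astype(int)
    strands = rng.random(n_reads) < 0.5
    reads = []
    truth = []
    for i in range(n_reads):
        genome, _ = community[sources[i]]
        glen = len(genome.sequence)
        rlen = min(read_lens[i], glen)
        start = int(rng.integers(0, glen - rlen + 1))
        seq = genome.sequence[start : start + rlen]
        if strands[i]:
            seq = revcomp(seq)
        if err_rate > 0:
            codes = seq_to_codes(seq).copy()
            sub = rng.random(rlen) < err_rate
            n_sub = int(sub.sum())
            if n_sub:
                codes[sub] = (codes[sub] + rng.integers(1, 4, size=n_sub)) % 4
            seq = codes_to_seq(codes.astype(np.int8))
        read_id = f"read{i:06d}"
        reads.append(Read(read_id, seq))
        truth.append((read_id, genome.name, start, rlen, "-" if strands[i] else "+"))
    truth_df = pd.DataFrame(truth, columns=["read_id", "source", "start", "length", "strand"])
    return reads, truth_df


def _mutate(seq: str, identity: float, rng: np.random.Generator) -> str:
    codes = seq_to_codes(seq).copy()
    sub = rng.random(len(codes)) < (1.0 - identity)
    n_sub = int(sub.sum())
    if n_sub:
        codes[sub] = (codes[sub] + rng.integers(1, 4, size=n_sub)) % 4
    return codes_to_seq(codes.astype(np.int8))


def simulate_survey(
    spec: SurveySpec, seed: int
) -> tuple[list[SiteRecord], dict[str, str], pd.DataFrame]:
    """Synthesize a site survey with planted occurrence niches.

    Each phylotype gets a random 16S reference gene. Sites inside a
    phylotype's (temperature, pH) niche receive a pool variant at
    ``inside_identity`` to that reference; sites outside receive only a
    distant variant at ``outside_identity``. Returns (sites, references,
    truth) where truth records the planted occupancy per site/phylotype.
    """
    if not spec.niche:
        raise ValueError("survey needs at least one phylotype niche")
    rng = np.random.default_rng(seed)
    references = {
        name: codes_to_seq(_draw_bases(rng, spec.gene_length, 0.55))
        for name in sorted(spec.niche)
    }
    sites = []
    truth_rows = []
    for s in range(spec.n_sites):
        site_id = f"site{s:03d}"
        temp = float(rng.uniform(*spec.temp_range))
        ph = float(rng.uniform(*spec.ph_range))
        pool = []
        for name in sorted(spec.niche):
            (t_lo, t_hi), (p_lo, p_hi) = spec.niche[name]
            inside = t_lo <= temp <= t_hi and p_lo <= ph <= p_hi
            ident = spec.inside_identity if inside else spec.outside_identity
            pool.append((f"{site_id}_{name}", _mutate(references[name], ident, rng)))
            truth_rows.append((site_id, name, inside, temp, ph))
        sites.append(SiteRecord(site_id, temp, ph, pool))
    truth = pd.DataFrame(truth_rows, columns=["site_id", "phylotype", "occupied", "temperature", "ph"])
    return sites, references, truth


# ---------------------------------------------------------------------------
# Protein-level helpers for relatedness scenarios

def simulate_proteome(
    n_proteins: int, seed: int, len_mean: int = 300, len_sd: int = 60, name: str = "prot"
) -> dict[str, str]:
    """Random proteome: uniform residues, normal lengths (>= 60 aa)."""
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(_AA.encode(), dtype=np.uint8)
    out = {}
    for i in range(n_proteins):
        n = max(int(rng.normal(len_mean, len_sd)), 60)
        out[f"{name}{i:04d}"] = aa[rng.integers(0, len(_AA), size=n)].tobytes().decode()
    return out


def diverge_proteome(proteome: Mapping[str, str], identity: float, seed: int) -> dict[str, str]:
    """Substitute residues i.i.d. at rate 1 - identity (uniform over the other 19)."""
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    out = {}
    for pid, seq in proteome.items():
        chars = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        sub = rng.random(len(chars)) < (1.0 - identity)
        idx = np.flatnonzero(sub)
        for i in idx:
            choices = [c for c in _AA if ord(c) != chars[i]]
            chars[i] = ord(choices[int(rng.integers(0, len(choices)))])
        out[pid] = chars.tobytes().decode()
    return out


def make_annotations(
    genome: SyntheticGenome,
    n_plain_cds: int = 50,
    partial_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Annotation table for a synthetic genome, from its truth sets.

    One CDS row per truth marker (a random subset flagged partial — a
    partial gene still evidences its marker), ``n_plain_cds`` unlabeled
    CDS rows, and one CDS row per truth COG. Columns: gene_id, type,
    marker, partial, cog.
    """
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for marker in sorted(genome.truth_markers):
        rows.append((f"{genome.name}_g{i:05d}", "CDS", marker, bool(rng.random() < partial_fraction), None))
        i += 1
    for cog in sorted(genome.truth_cogs):
        rows.append((f"{genome.name}_g{i:05d}", "CDS", None, False, cog))
        i += 1
    for _ in range(n_plain_cds):
        rows.append((f"{genome.name}_g{i:05d}", "CDS", None, False, None))
        i += 1
    return pd.DataFrame(rows, columns=["gene_id", "type", "marker", "partial", "cog"])
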