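"""Read recruitment against bin references at a nucleotide-identity threshold.

Each read is seed-aligned (both orientations) against every bin's
reference sequences; the best-scoring hit assigns the read when its
identity is strictly above the threshold (default >90%) and at least half
of the read aligns. Ties between bins, sub-threshold identities and
unaligned reads all fall into the ORPHAN category, mirroring the
conservative "Unassigned" semantics of abundance tables built this way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .binning import gc_content
from .identity import SeededAligner, AlignmentHit

__all__ = ["ORPHAN", "ReadAssignment", "recruit_reads", "abundance_table", "gc_histogram"]

ORPHAN = "ORPHAN"


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    bin: str
    identity: float | None  # fraction; None when nothing aligned
    aligned_len: int


def _as_read_pairs(reads) -> list[tuple[str, str]]:
    out = []
    for r in reads:
        if hasattr(r, "read_id"):
            out.append((r.read_id, r.sequence))
        elif hasattr(r, "id") and hasattr(r, "seq"):
            out.append((str(r.id), str(r.seq)))
        else:
            out.append((str(r[0]), str(r[1])))
    return out


def recruit_reads(
    reads,
    references: Mapping[str, Sequence],
    min_identity: float = 0.90,
    min_read_cov: float = 0.50,
    seed_k: int = 15,
    query_step: int = 7,
) -> list[ReadAssignment]:
    """Assign reads to bins by best seeded local alignment.

    ``references`` maps bin label -> reference sequence(s) (strings,
    Contigs, or SeqRecords). Assignment requires identity strictly
    greater than ``min_identity`` and an aligned fraction of the read of
    at least ``min_read_cov``; equal best scores in two bins orphan the
    read. An empty read set returns an empty list.
    """
    if not references:
        raise ValueError("references must be non-empty")
    aligners: dict[str, list[SeededAligner]] = {}
    for bin_label, refs in references.items():
        if isinstance(refs, str) or hasattr(refs, "sequence") or hasattr(refs, "seq"):
            refs = [refs]
        seqs = []
        for ref in refs:
            if hasattr(ref, "sequence"):
                seqs.append(ref.sequence)
            elif hasattr(ref, "seq"):
                seqs.append(str(ref.seq))
            else:
                seqs.append(str(ref))
        aligners[bin_label] = [SeededAligner(s, k=seed_k) for s in seqs]

    assignments = []
    for read_id, seq in _as_read_pairs(reads):
        rc = revcomp(seq)
        per_bin: dict[str, AlignmentHit] = {}
        for bin_label, bin_aligners in aligners.items():
            best = None
            for aligner in bin_aligners:
                for query in (seq, rc):
                    hit = aligner.align(query, query_step=query_step)
                    if hit is not None and (best is None or hit.score > best.score):
                        best = hit
            if best is not None:
                per_bin[bin_label] = best
        if not per_bin:
            assignments.append(ReadAssignment(read_id, ORPHAN, None, 0))
            continue
        best_score = max(h.score for h in per_bin.values())
        top = sorted(b for b, h in per_bin.items() if h.score == best_score)
        hit = per_bin[top[0]]
        aligned_frac = (hit.query_span[1] - hit.query_span[0]) / len(seq)
        if len(top) > 1 or hit.identity <= min_identity or aligned_frac < min_read_cov:
            assignments.append(ReadAssignment(read_id, ORPHAN, hit.identity, hit.columns))
        else:
            assignments.append(ReadAssignment(read_id, top[0], hit.identity, hit.columns))
    return assignments


def abundance_table(assignments: Sequence[ReadAssignment]) -> pd.Series:
    """Percentage of reads per bin (ORPHAN row included); sums to 100."""
    if not assignments:
        raise ValueError("cannot tabulate abundances for zero reads")
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.bin] = counts.get(a.bin, 0) + 1
    counts.setdefault(ORPHAN, 0)
    total = sum(counts.values())
    labels = sorted(b for b in counts if b != ORPHAN) + [ORPHAN]
    return pd.Series({b: 100.0 * counts[b] / total for b in labels}, name="percent")


def gc_histogram(
    reads,
    assignments: Sequence[ReadAssignment],
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Per-bin histograms of read G+C content (%), plus an ALL series.

    Rows are G+C bins (left edge, percent); each column's counts sum to
    the number of reads assigned to that bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    pairs = _as_read_pairs(reads)
    by_read = {a.read_id: a.bin for a in assignments}
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    labels = sorted({a.bin for a in assignments}) if assignments else []
    gc_values: dict[str, list[float]] = {b: [] for b in labels}
    all_values = []
    for read_id, seq in pairs:
        gc = 100.0 * gc_content(seq)
        all_values.append(gc)
        b = by_read.get(read_id)
        if b is not None:
            gc_values[b].append(gc)
    data = {b: np.histogram(v, bins=edges)[0] for b, v in gc_values.items()}
    data["ALL"] = np.histogram(all_values, bins=edges)[0]
    return pd.DataFrame(data, index=edges[:-1])
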