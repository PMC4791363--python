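"""Composition-based contig binning: word-frequency PCA plus G+C/coverage.

Contigs longer than a minimum (default 3 kbp) are summarized by canonical
k-mer (default tetranucleotide) frequency vectors, projected with PCA, and
clustered in a feature space that concatenates the standardized principal
coordinates with G+C content and log coverage. Contigs far from every
cluster centre are left unassigned (ORPHAN) — a seeded, reproducible
stand-in for the manual curation these plots traditionally receive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from ._seq import kmer_class_counts, canonical_kmer_table, seq_to_codes

__all__ = [
    "ORPHAN",
    "WordFrequencyVector",
    "PcaResult",
    "gc_content",
    "word_frequency",
    "word_frequency_matrix",
    "project_pca",
    "assign_bins",
    "bin_contigs",
]

ORPHAN = "ORPHAN"


class InsufficientDataError(ValueError):
    """Fewer contigs survive filtering than the analysis needs."""


@dataclass
class WordFrequencyVector:
    contig_id: str | None
    k: int
    freqs: pd.Series  # indexed by canonical k-mer, sums to 1
    n_windows: int
    seq_length: int


@dataclass
class PcaResult:
    coords: pd.DataFrame  # contig_id x PC1..PCn
    explained_variance_ratio: np.ndarray


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); ambiguous bases are excluded from both counts."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    codes = seq_to_codes(seq)
    unambiguous = codes >= 0
    total = int(unambiguous.sum())
    if total == 0:
        raise ValueError("sequence has no unambiguous bases; G+C undefined")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / total


def word_frequency(seq: str, k: int = 4, contig_id: str | None = None) -> WordFrequencyVector:
    """Canonical k-mer frequency vector of one sequence.

    Sliding windows of width k, step 1; each window pooled with its
    reverse complement; windows containing ambiguous bases skipped;
    counts normalized by the number of retained windows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    counts = kmer_class_counts(seq, k)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("no unambiguous windows of width k")
    _, kmers = canonical_kmer_table(k)
    return WordFrequencyVector(
        contig_id=contig_id,
        k=k,
        freqs=pd.Series(counts / n, index=list(kmers)),
        n_windows=n,
        seq_length=len(seq),
    )


def word_frequency_matrix(contigs: Sequence, k: int = 4) -> pd.DataFrame:
    """Stack per-contig word-frequency vectors into a DataFrame."""
    rows = {c.contig_id: word_frequency(c.sequence, k).freqs for c in contigs}
    return pd.DataFrame(rows).T


def project_pca(
    vectors: Sequence[WordFrequencyVector],
    min_len: int = 3000,
    n_components: int = 3,
) -> PcaResult:
    """PCA of word-frequency vectors for contigs strictly longer than min_len.

    Columns are mean-centered; components come out ordered by decreasing
    explained variance.
    """
    kept = [v for v in vectors if v.seq_length > min_len]
    if len(kept) < 2:
        raise InsufficientDataError(
            f"only {len(kept)} contigs longer than {min_len} bp; need at least 2"
        )
    X = np.vstack([v.freqs.to_numpy() for v in kept])
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    index = [v.contig_id for v in kept]
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcaResult(
        coords=pd.DataFrame(coords, index=index, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def assign_bins(
    coords: pd.DataFrame,
    gc: pd.Series,
    coverage: pd.Series,
    n_bins: int,
    seed: int = 0,
    orphan_quantile: float = 0.975,
    orphan_slack: float = 1.5,
) -> pd.DataFrame:
    """Cluster contigs into bins in (standardized PCs + G+C + log coverage).

    Seeded k-means; a contig farther than ``orphan_slack`` times the
    ``orphan_quantile`` quantile of within-cluster distances from every
    cluster centre becomes ORPHAN. The slack keeps the tail of a clean,
    single cluster assigned while still expelling genuine outliers.
    Returns a DataFrame (contig_id, bin, gc, coverage, PC columns).
    """
    index = coords.index
    if n_bins > len(index):
        raise ValueError(f"requested {n_bins} bins for {len(index)} contigs")
    gc = gc.loc[index]
    coverage = coverage.loc[index]
    feats = np.column_stack(
        [coords.to_numpy(), gc.to_numpy(), np.log10(coverage.to_numpy())]
    )
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / std
    km = KMeans(n_clusters=n_bins, n_init=10, random_state=seed)
    labels = km.fit_predict(feats)
    centre_dists = np.linalg.norm(feats[:, None, :] - km.cluster_centers_[None, :, :], axis=2)
    own = centre_dists[np.arange(len(labels)), labels]
    cutoff = orphan_slack * np.quantile(own, orphan_quantile)
    orphan = centre_dists.min(axis=1) > cutoff
    bins = np.array([f"bin{l:02d}" for l in labels], dtype=object)
    bins[orphan] = ORPHAN
    out = pd.DataFrame({"bin": bins, "gc": gc, "coverage": coverage}, index=index)
    return pd.concat([out, coords], axis=1)


def bin_contigs(
    contigs: Sequence,
    n_bins: int,
    k: int = 4,
    min_len: int = 3000,
    n_components: int = 3,
    seed: int = 0,
    orphan_quantile: float = 0.975,
    orphan_slack: float = 1.5,
) -> pd.DataFrame:
    """End-to-end composition binning of a contig set."""
    vectors = [word_frequency(c.sequence, k, contig_id=c.contig_id) for c in contigs]
    pca = project_pca(vectors, min_len=min_len, n_components=n_components)
    kept = pca.coords.index
    by_id = {c.contig_id: c for c in contigs}
    gc = pd.Series({cid: gc_content(by_id[cid].sequence) for cid in kept})
    cov = pd.Series({cid: by_id[cid].coverage for cid in kept})
    return assign_bins(
        pca.coords, gc, cov, n_bins, seed=seed,
        orphan_quantile=orphan_quantile, orphan_slack=orphan_slack,
    )
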