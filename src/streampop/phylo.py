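"""Marker-gene phylogeny utilities: reference curation, weighted
concatenation, corrected distances, neighbor joining, bootstrap support,
and conserved-signature-indel (CSI) scanning.

The 18-gene marker set (5 universal: pheT, rplE, rplO, rpsK, rpsM; 13
bacterial-specific: clpX, leuS, ligA, murD, pnp, pth, pyrG, rplL, rpoA,
rpoB, rpoC, secY, serS) is curated so that every retained reference
genome carries at least 16 of the 18 genes, with a whitelist for
deliberately kept incomplete genomes. Tree estimation here is a
distance-based stand-in for full ML inference: per-gene alignments are
concatenated with per-column confidence weights, pairwise weighted
p-distances are corrected for multiple hits (Poisson over s states:
d = -((s-1)/s) ln(1 - s p / (s-1)); s = 20 for proteins, 4 gives the
Jukes-Cantor form for nucleotides), and trees come from deterministic
neighbor joining with lexicographic tie-breaking. Support values resample
columns with replacement within each gene partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MARKER_GENES_18",
    "GenePartition",
    "ConcatAlignment",
    "CsiSignature",
    "Node",
    "BootstrapResult",
    "curate_references",
    "column_weights",
    "concatenate_partitions",
    "distance_matrix",
    "nj_tree",
    "tree_bipartitions",
    "bootstrap_support",
    "csi_scan",
]

MARKER_GENES_18 = (
    "clpX", "leuS", "ligA", "murD", "pheT", "pnp", "pth", "pyrG",
    "rplE", "rplL", "rplO", "rpoA", "rpoB", "rpoC", "rpsK", "rpsM",
    "secY", "serS",
)

GAP = "-"


@dataclass(frozen=True)
class GenePartition:
    gene: str
    start: int  # 0-based half-open column span in the concatenation
    stop: int
    weights: np.ndarray  # per-column, in [0, 1]


@dataclass
class ConcatAlignment:
    taxa: list
    matrix: np.ndarray  # (n_taxa, n_columns) of single characters, 'S1'
    partitions: list[GenePartition]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def weights(self) -> np.ndarray:
        w = np.ones(self.n_columns)
        for p in self.partitions:
            w[p.start : p.stop] = p.weights
        return w

    @property
    def informative_positions(self) -> int:
        """Columns with at least two distinct non-gap states."""
        count = 0
        gap = GAP.encode()
        for j in range(self.n_columns):
            col = self.matrix[:, j]
            states = set(col[col != gap].tolist())
            if len(states) >= 2:
                count += 1
        return count

    def row(self, taxon) -> str:
        i = self.taxa.index(taxon)
        return self.matrix[i].tobytes().decode("ascii")


@dataclass(frozen=True)
class CsiSignature:
    """A conserved signature indel: two flanking motifs around a variable span."""

    gene: str
    left_flank: str
    right_flank: str
    reference_span: int = 0  # residues between the flanks in the reference
    expected_range: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.left_flank or not self.right_flank:
            raise ValueError("flank motifs must be non-empty")


def curate_references(
    marker_tables: Mapping[str, Sequence[str]],
    min_genes: int = 16,
    total: int = 18,
    whitelist: Sequence[str] = (),
) -> list[str]:
    """Retain genomes carrying >= min_genes of the marker set (or whitelisted).

    ``marker_tables`` maps genome -> the marker genes found in it.
    """
    if total < min_genes:
        raise ValueError("total must be >= min_genes")
    whitelist = set(whitelist)
    retained = []
    for genome in sorted(marker_tables):
        n = len(set(marker_tables[genome]))
        if n >= min_genes or genome in whitelist:
            retained.append(genome)
    return retained


def _rows_to_matrix(rows: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(rows).encode("ascii"), dtype="S1").reshape(len(rows), -1)


def column_weights(alignment: Mapping[str, str] | Sequence[str]) -> np.ndarray:
    """Per-column confidence weights in [0, 1] for one gene alignment.

    weight = (fraction of non-gap rows) x (frequency of the modal residue
    among non-gap rows): gappy or ambiguously aligned columns are
    down-weighted, as an internal stand-in for external alignment-
    confidence tools.
    """
    rows = list(alignment.values()) if isinstance(alignment, Mapping) else list(alignment)
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows must have equal length")
    mat = _rows_to_matrix(rows)
    n, width = mat.shape
    gap = GAP.encode()
    weights = np.empty(width)
    for j in range(width):
        col = mat[:, j]
        nongap = col[col != gap]
        if len(nongap) == 0:
            weights[j] = 0.0
            continue
        _, counts = np.unique(nongap, return_counts=True)
        weights[j] = (len(nongap) / n) * (counts.max() / len(nongap))
    return weights


def concatenate_partitions(
    per_gene_alignments: Mapping[str, Mapping[str, str]],
    weights: Mapping[str, np.ndarray] | None = None,
) -> ConcatAlignment:
    """Concatenate per-gene alignments over the union of taxa.

    Genes are laid out in lexicographic order; a taxon missing from a
    gene is filled with gaps across that partition. ``weights`` maps
    gene -> per-column weights (defaults to 1 everywhere).
    """
    genes = sorted(per_gene_alignments)
    taxa = sorted({t for g in genes for t in per_gene_alignments[g]})
    partitions = []
    blocks = []
    offset = 0
    for gene in genes:
        aln = per_gene_alignments[gene]
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise ValueError(f"gene {gene!r}: rows have conflicting lengths {sorted(lengths)}")
        width = lengths.pop()
        w = np.asarray(weights[gene], dtype=float) if weights and gene in weights else np.ones(width)
        if len(w) != width:
            raise ValueError(f"gene {gene!r}: {len(w)} weights for {width} columns")
        rows = [aln.get(t, GAP * width) for t in taxa]
        blocks.append(_rows_to_matrix(rows))
        partitions.append(GenePartition(gene, offset, offset + width, w))
        offset += width
    return ConcatAlignment(taxa=taxa, matrix=np.hstack(blocks), partitions=partitions)


def _pairwise_distances(
    matrix: np.ndarray,
    weights: np.ndarray,
    n_states: int,
    max_distance: float,
) -> np.ndarray:
    n = matrix.shape[0]
    gap = GAP.encode()
    nongap = matrix != gap
    s = float(n_states)
    ceiling = (s - 1.0) / s
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            wsum = float(weights[both].sum())
            if wsum == 0:
                raise ValueError(f"taxa {i} and {j} share no comparable columns")
            diff = both & (matrix[i] != matrix[j])
            p = float(weights[diff].sum()) / wsum
            if p >= ceiling:
                d = max_distance
            else:
                d = -ceiling * math.log(1.0 - p / ceiling)
                d = min(d, max_distance)
            D[i, j] = D[j, i] = d
    return D


def distance_matrix(
    aln: ConcatAlignment,
    use_weights: bool = True,
    n_states: int = 20,
    max_distance: float = 10.0,
) -> np.ndarray:
    """Multiple-hit-corrected pairwise distances over the concatenation.

    The weighted p-distance (over columns where both taxa are non-gap) is
    corrected as d = -((s-1)/s) ln(1 - s p/(s-1)); saturated pairs cap at
    ``max_distance``. Use ``n_states=4`` for nucleotide (Jukes-Cantor)
    data.
    """
    if len(aln.taxa) < 3:
        raise ValueError("need at least 3 taxa")
    weights = aln.weights if use_weights else np.ones(aln.n_columns)
    return _pairwise_distances(aln.matrix, weights, n_states, max_distance)


# ---------------------------------------------------------------------------
# Neighbor joining

@dataclass
class Node:
    name: str | None = None
    children: list = field(default_factory=list)  # (Node, branch_length)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return str(self.name)
        inner = ",".join(f"{c._newick()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(distances, taxa: Sequence[str] | None = None) -> Node:
    """Neighbor-joining tree from a symmetric distance matrix.

    Deterministic: ties in the Q criterion break by the lexicographically
    smallest pair of subtree labels; negative branch lengths clamp to 0.
    Accepts a pandas DataFrame (taxa from its index) or an array plus
    ``taxa``. The returned root is an unrooted multifurcation.
    """
    if hasattr(distances, "to_numpy"):
        if taxa is None:
            taxa = list(distances.index)
        D = distances.to_numpy(dtype=float)
    else:
        D = np.asarray(distances, dtype=float)
        if taxa is None:
            taxa = [f"t{i}" for i in range(D.shape[0])]
    taxa = list(taxa)
    n = len(taxa)
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes = [Node(name=t) for t in taxa]
    labels = list(taxa)  # sort key: minimal leaf label of each active subtree
    D = D.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        pairs = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((labels[active[i]], labels[active[j]]))), i, j)
            for i, j in pairs if i < j
        )
        i, j = best[1], best[2]
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = Node(children=[(nodes[ai], li), (nodes[aj], lj)])
        # distances to the new node
        dnew = 0.5 * (D[ai, active] + D[aj, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        idx_new = D.shape[0] - 1
        D[idx_new, active] = dnew
        D[active, idx_new] = dnew
        nodes.append(new)
        labels.append(min(labels[ai], labels[aj]))
        active = [a for a in active if a not in (ai, aj)] + [idx_new]

    a, b = active
    dab = max(D[a, b], 0.0)
    left, right = nodes[a], nodes[b]
    if right.children:  # graft onto an internal node: unrooted multifurcation
        right.children.append((left, dab))
        return right
    if left.children:
        left.children.append((right, dab))
        return left
    return Node(children=[(left, dab / 2), (right, dab / 2)])


def tree_bipartitions(tree: Node) -> set[frozenset]:
    """Non-trivial bipartitions of the tree, each as its canonical side.

    Each internal edge splits the leaves in two; the side not containing
    the overall-minimum leaf label is stored, which makes sets comparable
    across differently rooted representations.
    """
    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    splits: set[frozenset] = set()

    def visit(node: Node) -> frozenset:
        if not node.children:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            side = visit(child)
            below |= side
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side if anchor not in side else all_leaves - side)
        return below

    visit(tree)
    return splits


@dataclass
class BootstrapResult:
    tree: Node
    newick: str
    supports: dict  # bipartition (frozenset) -> percent of replicates
    n_reps: int


def bootstrap_support(
    aln: ConcatAlignment,
    n_reps: int = 100,
    seed: int = 0,
    use_weights: bool = True,
    n_states: int = 20,
    max_distance: float = 10.0,
) -> BootstrapResult:
    """Column-bootstrap support for the NJ tree of a concatenated alignment.

    Columns are resampled with replacement within each gene partition
    (weights travel with their columns); each replicate is re-distanced
    and re-joined, and support is the percentage of replicates containing
    each bipartition of the original tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    base_weights = aln.weights if use_weights else np.ones(aln.n_columns)
    D = _pairwise_distances(aln.matrix, base_weights, n_states, max_distance)
    tree = nj_tree(D, aln.taxa)
    original = tree_bipartitions(tree)
    counts = {split: 0 for split in original}
    for _ in range(n_reps):
        idx = np.concatenate(
            [rng.integers(p.start, p.stop, size=p.stop - p.start) for p in aln.partitions]
        )
        Dr = _pairwise_distances(aln.matrix[:, idx], base_weights[idx], n_states, max_distance)
        rep_splits = tree_bipartitions(nj_tree(Dr, aln.taxa))
        for split in original:
            if split in rep_splits:
                counts[split] += 1
    supports = {split: 100.0 * c / n_reps for split, c in counts.items()}
    return BootstrapResult(tree=tree, newick=tree.to_newick(), supports=supports, n_reps=n_reps)


# ---------------------------------------------------------------------------
# Conserved signature indels

def csi_scan(alignment: Mapping[str, str], signature: CsiSignature) -> dict[str, int | None]:
    """Indel length between the signature flanks, per taxon.

    For each aligned row the gaps are stripped, the flank motifs located,
    and the result is (#residues strictly between the flanks) minus the
    signature's reference span. A missing flank yields None (not found);
    a flank matching twice raises, since the signature is then ambiguous.
    """
    results: dict[str, int | None] = {}
    for taxon, row in alignment.items():
        seq = row.replace(GAP, "")
        left_n = seq.count(signature.left_flank)
        right_n = seq.count(signature.right_flank)
        if left_n > 1 or right_n > 1:
            raise ValueError(f"flank matches more than once in {taxon!r}; signature ambiguous")
        if left_n == 0 or right_n == 0:
            results[taxon] = None
            continue
        left_end = seq.index(signature.left_flank) + len(signature.left_flank)
        right_start = seq.index(signature.right_flank)
        if right_start < left_end:
            results[taxon] = None
            continue
        results[taxon] = (right_start - left_end) - signature.reference_span
    return results
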