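"""Functional profiles: COG presence/absence, NMDS ordination, pathway scores.

Genomes are compared by the Euclidean distance between their binary COG
(cluster of orthologous groups) presence/absence vectors — for 0/1 rows
this is the square root of the Hamming distance — and ordinated with
non-metric multidimensional scaling. The NMDS minimizes Kruskal stress-1
by iterative majorization (SMACOF with isotonic regression) from several
seeded random starts plus one classical-scaling start, and reports the
best configuration with its stress. Pathway completeness is the fraction
of a pathway's required gene set present in a genome's annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

__all__ = [
    "PathwayDefinition",
    "OrdinationResult",
    "cog_matrix",
    "nmds",
    "kruskal_stress",
    "pathway_completeness",
    "default_pathways",
]


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    required: frozenset

    def __post_init__(self):
        if not self.required:
            raise ValueError("pathway requires a non-empty gene set")


@dataclass
class OrdinationResult:
    coords: pd.DataFrame  # genome x dimension
    stress: float  # Kruskal stress-1
    n_restarts: int
    seed: int


def cog_matrix(annotations: Mapping[str, Iterable[str]] | pd.DataFrame) -> pd.DataFrame:
    """Binary genome x COG matrix from per-genome COG label sets.

    Accepts a mapping genome -> COG labels, or a DataFrame with columns
    (genome, cog). Columns are the union of observed COGs; an entry is 1
    iff the genome has at least one gene with that COG.
    """
    if isinstance(annotations, pd.DataFrame):
        grouped: dict[str, set] = {
            g: set(sub["cog"].dropna()) for g, sub in annotations.groupby("genome")
        }
    else:
        grouped = {g: set(c) for g, c in annotations.items()}
    if len(grouped) < 2:
        raise ValueError("need at least two genomes")
    for g, cogs in grouped.items():
        if not cogs:
            warnings.warn(f"genome {g!r} has no COG annotations; all-zero row")
    genomes = sorted(grouped)
    cogs = sorted(set().union(*grouped.values()))
    data = [[1 if c in grouped[g] else 0 for c in cogs] for g in genomes]
    return pd.DataFrame(data, index=genomes, columns=cogs, dtype=int)


def kruskal_stress(dissimilarities: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against given dissimilarities.

    Fitted distances come from isotonic (monotone) regression of the
    configuration distances on the dissimilarity ranks.
    """
    delta = np.asarray(dissimilarities, dtype=float)
    if delta.ndim == 2:
        delta = delta[np.triu_indices(delta.shape[0], 1)]
    d = pdist(np.asarray(coords, dtype=float))
    order = np.argsort(delta, kind="stable")
    dhat = np.empty_like(d)
    dhat[order] = IsotonicRegression().fit_transform(np.arange(len(d)), d[order])
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _classical_scaling(D: np.ndarray, dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:dims]
    coords = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
    return coords


def nmds(
    dist,
    dims: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    eps: float = 1e-9,
) -> OrdinationResult:
    """Non-metric MDS of a symmetric distance matrix into ``dims`` dimensions.

    Runs SMACOF with monotone regression from ``n_restarts`` seeded random
    starts plus one classical-scaling start, recomputes Kruskal stress-1
    for each converged configuration, and returns the best. Deterministic
    given ``seed``.
    """
    if hasattr(dist, "to_numpy"):
        index = list(dist.index)
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        index = list(range(D.shape[0]))
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3 or n <= dims:
        raise ValueError(f"need more than dims={dims} points (and at least 3), got {n}")

    def run(init, random_state) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model = MDS(
                n_components=dims,
                metric="precomputed",
                metric_mds=False,
                n_init=1,
                max_iter=max_iter,
                eps=eps,
                random_state=random_state,
                normalized_stress=True,
            )
            return model.fit_transform(D, init=init)

    rng = np.random.default_rng(seed)
    candidates = [run(_classical_scaling(D, dims), 0)]
    for _ in range(n_restarts):
        init = rng.standard_normal((n, dims))
        candidates.append(run(init, int(rng.integers(0, 2**31 - 1))))
    stresses = [kruskal_stress(D, X) for X in candidates]
    best = int(np.argmin(stresses))
    X = candidates[best]
    X = X - X.mean(axis=0)
    coords = pd.DataFrame(X, index=index, columns=[f"NMDS{i + 1}" for i in range(dims)])
    return OrdinationResult(coords=coords, stress=stresses[best], n_restarts=n_restarts, seed=seed)


def pathway_completeness(genes_present: Iterable[str], pathway: PathwayDefinition) -> float:
    """Fraction of the pathway's required genes present in the annotation set."""
    present = set(genes_present) & pathway.required
    return len(present) / len(pathway.required)


def default_pathways() -> dict[str, PathwayDefinition]:
    """Bundled example pathway definitions (editable TSV resource)."""
    text = resources.files("streampop").joinpath("data/pathways.tsv").read_text()
    by_name: dict[str, set] = {}
    for line in text.strip().splitlines()[1:]:
        pathway, gene = line.split("\t")
        by_name.setdefault(pathway, set()).add(gene)
    return {n: PathwayDefinition(n, frozenset(g)) for n, g in by_name.items()}
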