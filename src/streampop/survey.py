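"""Ecological distribution: 16S identity occurrence calls and rank statistics.

A phylotype is scored "present" at a survey site when any sequence in the
site's 16S pool exceeds a nucleotide-identity threshold (strictly >97% by
default) against the phylotype's reference gene. Temperature and pH
distributions of occupied sites are then compared with a Kruskal-Wallis
rank-sum test; environmental ranges across surveys are compared with a
Pearson correlation. Temperature values given as ranges collapse to their
arithmetic mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .identity import rrna_identity

__all__ = [
    "SiteRecord",
    "OccurrenceCall",
    "RankTestResult",
    "occurrence_call",
    "kruskal_wallis",
    "pearson_r",
    "mean_of_range",
]

ORPHAN = "ORPHAN"


def mean_of_range(value) -> float:
    """Collapse '70-75'-style range strings to their arithmetic mean."""
    if isinstance(value, str) and "-" in value.strip("-"):
        lo, hi = value.split("-", 1)
        return (float(lo) + float(hi)) / 2.0
    return float(value)


@dataclass
class SiteRecord:
    """One survey site: metadata plus its pool of 16S gene sequences."""

    site_id: str
    temperature: float
    ph: float
    pool: list[tuple[str, str]] = field(default_factory=list)  # (seq id, sequence)

    def __post_init__(self):
        self.temperature = mean_of_range(self.temperature)
        self.ph = mean_of_range(self.ph)
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"pH {self.ph} outside [0, 14]")


@dataclass(frozen=True)
class OccurrenceCall:
    site_id: str
    phylotype: str | None
    best_identity: float | None  # percentage; None for an empty pool
    positive: bool


@dataclass(frozen=True)
class RankTestResult:
    h: float
    df: int
    p_value: float
    tie_corrected: bool
    p_exact: float | None = None


def occurrence_call(
    reference,
    sites: Sequence[SiteRecord],
    threshold: float = 97.0,
    phylotype: str | None = None,
) -> list[OccurrenceCall]:
    """Call presence/absence of one phylotype across sites.

    Positive iff the best pool identity is strictly greater than
    ``threshold`` (percent). An empty pool yields a negative call with
    ``best_identity=None``.
    """
    if isinstance(reference, tuple):
        phylotype = phylotype or reference[0]
        ref_seq = reference[1]
    else:
        ref_seq = str(reference)
    if len(ref_seq) < 200:
        raise ValueError("reference 16S gene must be >= 200 bases")
    calls = []
    for site in sites:
        if not site.pool:
            calls.append(OccurrenceCall(site.site_id, phylotype, None, False))
            continue
        best = max(rrna_identity(ref_seq, seq) for _, seq in site.pool)
        calls.append(OccurrenceCall(site.site_id, phylotype, best, best > threshold))
    return calls


def _h_statistic(ranks: np.ndarray, sizes: Sequence[int], tie_factor: float) -> float:
    n = len(ranks)
    h = 0.0
    offset = 0
    for size in sizes:
        r = ranks[offset : offset + size].sum()
        h += r * r / size
        offset += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_factor


def kruskal_wallis(groups: Sequence[Sequence[float]], exact: bool = False) -> RankTestResult:
    """Kruskal-Wallis rank-sum test with mid-rank tie correction.

    The chi-squared p-value uses k-1 degrees of freedom. With
    ``exact=True`` and total n <= 10, an exact permutation p-value over
    all distinct group assignments is also computed.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(groups)
    n = len(pooled)
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = stats.rankdata(pooled)
    tie_factor = stats.tiecorrect(ranks)
    if tie_factor == 0:
        # all observations identical: no evidence of any difference
        return RankTestResult(0.0, len(groups) - 1, 1.0, True, 1.0 if exact else None)
    sizes = [len(g) for g in groups]
    h = _h_statistic(ranks, sizes, tie_factor)
    df = len(groups) - 1
    p = float(stats.chi2.sf(h, df))
    p_exact = None
    if exact and n <= 10:
        h_obs = h - 1e-12
        indices = list(range(n))
        count = total = 0
        for assignment in _group_assignments(indices, sizes):
            perm_ranks = ranks[assignment]
            if _h_statistic(perm_ranks, sizes, tie_factor) >= h_obs:
                count += 1
            total += 1
        p_exact = count / total
    return RankTestResult(float(h), df, p, bool(tie_factor < 1.0), p_exact)


def _group_assignments(indices: list[int], sizes: Sequence[int]):
    """All distinct splits of ``indices`` into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield list(indices)
        return
    first, rest = sizes[0], sizes[1:]
    for combo in itertools.combinations(indices, first):
        remaining = [i for i in indices if i not in combo]
        for tail in _group_assignments(remaining, rest):
            yield list(combo) + tail


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
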