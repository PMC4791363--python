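"""Assembly statistics and marker-based genome completeness.

Completeness of a genome bin is estimated as the fraction of a reference
single-copy marker catalog with at least one (possibly partial) annotated
gene, averaged over three catalogs: 21 tRNA-synthetase genes, 40
conserved universal prokaryotic markers, and 178 conserved bacterial
housekeeping genes. The bundled catalogs are editable placeholders (the
21 aminoacyl-tRNA-synthetase names are the standard gene symbols; the
larger lists carry generic labels): for real annotations, supply the
catalogs that match the annotation vocabulary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import gc_content

__all__ = [
    "MarkerCatalog",
    "CompletenessReport",
    "default_catalogs",
    "marker_fraction",
    "assembly_stats",
    "completeness_report",
]


@dataclass(frozen=True)
class MarkerCatalog:
    """A named set of single-copy marker labels.

    ``mode`` controls what counts as evidence for a marker:
    "at-least-one-partial" (default) accepts partial genes, "full-only"
    requires at least one non-partial gene.
    """

    name: str
    markers: frozenset
    mode: str = "at-least-one-partial"

    def __post_init__(self):
        if not self.markers:
            raise ValueError("marker catalog must be non-empty")
        if self.mode not in ("at-least-one-partial", "full-only"):
            raise ValueError(f"unknown catalog mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class CompletenessReport:
    fractions: dict  # catalog name -> fraction in [0, 1]
    mean_pct: float  # unweighted mean of the fractions, as a percentage
    stats: dict | None = None


def default_catalogs() -> tuple[MarkerCatalog, MarkerCatalog, MarkerCatalog]:
    """The three bundled catalogs (21 tRNA synthetases, 40 universal, 178 bacterial)."""
    text = resources.files("streampop").joinpath("data/marker_catalogs.tsv").read_text()
    by_name: dict[str, set[str]] = {}
    for line in text.strip().splitlines()[1:]:
        catalog, marker = line.split("\t")
        by_name.setdefault(catalog, set()).add(marker)
    order = ["trna_synthetases", "universal_40", "bacterial_178"]
    return tuple(MarkerCatalog(n, frozenset(by_name[n])) for n in order)


def marker_fraction(annotations: pd.DataFrame, catalog: MarkerCatalog) -> float:
    """Fraction of catalog markers with at least one annotated gene.

    ``annotations`` needs columns ``marker`` and ``partial``; rows whose
    marker is not in the catalog are ignored (unknown labels warn).
    """
    rows = annotations[annotations["marker"].notna()]
    if len(rows):
        unknown = set(rows["marker"]) - set(catalog.markers)
        # labels from other catalogs are routine; warn only informatively
        if unknown - _all_known_markers():
            warnings.warn(f"ignoring unknown marker labels: {sorted(unknown - _all_known_markers())[:5]}")
    if catalog.mode == "full-only":
        rows = rows[~rows["partial"].astype(bool)]
    present = set(rows["marker"]) & set(catalog.markers)
    return len(present) / len(catalog)


def _all_known_markers() -> frozenset:
    return frozenset().union(*(c.markers for c in default_catalogs()))


def assembly_stats(contigs: Sequence, annotations: pd.DataFrame | None = None) -> dict:
    """Basic assembly statistics of a bin.

    Returns size (Mbp), G+C (%) over the concatenated contigs, contig
    count, longest contig (kbp), and — when annotations are supplied —
    the count of coding (type == "CDS") genes.
    """
    if not contigs:
        raise ValueError("bin must contain at least one contig")
    lengths = [len(c.sequence) for c in contigs]
    concatenated = "".join(c.sequence for c in contigs)
    stats = {
        "size_mbp": sum(lengths) / 1e6,
        "gc_pct": 100.0 * gc_content(concatenated),
        "n_contigs": len(contigs),
        "longest_contig_kbp": max(lengths) / 1e3,
    }
    if annotations is not None:
        stats["coding_genes"] = int((annotations["type"] == "CDS").sum())
    return stats


def completeness_report(
    contigs: Sequence,
    annotations: pd.DataFrame,
    catalogs: Sequence[MarkerCatalog] | None = None,
) -> CompletenessReport:
    """Three per-catalog marker fractions, their mean (%), and assembly stats."""
    if catalogs is None:
        catalogs = default_catalogs()
    if len(catalogs) != 3:
        raise ValueError(f"exactly three marker catalogs required, got {len(catalogs)}")
    fractions = {c.name: marker_fraction(annotations, c) for c in catalogs}
    mean_pct = 100.0 * float(np.mean(list(fractions.values())))
    return CompletenessReport(
        fractions=fractions,
        mean_pct=mean_pct,
        stats=assembly_stats(contigs, annotations),
    )
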