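"""File formats: FASTA (with coverage-tagged contigs), TSV tables.

Contig coverage travels in the FASTA description line as ``cov=<float>``,
so a contig set round-trips through a single plain FASTA file. Truth
tables, annotation tables, and site metadata are tab-separated files read
and written with pandas; temperature/pH ranges like "70-75" collapse to
their mean on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .survey import SiteRecord, mean_of_range
from .synth import Contig, Read

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_contigs",
    "write_contigs",
    "read_reads",
    "write_reads",
    "read_table",
    "write_table",
    "read_sites",
]

_COV_RE = re.compile(r"cov=([0-9.eE+\-]+)")


def write_fasta(path, records: Iterable[tuple]) -> None:
    """Write (id, seq) or (id, seq, description) tuples as FASTA."""
    seq_records = []
    for rec in records:
        name, seq = rec[0], rec[1]
        desc = rec[2] if len(rec) > 2 else ""
        seq_records.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str, str]]:
    """Read FASTA into (id, sequence, description) tuples."""
    return [(r.id, str(r.seq), r.description) for r in SeqIO.parse(str(path), "fasta")]


def write_contigs(path, contigs: Sequence[Contig]) -> None:
    write_fasta(path, [(c.contig_id, c.sequence, f"cov={c.coverage:.4f}") for c in contigs])


def read_contigs(path) -> list[Contig]:
    contigs = []
    for name, seq, desc in read_fasta(path):
        m = _COV_RE.search(desc)
        cov = float(m.group(1)) if m else 1.0
        contigs.append(Contig(contig_id=name, sequence=seq, coverage=cov))
    return contigs


def write_reads(path, reads: Sequence[Read]) -> None:
    write_fasta(path, [(r.read_id, r.sequence) for r in reads])


def read_reads(path) -> list[Read]:
    return [Read(name, seq) for name, seq, _ in read_fasta(path)]


def write_table(path, table: pd.DataFrame, index: bool = False) -> None:
    table.to_csv(str(path), sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")


def read_sites(metadata_path, pools_dir=None) -> list[SiteRecord]:
    """Site records from a metadata TSV (site_id, temperature, ph).

    Temperature and pH entries may be ranges ("70-75"); they collapse to
    their mean. With ``pools_dir``, each site's 16S pool is loaded from
    ``<pools_dir>/<site_id>.fasta`` when present.
    """
    meta = pd.read_csv(str(metadata_path), sep="\t", dtype={"site_id": str})
    sites = []
    for _, row in meta.iterrows():
        pool = []
        if pools_dir is not None:
            fasta = Path(pools_dir) / f"{row['site_id']}.fasta"
            if fasta.exists():
                pool = [(name, seq) for name, seq, _ in read_fasta(fasta)]
        sites.append(
            SiteRecord(
                site_id=row["site_id"],
                temperature=mean_of_range(row["temperature"]),
                ph=mean_of_range(row["ph"]),
                pool=pool,
            )
        )
    return sites
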