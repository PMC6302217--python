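"""Contig container and FASTA / metadata-TSV I/O.

A :class:`Contig` is the atom of every stage: a nucleotide sequence plus the
sample label and the read coverage it was assembled at. FASTA I/O goes
through Biopython (60-column wrap); per-contig metadata travels in a sidecar
TSV with columns ``id  sample  length  gc  coverage``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

METADATA_COLUMNS = ["id", "sample", "length", "gc", "coverage"]


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class Contig:
    """A nucleotide sequence with sample label and x-fold coverage."""

    id: str
    sequence: str
    sample: str = ""
    coverage: float = 0.0

    @property
    def length(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "Contig":
        return Contig(self.id, reverse_complement(self.sequence),
                      sample=self.sample, coverage=self.coverage)


def write_fasta(contigs: Iterable[Contig], path: str | Path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, metadata: pd.DataFrame | None = None,
               sample: str = "") -> list[Contig]:
    """Load contigs; if a metadata frame is given, attach sample/coverage."""
    meta = None
    if metadata is not None:
        meta = metadata.set_index("id")
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        c = Contig(rec.id, str(rec.seq).upper(), sample=sample)
        if meta is not None and rec.id in meta.index:
            row = meta.loc[rec.id]
            c.sample = str(row["sample"])
            c.coverage = float(row["coverage"])
        contigs.append(c)
    return contigs


def write_metadata(contigs: Iterable[Contig], path: str | Path) -> None:
    from .seqprofile import gc_content  # local import to avoid a cycle
    rows = [
        {"id": c.id, "sample": c.sample, "length": c.length,
         "gc": round(gc_content(c), 6), "coverage": c.coverage}
        for c in contigs
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "sample": str})
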