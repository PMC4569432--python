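"""Raw sequence records and their FASTA/FASTQ serialisation.

Two record kinds feed the pipeline: full-length reference 16S genes
(:class:`RefRecord`) and quality-scored V1-V2 amplicon reads
(:class:`ReadRecord`).  Reference records carry a eukaryote flag in the FASTA
description (``euk=1``) because eukaryote screening is an input annotation,
not a classifier, in this pipeline.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import ambiguous_count


@dataclass
class RefRecord:
    """A full-length 16S reference sequence."""

    id: str
    sequence: str
    eukaryote_flag: bool = False
    source: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def ambiguous_count(self) -> int:
        return ambiguous_count(self.sequence)


@dataclass
class ReadRecord:
    """A single amplicon read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int] = field(default_factory=list)
    sample_id: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if len(self.qualities) and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases")

    @property
    def mean_quality(self) -> float:
        if len(self.qualities) == 0:
            raise ValueError(f"read {self.id}: empty quality string")
        return float(np.asarray(self.qualities, dtype=np.float64).mean())


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA (references)


def write_reference_fasta(records: Iterable[RefRecord], path: str | Path) -> None:
    seqs = []
    for r in records:
        desc = f"euk={1 if r.eukaryote_flag else 0}"
        if r.source:
            desc += f" source={r.source}"
        seqs.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    with _open(path, "wt") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_reference_fasta(path: str | Path) -> list[RefRecord]:
    out = []
    with _open(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            tags = dict(
                t.split("=", 1) for t in rec.description.split()[1:] if "=" in t)
            out.append(RefRecord(
                id=rec.id,
                sequence=str(rec.seq),
                eukaryote_flag=tags.get("euk", "0") == "1",
                source=tags.get("source", ""),
            ))
    return out


# ---------------------------------------------------------------------------
# FASTQ (reads; Phred+33, plain or gzip)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path: str | Path, sample_id: str = "") -> list[ReadRecord]:
    out = []
    with _open(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            out.append(ReadRecord(
                id=rec.id,
                sequence=str(rec.seq),
                qualities=list(rec.letter_annotations["phred_quality"]),
                sample_id=sample_id,
            ))
    return out


def write_fasta(named_seqs: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Plain FASTA for trimmed reads or cluster representatives."""
    with _open(path, "wt") as fh:
        for name, seq in named_seqs:
            fh.write(f">{name}\n{seq}\n")


def iter_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    with _open(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)
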