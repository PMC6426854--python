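"""FASTA/FASTQ reading and writing (thin Biopython wrappers)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict (upper-cased)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> dict[str, str]:
    """Read a FASTQ file into an ordered {id: sequence} dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")
    }


def write_fastq(reads, path: str | Path, quality: int = 40) -> None:
    """Write reads as Sanger FASTQ (Phred+33) with a constant quality.

    ``reads`` is an iterable of objects with ``read_id`` and ``seq``
    attributes, or of (id, seq) pairs.
    """
    records = []
    for r in reads:
        rid, seq = (r.read_id, r.seq) if hasattr(r, "read_id") else r
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
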