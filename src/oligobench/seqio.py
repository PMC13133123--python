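"""FASTA/FASTQ I/O for reference pools and read sets.

Pools are exchanged as FASTA; simulated reads as FASTQ with a constant
placeholder quality (the pipeline never uses qualities).  A read's true
origin index and multiplicity are stored in the record description as
``origin=<i> abundance=<n>`` and recovered on round-trip.
"""

from __future__ import annotations

import re

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import FormatError, Read, ReadSet, ReferencePool, is_dna

PLACEHOLDER_QUALITY = 40  # Phred score written for every base

_ORIGIN_RE = re.compile(r"origin=(\d+)")
_ABUNDANCE_RE = re.compile(r"abundance=(\d+)")


def _check_dna(seq: str, record_id: str, strict: bool) -> None:
    if strict and not is_dna(seq):
        raise FormatError(
            f"record {record_id!r} contains non-ACGT characters (strict mode)"
        )
    if not seq:
        raise FormatError(f"record {record_id!r} has an empty sequence")


def read_fasta(path, strict: bool = True) -> ReferencePool:
    """Read a reference pool from FASTA.

    In strict mode any character outside {A, C, G, T} (e.g. IUPAC "N") is
    a format error naming the offending record.
    """
    ids: list[str] = []
    sequences: list[str] = []
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            seq = str(record.seq).upper()
            _check_dna(seq, record.id, strict)
            ids.append(record.id)
            sequences.append(seq)
    except ValueError as exc:  # malformed FASTA from Biopython
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not sequences:
        raise FormatError(f"no FASTA records found in {path}")
    return ReferencePool(sequences=sequences, ids=ids)


def write_fasta(pool: ReferencePool, path) -> None:
    if not len(pool):
        raise FormatError("refusing to write an empty pool")
    records = [
        SeqRecord(Seq(seq), id=rid, description="")
        for rid, seq in zip(pool.ids, pool.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path, strict: bool = True) -> ReadSet:
    """Read simulated reads from FASTQ; qualities are ignored.

    Identical records written from one multiplicity-``n`` read come back
    as ``n`` unit-abundance reads; callers aggregate as needed.
    """
    reads: list[Read] = []
    try:
        for record in SeqIO.parse(str(path), "fastq"):
            seq = str(record.seq).upper()
            _check_dna(seq, record.id, strict)
            desc = record.description
            m = _ORIGIN_RE.search(desc)
            origin = int(m.group(1)) if m else None
            reads.append(Read(sequence=seq, origin=origin, abundance=1))
    except ValueError as exc:  # mismatched quality length etc.
        raise FormatError(f"malformed FASTQ {path}: {exc}") from exc
    if not reads:
        raise FormatError(f"no FASTQ records found in {path}")
    return ReadSet(reads=reads)


def write_fastq(readset: ReadSet, path) -> None:
    """Write reads as FASTQ, expanding multiplicities into distinct records."""
    if not len(readset):
        raise FormatError("refusing to write an empty read set")
    records = []
    idx = 0
    for read in readset.reads:
        for copy in range(read.abundance):
            desc = f"abundance={read.abundance}"
            if read.origin is not None:
                desc = f"origin={read.origin} {desc}"
            rec = SeqRecord(
                Seq(read.sequence),
                id=f"read{idx}.{copy}",
                description=desc,
            )
            rec.letter_annotations["phred_quality"] = [PLACEHOLDER_QUALITY] * len(
                read.sequence
            )
            records.append(rec)
        idx += 1
    SeqIO.write(records, str(path), "fastq")
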