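"""Domain types and seeded fixture generation.

The package models a DNA data-storage experiment as a pipeline of four
stages: a codec encodes a binary payload into a pool of reference
sequences, a channel turns the pool into sequencing reads, clustering and
consensus calling reduce the reads back to candidate sequences, and the
codec attempts to decode them.  The types here are the containers those
stages exchange.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

DNA_ALPHABET = "ACGT"
_DNA_SET = frozenset(DNA_ALPHABET)

#: byte value <-> base mapping used by every codec (2 bits per nucleotide)
BASE_TO_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
BITS_TO_BASE = "ACGT"


class OligobenchError(Exception):
    """Base class for package errors."""


class ArgumentError(OligobenchError, ValueError):
    """Invalid argument to an operation."""


class FormatError(OligobenchError, ValueError):
    """Malformed sequence file or record."""


def is_dna(sequence: str) -> bool:
    """True if *sequence* is non-empty and over {A, C, G, T}."""
    return bool(sequence) and set(sequence) <= _DNA_SET


def derive_rng(seed: int, *tags: object) -> np.random.Generator:
    """Derive an independent RNG stream from a root seed and stage tags.

    Each pipeline stage derives its own stream from ``(root seed, stage
    name, ...)`` so stages can be re-run in isolation and remain
    bit-reproducible.  String tags are hashed with CRC32; integer tags are
    used directly.
    """
    keys = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        if isinstance(tag, (int, np.integer)):
            keys.append(int(tag) & 0x7FFFFFFF)
        else:
            keys.append(zlib.crc32(str(tag).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(keys))


@dataclass(frozen=True)
class Payload:
    """A binary payload to be stored in DNA.

    The default benchmark payload is a random-content file of 19456 bytes
    ("19 kB"); any byte string can be wrapped.
    """

    data: bytes
    label: str = "payload"

    @property
    def size_bytes(self) -> int:
        return len(self.data)

    def write(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.data)

    @classmethod
    def read(cls, path, label: str | None = None) -> "Payload":
        with open(path, "rb") as fh:
            data = fh.read()
        return cls(data=data, label=label or str(path))


def generate_payload(size_bytes: int, seed: int, label: str = "random") -> Payload:
    """Generate a uniformly random payload, deterministic per seed."""
    if size_bytes < 1:
        raise ArgumentError(f"size_bytes must be >= 1, got {size_bytes}")
    rng = derive_rng(seed, "payload")
    data = rng.integers(0, 256, size=size_bytes, dtype=np.uint8).tobytes()
    return Payload(data=data, label=label)


@dataclass
class ReferencePool:
    """Ordered set of encoded DNA sequences; ground truth for evaluation."""

    sequences: list[str]
    ids: list[str] = field(default_factory=list)
    payload_size: int = 0
    design_length: int = 0

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = [f"seq{i}" for i in range(len(self.sequences))]
        if len(self.ids) != len(self.sequences):
            raise ArgumentError("ids and sequences must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ArgumentError("pool ids must be unique")
        if not self.design_length and self.sequences:
            self.design_length = len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def code_rate(self) -> float:
        """Data bits stored per designed nucleotide, 8·payload/(count·L)."""
        total_nt = len(self.sequences) * self.design_length
        if total_nt == 0:
            return 0.0
        return 8.0 * self.payload_size / total_nt


@dataclass(frozen=True)
class Read:
    """A (simulated) sequencing read.

    ``origin`` carries the true reference index when the read comes from
    the simulator; real data would recover it by read mapping.
    ``abundance`` is the multiplicity of identical reads.
    """

    sequence: str
    origin: int | None = None
    abundance: int = 1

    def __post_init__(self) -> None:
        if not is_dna(self.sequence):
            raise ArgumentError("read sequence must be non-empty over ACGT")
        if self.abundance < 1:
            raise ArgumentError("read abundance must be positive")


@dataclass
class ReadSet:
    """Multiset of reads with a link back to the originating pool."""

    reads: list[Read]
    pool_ref: str = ""
    pool_size: int = 0

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def total_reads(self) -> int:
        return sum(r.abundance for r in self.reads)

    @property
    def depth(self) -> float:
        """Mean reads per reference sequence (with multiplicity)."""
        if not self.pool_size:
            return float("nan")
        return self.total_reads / self.pool_size

    def origins(self) -> list[int | None]:
        return [r.origin for r in self.reads]

    def unique_counts(self) -> dict[str, int]:
        """Aggregate multiplicities of identical read sequences."""
        counts: dict[str, int] = {}
        for r in self.reads:
            counts[r.sequence] = counts.get(r.sequence, 0) + r.abundance
        return counts


def pad_trim(sequence: str, length: int, pad_base: str = "A") -> str:
    """Pad (with a fixed base) or trim a sequence to the design length."""
    if len(sequence) >= length:
        return sequence[:length]
    return sequence + pad_base * (length - len(sequence))


def dna_to_bytes(sequence: str) -> bytes:
    """Pack a DNA string into bytes, 2 bits per nucleotide (A=00..T=11).

    The length must be a multiple of 4 nt.
    """
    if len(sequence) % 4:
        raise ArgumentError("sequence length must be a multiple of 4 nt")
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for base, val in BASE_TO_BITS.items():
        lut[ord(base)] = val
    bits = lut[codes].reshape(-1, 4)
    packed = (bits[:, 0] << 6) | (bits[:, 1] << 4) | (bits[:, 2] << 2) | bits[:, 3]
    return packed.astype(np.uint8).tobytes()


def bytes_to_dna(data: bytes) -> str:
    """Unpack bytes into a DNA string, 2 bits per nucleotide."""
    arr = np.frombuffer(data, dtype=np.uint8)
    out = np.empty((len(arr), 4), dtype=np.uint8)
    out[:, 0] = (arr >> 6) & 3
    out[:, 1] = (arr >> 4) & 3
    out[:, 2] = (arr >> 2) & 3
    out[:, 3] = arr & 3
    lut = np.frombuffer(BITS_TO_BASE.encode("ascii"), dtype=np.uint8)
    return lut[out.ravel()].tobytes().decode("ascii")
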