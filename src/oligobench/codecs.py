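"""Reference encoder/decoder implementations.

Three codecs embody the design space the benchmark compares:

* ``BaselineCodec`` — index + payload at 2 bit/nt with no error
  correction; relies entirely on clustering/consensus and tolerates no
  sequence dropout.
* ``RSInnerOuterCodec`` — the inner/outer code-separation strategy: an
  inner Reed–Solomon code corrects symbol errors within each sequence,
  an outer RS code across sequences recovers dropped or uncorrectable
  sequences as erasures (errors-and-erasures decoding).
* ``FountainCodec`` — an LT/fountain code: each sequence is a droplet
  (XOR of a robust-soliton-distributed subset of source segments) with a
  small inner RS code used only to *detect* and discard corrupted
  droplets.

Every encoder prepends an 8-byte header (payload length + CRC32) so
decoders can verify byte-exact recovery internally and never report a
wrong success.  An :class:`ExternalCodecAdapter` wraps subprocess
encode/decode commands in the same contract.
"""

from __future__ import annotations

import math
import shlex
import struct
import subprocess
import tempfile
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .core import (
    ArgumentError,
    Payload,
    ReferencePool,
    bytes_to_dna,
    dna_to_bytes,
    pad_trim,
)
from .reedsolomon import RSDecodeError, rs_check, rs_decode, rs_encode

_HEADER = struct.Struct("<II")  # payload length, CRC32
HEADER_BYTES = _HEADER.size


def _wrap(payload: bytes) -> bytes:
    return _HEADER.pack(len(payload), zlib.crc32(payload)) + payload


def _unwrap(message: bytes) -> bytes | None:
    """Recover and verify the payload; None when the checksum fails."""
    if len(message) < HEADER_BYTES:
        return None
    length, crc = _HEADER.unpack(message[:HEADER_BYTES])
    body = message[HEADER_BYTES : HEADER_BYTES + length]
    if len(body) != length or zlib.crc32(body) != crc:
        return None
    return body


@dataclass
class DecodeResult:
    status: str  # "success" | "failure"
    payload: bytes | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def success(self) -> bool:
        return self.status == "success"


def load_presets() -> dict:
    """Standardized parameter sets (rates 0.50/1.00/1.50 at L = 152 nt)."""
    text = resources.files("oligobench.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def get_codec(name: str, rate: str | float = "1.00"):
    """Instantiate a codec from the shipped presets.

    ``name`` is one of baseline | rs | fountain; ``rate`` one of the
    standardized code-rate labels (ignored for baseline).
    """
    presets = load_presets()
    if name == "baseline":
        cfg = presets["baseline"]["max"]
        return BaselineCodec(length=cfg["length"], index_bytes=cfg["index_bytes"])
    key = rate if isinstance(rate, str) else f"{rate:.2f}"
    if name == "rs":
        cfg = presets["rs"][key]
        return RSInnerOuterCodec(
            length=cfg["length"],
            index_bytes=cfg["index_bytes"],
            inner_k=cfg["inner_k"],
            outer_n=cfg["outer_n"],
            outer_k=cfg["outer_k"],
        )
    if name == "fountain":
        cfg = presets["fountain"][key]
        return FountainCodec(
            length=cfg["length"],
            seed_bytes=cfg["seed_bytes"],
            parity_bytes=cfg["parity_bytes"],
            overhead=cfg["overhead"],
            soliton_c=cfg["c"],
            soliton_delta=cfg["delta"],
        )
    raise ArgumentError(f"unknown codec {name!r}")


def _seq_bytes(sequence: str, length: int) -> bytes:
    return dna_to_bytes(pad_trim(sequence, length))


class BaselineCodec:
    """Index + raw payload chunk at 2 bit/nt; no error correction."""

    name = "baseline"

    def __init__(self, length: int = 152, index_bytes: int = 2):
        if length % 4:
            raise ArgumentError("sequence length must be a multiple of 4 nt")
        self.length = length
        self.index_bytes = index_bytes
        self.chunk = length // 4 - index_bytes
        if self.chunk < 1:
            raise ArgumentError("sequence too short for index + payload")

    def encode(self, payload: bytes) -> ReferencePool:
        msg = _wrap(payload)
        n_seqs = math.ceil(len(msg) / self.chunk)
        if n_seqs > 256**self.index_bytes:
            raise ArgumentError("payload too large for the index width")
        msg = msg.ljust(n_seqs * self.chunk, b"\x00")
        sequences = []
        for i in range(n_seqs):
            record = i.to_bytes(self.index_bytes, "big") + msg[
                i * self.chunk : (i + 1) * self.chunk
            ]
            sequences.append(bytes_to_dna(record))
        return ReferencePool(
            sequences=sequences, payload_size=len(payload), design_length=self.length
        )

    def decode(self, sequences, abundances=None) -> DecodeResult:
        if abundances is None:
            abundances = [1] * len(sequences)
        best: dict[int, tuple[int, bytes]] = {}
        for seq, ab in zip(sequences, abundances):
            record = _seq_bytes(seq, self.length)
            idx = int.from_bytes(record[: self.index_bytes], "big")
            if idx not in best or ab > best[idx][0]:
                best[idx] = (ab, record[self.index_bytes :])
        n_seqs = (max(best) + 1) if best else 0
        chunks = []
        missing = 0
        for i in range(n_seqs):
            if i in best:
                chunks.append(best[i][1])
            else:
                missing += 1
                chunks.append(b"\x00" * self.chunk)
        payload = _unwrap(b"".join(chunks)) if missing == 0 else None
        diag = {"missing": missing, "indexed": len(best)}
        if payload is None:
            return DecodeResult("failure", diagnostics=diag)
        return DecodeResult("success", payload=payload, diagnostics=diag)


class RSInnerOuterCodec:
    """Reed–Solomon inner/outer code separation.

    Each sequence is an inner RS(n, k) codeword over GF(256) holding a
    global index plus a payload chunk; pools larger than one outer block
    are split into B blocks interleaved round-robin by index (sequence
    ``g`` sits at position ``g // B`` of block ``g % B``).  The outer
    RS(N, K) code runs column-wise over each block's chunk bytes.
    """

    name = "rs"

    def __init__(
        self,
        length: int = 152,
        index_bytes: int = 2,
        inner_k: int = 30,
        outer_n: int = 28,
        outer_k: int = 19,
    ):
        if length % 4:
            raise ArgumentError("sequence length must be a multiple of 4 nt")
        self.length = length
        self.inner_n = length // 4
        self.inner_k = inner_k
        self.index_bytes = index_bytes
        self.chunk = inner_k - index_bytes
        self.outer_n = outer_n
        self.outer_k = outer_k
        if not (1 <= inner_k <= self.inner_n <= 255):
            raise ArgumentError("inner (n, k) outside GF(256) bounds")
        if not (1 <= outer_k <= outer_n <= 255):
            raise ArgumentError("outer (N, K) outside GF(256) bounds")
        if self.chunk < 1:
            raise ArgumentError("inner_k leaves no room for payload")
        self._blocks: int | None = None  # remembered from the last encode

    @property
    def inner_radius(self) -> int:
        return (self.inner_n - self.inner_k) // 2

    @property
    def erasure_bound(self) -> int:
        """Dropped sequences tolerated per outer block."""
        return self.outer_n - self.outer_k

    def _geometry(self, msg_len: int) -> int:
        n_chunks = math.ceil(msg_len / self.chunk)
        return math.ceil(n_chunks / self.outer_k)  # number of blocks B

    def encode(self, payload: bytes) -> ReferencePool:
        msg = _wrap(payload)
        blocks = self._geometry(len(msg))
        self._blocks = blocks
        if blocks * self.outer_n > 256**self.index_bytes:
            raise ArgumentError("pool exceeds the index space")
        msg = msg.ljust(blocks * self.outer_k * self.chunk, b"\x00")

        # data chunk with global index g lives at block g % B, position g // B
        n_total = blocks * self.outer_n
        records: list[bytes | None] = [None] * n_total
        for b in range(blocks):
            data = [
                msg[(p * blocks + b) * self.chunk : (p * blocks + b + 1) * self.chunk]
                for p in range(self.outer_k)
            ]
            columns = [
                rs_encode([data[p][t] for p in range(self.outer_k)],
                          self.outer_n - self.outer_k)
                for t in range(self.chunk)
            ]
            for p in range(self.outer_n):
                g = p * blocks + b
                chunk = bytes(columns[t][p] for t in range(self.chunk))
                inner_data = g.to_bytes(self.index_bytes, "big") + chunk
                records[g] = rs_encode(inner_data, self.inner_n - self.inner_k)
        sequences = [bytes_to_dna(r) for r in records]  # type: ignore[arg-type]
        return ReferencePool(
            sequences=sequences, payload_size=len(payload), design_length=self.length
        )

    def decode(self, sequences, abundances=None, n_blocks: int | None = None,
               message_bytes: int | None = None) -> DecodeResult:
        """Decode a consensus sequence set.

        The block count is inferred from the largest plausible recovered
        index unless given explicitly.
        """
        if abundances is None:
            abundances = [1] * len(sequences)
        nsym_in = self.inner_n - self.inner_k
        diag = {"inner_corrected": 0, "inner_failed": 0, "erased": 0,
                "outer_recovered": 0}
        candidates: dict[int, tuple[int, bytes]] = {}
        for seq, ab in zip(sequences, abundances):
            word = _seq_bytes(seq, self.length)
            if rs_check(word, nsym_in):
                data = word[: self.inner_k]
            else:
                try:
                    data, ncorr = rs_decode(word, nsym_in)
                    diag["inner_corrected"] += 1
                except RSDecodeError:
                    diag["inner_failed"] += 1
                    continue
            g = int.from_bytes(data[: self.index_bytes], "big")
            if g not in candidates or ab > candidates[g][0]:
                candidates[g] = (ab, data[self.index_bytes :])

        if not candidates:
            return DecodeResult("failure", diagnostics=diag)
        if n_blocks is None:
            n_blocks = self._blocks or math.ceil(
                (max(candidates) + 1) / self.outer_n
            )
        blocks = n_blocks
        candidates = {g: v for g, v in candidates.items()
                      if g < blocks * self.outer_n}

        msg = bytearray(blocks * self.outer_k * self.chunk)
        failed_blocks = 0
        for b in range(blocks):
            present = {}
            for p in range(self.outer_n):
                g = p * blocks + b
                if g in candidates:
                    present[p] = candidates[g][1]
            erasures = [p for p in range(self.outer_n) if p not in present]
            diag["erased"] += len(erasures)
            if len(erasures) > self.erasure_bound:
                failed_blocks += 1
                continue
            data = np.zeros((self.outer_k, self.chunk), dtype=np.uint8)
            ok = True
            for t in range(self.chunk):
                word = [present[p][t] if p in present else 0
                        for p in range(self.outer_n)]
                try:
                    col, _ = rs_decode(word, self.outer_n - self.outer_k,
                                       erase_pos=erasures)
                except RSDecodeError:
                    ok = False
                    break
                data[:, t] = list(col[: self.outer_k])
            if not ok:
                failed_blocks += 1
                continue
            diag["outer_recovered"] += len(erasures)
            for p in range(self.outer_k):
                g = p * blocks + b
                msg[g * self.chunk : (g + 1) * self.chunk] = data[p].tobytes()
        diag["failed_blocks"] = failed_blocks
        payload = _unwrap(bytes(msg)) if failed_blocks == 0 else None
        if payload is None:
            return DecodeResult("failure", diagnostics=diag)
        return DecodeResult("success", payload=payload, diagnostics=diag)


def robust_soliton(k: int, c: float = 0.03, delta: float = 0.05) -> np.ndarray:
    """Robust soliton degree distribution over degrees 1..k."""
    if k < 1:
        raise ArgumentError("k must be positive")
    d = np.arange(1, k + 1, dtype=float)
    rho = np.zeros(k)
    rho[0] = 1.0 / k
    if k > 1:
        rho[1:] = 1.0 / (d[1:] * (d[1:] - 1.0))
    big_r = c * math.log(k / delta) * math.sqrt(k)
    tau = np.zeros(k)
    if big_r > 1.0:
        spike = min(k, max(1, int(round(k / big_r))))
        for i in range(1, spike):
            tau[i - 1] = big_r / (i * k)
        tau[spike - 1] = big_r * math.log(big_r / delta) / k
    mu = rho + tau
    return mu / mu.sum()


class FountainCodec:
    """LT fountain code with detection-only inner RS parity.

    Droplet ``d`` stores its own seed; degree and segment subset are
    regenerated from that seed at decode time.  Decoding peels
    degree-one droplets (belief propagation); if peeling stalls, the
    remaining equations are solved by GF(2) Gaussian elimination, which
    makes small-K instances decodable at the low droplet overheads of
    the high-rate presets (flagged in diagnostics).
    """

    name = "fountain"

    def __init__(
        self,
        length: int = 152,
        seed_bytes: int = 4,
        parity_bytes: int = 4,
        overhead: float = 0.10,
        soliton_c: float = 0.03,
        soliton_delta: float = 0.05,
    ):
        if length % 4:
            raise ArgumentError("sequence length must be a multiple of 4 nt")
        if overhead < 0:
            raise ArgumentError("droplet overhead must be non-negative")
        self.length = length
        self.seed_bytes = seed_bytes
        self.parity_bytes = parity_bytes
        self.segment = length // 4 - seed_bytes - parity_bytes
        if self.segment < 1:
            raise ArgumentError("sequence too short for seed + data + parity")
        self.overhead = overhead
        self.soliton_c = soliton_c
        self.soliton_delta = soliton_delta
        self._k: int | None = None  # set at encode; needed for decode

    def _droplet_subset(self, seed: int, k: int, cdf: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(seed)
        degree = int(np.searchsorted(cdf, rng.random(), side="right")) + 1
        return np.sort(rng.choice(k, size=min(degree, k), replace=False))

    def encode(self, payload: bytes) -> ReferencePool:
        msg = _wrap(payload)
        k = math.ceil(len(msg) / self.segment)
        self._k = k
        msg = msg.ljust(k * self.segment, b"\x00")
        segments = np.frombuffer(msg, dtype=np.uint8).reshape(k, self.segment)
        n_droplets = math.ceil(k * (1.0 + self.overhead))
        if n_droplets >= 256**self.seed_bytes:
            raise ArgumentError("droplet count exceeds the seed space")
        cdf = np.cumsum(robust_soliton(k, self.soliton_c, self.soliton_delta))
        sequences = []
        for d in range(n_droplets):
            subset = self._droplet_subset(d, k, cdf)
            data = np.bitwise_xor.reduce(segments[subset], axis=0).tobytes()
            record = rs_encode(
                d.to_bytes(self.seed_bytes, "big") + data, self.parity_bytes
            )
            sequences.append(bytes_to_dna(record))
        return ReferencePool(
            sequences=sequences, payload_size=len(payload), design_length=self.length
        )

    def decode(self, sequences, abundances=None, k: int | None = None) -> DecodeResult:
        k = k if k is not None else self._k
        if k is None:
            raise ArgumentError("segment count k unknown; encode first or pass k")
        diag = {"discarded": 0, "droplets": 0, "ge_used": False}
        n_droplets = math.ceil(k * (1.0 + self.overhead))
        cdf = np.cumsum(robust_soliton(k, self.soliton_c, self.soliton_delta))
        equations: dict[int, tuple[set[int], np.ndarray]] = {}
        for seq in sequences:
            record = _seq_bytes(seq, self.length)
            if not rs_check(record, self.parity_bytes):
                diag["discarded"] += 1  # detection only: discard, never correct
                continue
            d = int.from_bytes(record[: self.seed_bytes], "big")
            if d >= n_droplets or d in equations:
                continue
            data = np.frombuffer(
                record[self.seed_bytes : self.seed_bytes + self.segment],
                dtype=np.uint8,
            ).copy()
            subset = self._droplet_subset(d, k, cdf)
            equations[d] = (set(subset.tolist()), data)
        diag["droplets"] = len(equations)

        solved: dict[int, np.ndarray] = {}
        # belief-propagation peeling
        queue = [d for d, (s, _) in equations.items() if len(s) == 1]
        while queue:
            d = queue.pop()
            if d not in equations:
                continue
            subset, data = equations.pop(d)
            if len(subset) != 1:
                continue
            seg = subset.pop()
            if seg in solved:
                continue
            solved[seg] = data
            for d2, (s2, data2) in equations.items():
                if seg in s2:
                    s2.discard(seg)
                    data2 ^= data
                    if len(s2) == 1:
                        queue.append(d2)

        if len(solved) < k and equations:
            diag["ge_used"] = True
            unknowns = sorted(set(range(k)) - set(solved))
            col = {seg: j for j, seg in enumerate(unknowns)}
            rows, rhs = [], []
            for s2, data2 in equations.values():
                row = np.zeros(len(unknowns), dtype=bool)
                for seg in s2:
                    row[col[seg]] = True
                rows.append(row)
                rhs.append(data2.copy())
            if rows:
                a = np.array(rows)
                b = np.array(rhs)
                pivot_of: dict[int, int] = {}
                r = 0
                for j in range(len(unknowns)):
                    pivots = np.flatnonzero(a[r:, j]) + r
                    if pivots.size == 0:
                        continue
                    p = pivots[0]
                    a[[r, p]] = a[[p, r]]
                    b[[r, p]] = b[[p, r]]
                    hit = np.flatnonzero(a[:, j])
                    hit = hit[hit != r]
                    a[hit] ^= a[r]
                    b[hit] ^= b[r]
                    pivot_of[j] = r
                    r += 1
                if len(pivot_of) == len(unknowns):
                    for seg, j in col.items():
                        solved[seg] = b[pivot_of[j]]

        if len(solved) < k:
            diag["unresolved"] = k - len(solved)
            return DecodeResult("failure", diagnostics=diag)
        msg = b"".join(solved[i].tobytes() for i in range(k))
        payload = _unwrap(msg)
        if payload is None:
            return DecodeResult("failure", diagnostics=diag)
        return DecodeResult("success", payload=payload, diagnostics=diag)


class ExternalCodecAdapter:
    """Run an external codec through subprocess encode/decode commands.

    Commands are shell-style templates: the encode command receives
    ``{payload}`` (input file) and ``{fasta}`` (output pool), the decode
    command ``{fasta}`` (input sequences) and ``{payload}`` (output
    file).  A nonzero exit status, a missing output file, or exceeding
    the time limit yields a decode failure, never an exception.
    """

    name = "external"

    def __init__(self, encode_cmd: str, decode_cmd: str, timeout_s: float = 3600.0):
        self.encode_cmd = encode_cmd
        self.decode_cmd = decode_cmd
        self.timeout_s = timeout_s

    def encode(self, payload: bytes) -> ReferencePool:
        from . import seqio

        with tempfile.TemporaryDirectory() as tmp:
            p_in = Path(tmp) / "payload.bin"
            f_out = Path(tmp) / "pool.fasta"
            p_in.write_bytes(payload)
            cmd = self.encode_cmd.format(payload=p_in, fasta=f_out)
            subprocess.run(
                shlex.split(cmd), check=True, timeout=self.timeout_s,
                capture_output=True,
            )
            pool = seqio.read_fasta(f_out)
            pool.payload_size = len(payload)
            return pool

    def decode(self, sequences, abundances=None) -> DecodeResult:
        from .core import ReferencePool as _Pool
        from . import seqio

        with tempfile.TemporaryDirectory() as tmp:
            f_in = Path(tmp) / "consensus.fasta"
            p_out = Path(tmp) / "decoded.bin"
            seqio.write_fasta(_Pool(sequences=list(sequences)), f_in)
            cmd = self.decode_cmd.format(fasta=f_in, payload=p_out)
            try:
                proc = subprocess.run(
                    shlex.split(cmd), timeout=self.timeout_s, capture_output=True
                )
            except subprocess.TimeoutExpired:
                return DecodeResult("failure", diagnostics={"timeout": True})
            if proc.returncode != 0 or not p_out.exists():
                return DecodeResult(
                    "failure", diagnostics={"returncode": proc.returncode}
                )
            return DecodeResult("success", payload=p_out.read_bytes())
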