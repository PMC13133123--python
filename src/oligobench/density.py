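"""Storage-density accounting and read-set error/coverage profiling.

Storage density converts a codec's code rate and the physical redundancy
kept during storage into payload bytes per gram of DNA:

    D = ρ · N_A / (R · M · 8 · 10¹⁸)   [EB g⁻¹, decimal exabytes]

with ρ the code rate in bit/nt, R the mean physical oligo copies per
sequence, M the molecular weight per base pair (default 662 g mol⁻¹
bp⁻¹ for double-stranded DNA) and N_A Avogadro's number.  At the
biophysical limit (ρ = 2 bit/nt, R = 1) this gives ≈ 227 EB g⁻¹.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from .core import ArgumentError, ReadSet, ReferencePool

AVOGADRO = 6.022e23  # mol^-1
MW_DSDNA = 662.0  # g mol^-1 bp^-1
_EB = 1e18  # decimal exabyte in bytes

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class DensityReport:
    code_rate: float  # bit nt^-1
    redundancy: float  # physical oligo copies per sequence
    molecular_weight: float  # g mol^-1 bp^-1
    density_eb_per_g: float
    basis: str = "payload_only"


def storage_density(
    code_rate: float,
    redundancy: float,
    molecular_weight: float = MW_DSDNA,
    basis: str = "payload_only",
    payload_length: int | None = None,
    total_length: int | None = None,
) -> DensityReport:
    """Payload storage density in decimal EB per gram of DNA.

    The ``with_adapters`` basis scales by payload/total sequence length
    (both must be given), accounting for adapter overhead mass.
    """
    if code_rate <= 0 or redundancy <= 0 or molecular_weight <= 0:
        raise ArgumentError("code_rate, redundancy and molecular weight must be > 0")
    density = code_rate * AVOGADRO / (redundancy * molecular_weight * 8.0 * _EB)
    if basis == "with_adapters":
        if not payload_length or not total_length:
            raise ArgumentError("with_adapters basis needs payload and total lengths")
        density *= payload_length / total_length
    elif basis != "payload_only":
        raise ArgumentError(f"unknown basis {basis!r}")
    return DensityReport(
        code_rate=code_rate,
        redundancy=redundancy,
        molecular_weight=molecular_weight,
        density_eb_per_g=density,
        basis=basis,
    )


def redundancy_from_mass(
    n_sequences: int,
    length_bp: int,
    mass_ng: float,
    molecular_weight: float = MW_DSDNA,
) -> float:
    """Physical redundancy implied by a DNA mass (copies per sequence)."""
    if n_sequences <= 0 or length_bp <= 0 or mass_ng <= 0 or molecular_weight <= 0:
        raise ArgumentError("all arguments must be positive")
    return mass_ng * 1e-9 * AVOGADRO / (n_sequences * length_bp * molecular_weight)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-type mean error rates, dropout, and coverage dispersion."""

    sub_rate: float  # nt^-1
    del_rate: float
    ins_rate: float
    dropout: float  # fraction of references with zero reads
    coverage_cv: float  # std/mean of per-reference read counts

    @property
    def overall_rate(self) -> float:
        return self.sub_rate + self.del_rate + self.ins_rate


def analyze_error_rates(readset: ReadSet, references: ReferencePool) -> ErrorProfile:
    """Recover channel error statistics from reads with known origins.

    Each read is globally aligned to its origin reference (minimal
    unit-cost alignment); substitutions, deletions and insertions are
    counted from the alignment path and normalized by the total aligned
    reference length.  Reads without an origin are assigned to the
    nearest reference by Levenshtein distance.
    """
    if not len(readset):
        raise ArgumentError("readset must be non-empty")
    if not len(references):
        raise ArgumentError("references must be non-empty")
    n_ref = len(references)
    counts = np.zeros(n_ref, dtype=np.int64)
    subs = dels = inss = 0
    ref_nt = 0
    for read in readset.reads:
        origin = read.origin
        if origin is None:
            dists = [
                edlib.align(read.sequence, ref, mode="NW", task="distance")[
                    "editDistance"
                ]
                for ref in references.sequences
            ]
            origin = int(np.argmin(dists))
        ref = references.sequences[origin]
        counts[origin] += read.abundance
        result = edlib.align(read.sequence, ref, mode="NW", task="path")
        for length_s, op in _CIGAR_RE.findall(result["cigar"]):
            length = int(length_s) * read.abundance
            if op == "X":
                subs += length
            elif op == "D":  # read is missing reference bases
                dels += length
            elif op == "I":  # read carries extra bases
                inss += length
        ref_nt += len(ref) * read.abundance
    mean = counts.mean()
    cv = float(counts.std() / mean) if mean > 0 else float("nan")
    return ErrorProfile(
        sub_rate=subs / ref_nt,
        del_rate=dels / ref_nt,
        ins_rate=inss / ref_nt,
        dropout=float((counts == 0).mean()),
        coverage_cv=cv,
    )
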