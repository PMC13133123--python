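"""Read clustering, consensus calling, and clustering evaluation metrics.

Two clusterers are provided: *naïve* clustering collapses reads to their
unique sequences sorted by abundance (no alignment), and *LSH*
clustering groups reads greedily by MinHash-estimated k-mer Jaccard
similarity.  Consensus calling star-aligns each cluster to its
highest-abundance member and takes a per-column plurality vote.
Clustering quality is scored against the reference pool with the three
standard metrics — sensitivity, accuracy, specificity — after assigning
each consensus sequence to its nearest reference by Levenshtein
distance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .core import ArgumentError, ReadSet, ReferencePool, derive_rng, pad_trim

PAD_BASE = "A"

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def levenshtein_similarity(a: str, b: str) -> float:
    """1 − d/max(|a|, |b|); 1.0 for identical strings."""
    if not a and not b:
        return 1.0
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


@dataclass
class Cluster:
    """A group of reads presumed to share one reference origin."""

    members: list[tuple[str, int]]  # (sequence, multiplicity)
    representative: str

    @property
    def size(self) -> int:
        return sum(m for _, m in self.members)


@dataclass
class ConsensusSet:
    """Consensus sequences padded/trimmed to the design length."""

    sequences: list[str]
    sizes: list[int]
    design_length: int

    def __len__(self) -> int:
        return len(self.sequences)


def _sorted_unique(readset: ReadSet) -> list[tuple[str, int]]:
    counts = readset.unique_counts()
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def naive_cluster(readset: ReadSet, design_length: int | None = None) -> ConsensusSet:
    """Unique read sequences ordered by descending abundance.

    No alignment is performed; each unique sequence is padded or trimmed
    to the design length.  Ties in abundance break lexicographically, so
    the output is invariant under read permutation.
    """
    if not len(readset):
        raise ArgumentError("readset must be non-empty")
    length = design_length or len(readset.reads[0].sequence)
    items = _sorted_unique(readset)
    return ConsensusSet(
        sequences=[pad_trim(seq, length, PAD_BASE) for seq, _ in items],
        sizes=[count for _, count in items],
        design_length=length,
    )


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    lut[ord("C")] = 1
    lut[ord("G")] = 2
    lut[ord("T")] = 3
    vals = lut[codes]
    kmers = np.zeros(len(seq) - k + 1, dtype=np.int64)
    for i in range(k):
        kmers = (kmers << 2) | vals[i : len(seq) - k + 1 + i]
    return np.unique(kmers)


_MERSENNE = (1 << 61) - 1


def minhash_signature(
    seq: str, k: int, coeffs: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """MinHash signature over the k-mer set (h independent hash functions)."""
    kmers = _kmer_codes(seq, k)
    a, b = coeffs
    hashed = (a[:, None] * kmers[None, :] + b[:, None]) % _MERSENNE
    return hashed.min(axis=1)


def lsh_cluster(
    readset: ReadSet,
    k: int = 8,
    num_hashes: int = 64,
    tau: float = 0.15,
    seed: int = 0,
) -> list[Cluster]:
    """Greedy single-pass MinHash clustering.

    Unique reads are processed in descending abundance order (ties
    lexicographic); each read joins the earliest-founded cluster whose
    representative signature agrees on a fraction ≥ tau of hash slots
    (the MinHash estimate of k-mer Jaccard similarity), else founds a
    new cluster.  Deterministic per seed.
    """
    if not len(readset):
        raise ArgumentError("readset must be non-empty")
    items = _sorted_unique(readset)
    min_len = min(len(seq) for seq, _ in items)
    if k >= min_len:
        raise ArgumentError(f"k-mer size {k} must be below read length {min_len}")
    rng = derive_rng(seed, "lsh")
    a = rng.integers(1, _MERSENNE, size=num_hashes, dtype=np.int64)
    b = rng.integers(0, _MERSENNE, size=num_hashes, dtype=np.int64)

    clusters: list[Cluster] = []
    signatures = np.empty((0, num_hashes), dtype=np.int64)
    for seq, count in items:
        sig = minhash_signature(seq, k, (a, b))
        if len(clusters):
            agreement = (signatures == sig[None, :]).mean(axis=1)
            hits = np.flatnonzero(agreement >= tau)
        else:
            hits = np.empty(0, dtype=np.int64)
        if hits.size:
            clusters[int(hits[0])].members.append((seq, count))
        else:
            clusters.append(Cluster(members=[(seq, count)], representative=seq))
            signatures = np.vstack([signatures, sig[None, :]])
    return clusters


def _vote(counts: dict[str, int]) -> str:
    """Plurality winner; ties break A<C<G<T, then non-gap over gap."""
    best_symbol, best_count = "-", -1
    for symbol in "ACGT-":
        c = counts.get(symbol, 0)
        if c > best_count:
            best_symbol, best_count = symbol, c
    return best_symbol


def call_consensus(cluster: Cluster, design_length: int) -> str:
    """Star alignment against the highest-abundance member, column vote.

    Every member is globally aligned to the cluster representative
    (exact bit-parallel edit-distance alignment); per-column plurality
    vote over aligned symbols including the gap symbol; gap-majority
    columns are deleted; the result is padded/trimmed to the design
    length.
    """
    if not cluster.members:
        raise ArgumentError("cluster must be non-empty")
    rep = max(cluster.members, key=lambda sc: (sc[1], sc[0]))[0]
    if len(cluster.members) == 1:
        return pad_trim(rep, design_length, PAD_BASE)

    n_rep = len(rep)
    total = cluster.size
    # votes per representative column, and per insertion slot (col, offset)
    col_votes: list[dict[str, int]] = [dict() for _ in range(n_rep)]
    ins_votes: dict[tuple[int, int], dict[str, int]] = {}

    for seq, mult in cluster.members:
        if seq == rep:
            for i, base in enumerate(rep):
                col_votes[i][base] = col_votes[i].get(base, 0) + mult
            continue
        result = edlib.align(seq, rep, mode="NW", task="path")
        pos_q = pos_t = 0
        for length_s, op in _CIGAR_RE.findall(result["cigar"]):
            length = int(length_s)
            if op in "=XM":
                for j in range(length):
                    base = seq[pos_q + j]
                    votes = col_votes[pos_t + j]
                    votes[base] = votes.get(base, 0) + mult
                pos_q += length
                pos_t += length
            elif op == "D":  # gap in the read at these rep columns
                for j in range(length):
                    votes = col_votes[pos_t + j]
                    votes["-"] = votes.get("-", 0) + mult
                pos_t += length
            else:  # op == "I": inserted bases before rep column pos_t
                for j in range(length):
                    votes = ins_votes.setdefault((pos_t, j), {})
                    base = seq[pos_q + j]
                    votes[base] = votes.get(base, 0) + mult
                pos_q += length

    out: list[str] = []
    for col in range(n_rep + 1):
        offset = 0
        while (col, offset) in ins_votes:
            votes = dict(ins_votes[(col, offset)])
            # members without an insertion here implicitly vote gap
            votes["-"] = votes.get("-", 0) + total - sum(votes.values())
            winner = _vote(votes)
            if winner != "-":
                out.append(winner)
            offset += 1
        if col < n_rep:
            winner = _vote(col_votes[col])
            if winner != "-":
                out.append(winner)
    return pad_trim("".join(out), design_length, PAD_BASE)


def consensus_set(clusters: list[Cluster], design_length: int) -> ConsensusSet:
    """Call a consensus for every cluster."""
    return ConsensusSet(
        sequences=[call_consensus(c, design_length) for c in clusters],
        sizes=[c.size for c in clusters],
        design_length=design_length,
    )


def cluster_and_consensus(
    readset: ReadSet,
    design_length: int,
    method: str = "lsh",
    **kwargs,
) -> ConsensusSet:
    """Convenience pipeline stage: cluster reads, then call consensi."""
    if method == "naive":
        return naive_cluster(readset, design_length)
    if method == "lsh":
        clusters = lsh_cluster(readset, **kwargs)
        return consensus_set(clusters, design_length)
    raise ArgumentError(f"unknown clustering method {method!r}")


@dataclass
class ClusterMetrics:
    """The three clustering quality metrics plus the assignment map."""

    sensitivity: float
    accuracy: float
    specificity: float
    assignment: list[int] = field(default_factory=list)


def evaluate_clustering(
    consensus: ConsensusSet, references: ReferencePool
) -> ClusterMetrics:
    """Score a consensus set against the reference pool.

    Each consensus sequence is assigned to the reference minimizing
    Levenshtein distance (ties to the lowest reference index).
    Sensitivity is the fraction of references with at least one assigned
    consensus; specificity divides that same numerator by the total
    consensus count; accuracy is the mean, over references, of the
    Levenshtein similarity of each reference's closest consensus.
    """
    if not len(consensus) or not len(references):
        raise ArgumentError("consensus set and references must be non-empty")
    n_cons, n_ref = len(consensus), len(references)
    dist = np.empty((n_cons, n_ref), dtype=np.int64)
    for i, cons in enumerate(consensus.sequences):
        for j, ref in enumerate(references.sequences):
            dist[i, j] = levenshtein(cons, ref)
    assignment = dist.argmin(axis=1)  # argmin takes the lowest index on ties
    covered = np.zeros(n_ref, dtype=bool)
    covered[assignment] = True
    sensitivity = covered.mean()
    specificity = covered.sum() / n_cons

    sims = np.empty(n_ref)
    for j, ref in enumerate(references.sequences):
        i = int(dist[:, j].argmin())
        length = max(len(consensus.sequences[i]), len(ref))
        sims[j] = 1.0 - dist[i, j] / length
    return ClusterMetrics(
        sensitivity=float(sensitivity),
        accuracy=float(sims.mean()),
        specificity=float(specificity),
        assignment=assignment.tolist(),
    )
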