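"""Clustering, consensus calling, and the clustering quality metrics."""

import numpy as np
import pytest

from oligobench import (
    ArgumentError,
    BasicScenarioParams,
    ErrorSpec,
    Read,
    ReadSet,
    ReferencePool,
    cluster_and_consensus,
    evaluate_clustering,
    lsh_cluster,
    naive_cluster,
    run_basic_scenario,
)
from oligobench.cluster import (
    Cluster,
    ConsensusSet,
    call_consensus,
    consensus_set,
    minhash_signature,
)


def _readset(seq_counts: dict[str, int], pool_size: int = 1) -> ReadSet:
    reads = [Read(sequence=s, abundance=c) for s, c in seq_counts.items()]
    return ReadSet(reads=reads, pool_size=pool_size)


def _python_levenshtein(a: str, b: str) -> int:
    """Reference DP implementation, independent of the library path."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestNaiveCluster:
    def test_noiseless_reads_collapse_to_references(self, small_pool):
        params = BasicScenarioParams(error=ErrorSpec(0.0), copies=30, seed=1)
        reads = run_basic_scenario(small_pool, params)
        cons = naive_cluster(reads, small_pool.design_length)
        assert sorted(cons.sequences) == sorted(small_pool.sequences)

    def test_ordering_by_abundance_then_lexicographic(self):
        cons = naive_cluster(_readset({"AAAT": 1, "AAAA": 3}), 4)
        assert cons.sequences == ["AAAA", "AAAT"]
        assert cons.sizes == [3, 1]

    def test_pad_and_trim_to_design_length(self):
        cons = naive_cluster(_readset({"ACGTAC": 1, "ACG": 1}), 4)
        assert cons.sequences == ["ACG" + "A", "ACGT"]

    def test_invariant_under_read_permutation(self):
        reads = [Read(sequence=s) for s in ["TTTT", "AAAA", "TTTT", "CCCC"]]
        a = naive_cluster(ReadSet(reads=reads, pool_size=2), 4)
        b = naive_cluster(ReadSet(reads=reads[::-1], pool_size=2), 4)
        assert a.sequences == b.sequences and a.sizes == b.sizes

    def test_empty_readset_rejected(self):
        with pytest.raises(ArgumentError):
            naive_cluster(ReadSet(reads=[], pool_size=1), 4)


class TestLshCluster:
    def test_identical_reads_form_one_cluster(self):
        rs = _readset({"ACGTACGTACGTACGT": 2})
        clusters = lsh_cluster(rs, k=4)
        assert len(clusters) == 1
        assert clusters[0].size == 2

    def test_rejects_kmer_size_at_or_above_read_length(self):
        with pytest.raises(ArgumentError):
            lsh_cluster(_readset({"ACGT": 1}), k=4)

    def test_cluster_count_and_purity_against_origin_oracle(self):
        # 30 copies per reference at r=0.02: cluster count within
        # [N, 1.2 N] and no cluster mixing two origins
        rng = np.random.default_rng(7)
        n = 50
        seqs = ["".join(rng.choice(list("ACGT"), 150)) for _ in range(n)]
        pool = ReferencePool(sequences=seqs)
        params = BasicScenarioParams(error=ErrorSpec(0.02), copies=30, seed=2)
        reads = run_basic_scenario(pool, params)
        clusters = lsh_cluster(reads, seed=1)
        assert n <= len(clusters) <= 1.2 * n
        origin_of: dict[str, set] = {}
        for read in reads.reads:
            origin_of.setdefault(read.sequence, set()).add(read.origin)
        for cluster in clusters:
            origins = set()
            for seq, _ in cluster.members:
                origins |= origin_of[seq]
            assert len(origins) == 1

    def test_tau_one_degenerates_toward_unique_signatures(self):
        rng = np.random.default_rng(8)
        seqs = {"".join(rng.choice(list("ACGT"), 60)): 1 for _ in range(30)}
        rs = _readset(seqs)
        clusters = lsh_cluster(rs, k=8, tau=1.0, seed=3)
        # members of any cluster must then share an identical signature
        from oligobench.core import derive_rng
        from oligobench.cluster import _MERSENNE

        h_rng = derive_rng(3, "lsh")
        a = h_rng.integers(1, _MERSENNE, size=64, dtype=np.int64)
        b = h_rng.integers(0, _MERSENNE, size=64, dtype=np.int64)
        for cluster in clusters:
            sigs = {
                tuple(minhash_signature(s, 8, (a, b)).tolist())
                for s, _ in cluster.members
            }
            assert len(sigs) == 1

    def test_deterministic_per_seed_and_input(self):
        rng = np.random.default_rng(9)
        pool = ReferencePool(
            sequences=["".join(rng.choice(list("ACGT"), 100)) for _ in range(20)]
        )
        params = BasicScenarioParams(error=ErrorSpec(0.03), copies=10, seed=4)
        reads = run_basic_scenario(pool, params)
        a = lsh_cluster(reads, seed=5)
        b = lsh_cluster(reads, seed=5)
        assert [c.members for c in a] == [c.members for c in b]


class TestCallConsensus:
    def test_unanimous_cluster_returns_the_read(self):
        cluster = Cluster(members=[("ACGTACGT", 5)], representative="ACGTACGT")
        assert call_consensus(cluster, 8) == "ACGTACGT"

    def test_majority_removes_single_substitution(self):
        good = "ACGTACGTACGTACGTACGT"
        bad = good[:10] + "T" + good[11:]
        cluster = Cluster(members=[(good, 29), (bad, 1)], representative=good)
        assert call_consensus(cluster, len(good)) == good

    def test_majority_removes_indels(self):
        good = "ACGTTGCAACGTACGTGGCA"
        with_del = good[:5] + good[6:]
        with_ins = good[:12] + "T" + good[12:]
        cluster = Cluster(
            members=[(good, 3), (with_del, 1), (with_ins, 1)],
            representative=good,
        )
        assert call_consensus(cluster, len(good)) == good

    def test_consensus_recovers_references_at_4pct_error(self):
        # 30 independently corrupted copies at r=0.04: the consensus
        # equals the true reference for >= 99% of N=100 sequences
        rng = np.random.default_rng(10)
        n = 100
        seqs = ["".join(rng.choice(list("ACGT"), 150)) for _ in range(n)]
        pool = ReferencePool(sequences=seqs)
        params = BasicScenarioParams(error=ErrorSpec(0.04), copies=30, seed=6)
        reads = run_basic_scenario(pool, params)
        by_origin: dict[int, dict[str, int]] = {}
        for read in reads.reads:
            d = by_origin.setdefault(read.origin, {})
            d[read.sequence] = d.get(read.sequence, 0) + read.abundance
        correct = 0
        for origin, counts in by_origin.items():
            members = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            cluster = Cluster(members=members, representative=members[0][0])
            if call_consensus(cluster, 150) == pool.sequences[origin]:
                correct += 1
        assert correct >= 0.99 * n


class TestEvaluateClustering:
    def test_perfect_recovery_scores_ones(self, small_pool):
        cons = ConsensusSet(
            sequences=list(small_pool.sequences),
            sizes=[1] * len(small_pool),
            design_length=small_pool.design_length,
        )
        m = evaluate_clustering(cons, small_pool)
        assert m.sensitivity == 1.0
        assert m.accuracy == 1.0
        assert m.specificity == 1.0

    def test_two_reference_worked_example(self):
        refs = ReferencePool(sequences=["ACGT", "TTTT"])
        cons = ConsensusSet(sequences=["ACCT"], sizes=[1], design_length=4)
        m = evaluate_clustering(cons, refs)
        # ACCT is assigned to ACGT (distance 1 vs 3): sensitivity 1/2;
        # accuracy averages each reference's closest-consensus similarity:
        # (0.75 + 0.25) / 2
        assert m.sensitivity == pytest.approx(0.5)
        assert m.accuracy == pytest.approx(0.5)
        assert m.specificity == pytest.approx(1.0)
        assert m.assignment == [0]

    def test_redundant_consensus_counts_hit_specificity(self):
        rng = np.random.default_rng(11)
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(10)]
        refs = ReferencePool(sequences=seqs)
        cons = ConsensusSet(sequences=[seqs[0]] * 20, sizes=[1] * 20,
                            design_length=30)
        m = evaluate_clustering(cons, refs)
        assert m.sensitivity == pytest.approx(0.1)
        assert m.specificity == pytest.approx(0.05)

    def test_matches_brute_force_distance_oracle(self):
        rng = np.random.default_rng(12)
        refs = ReferencePool(
            sequences=["".join(rng.choice(list("ACGT"), 25)) for _ in range(8)]
        )
        cons_seqs = ["".join(rng.choice(list("ACGT"), 25)) for _ in range(12)]
        cons = ConsensusSet(sequences=cons_seqs, sizes=[1] * 12, design_length=25)
        m = evaluate_clustering(cons, refs)
        dist = np.array(
            [[_python_levenshtein(c, r) for r in refs.sequences]
             for c in cons_seqs]
        )
        assignment = dist.argmin(axis=1)
        covered = set(assignment.tolist())
        assert m.assignment == assignment.tolist()
        assert m.sensitivity == pytest.approx(len(covered) / 8)
        assert m.specificity == pytest.approx(len(covered) / 12)
        sims = [
            1.0 - dist[:, j].min() / 25 for j in range(8)
        ]
        assert m.accuracy == pytest.approx(np.mean(sims))


class TestPipelineProperties:
    def test_error_free_reads_reproduce_pool_through_any_clusterer(
        self, small_pool
    ):
        params = BasicScenarioParams(error=ErrorSpec(0.0), copies=10, seed=13)
        reads = run_basic_scenario(small_pool, params)
        for method in ("naive", "lsh"):
            cons = cluster_and_consensus(
                reads, small_pool.design_length, method=method
            )
            m = evaluate_clustering(cons, small_pool)
            assert m.sensitivity == 1.0
            assert m.accuracy == 1.0
            assert m.specificity == 1.0

    def test_consensus_accuracy_improves_with_copies(self):
        # consensus error is monotonically non-increasing in the number
        # of copies at fixed error rate (checked via the accuracy metric)
        rng = np.random.default_rng(14)
        pool = ReferencePool(
            sequences=["".join(rng.choice(list("ACGT"), 120)) for _ in range(40)]
        )
        accuracies = []
        for copies in (3, 30):
            vals = []
            for seed in range(3):
                params = BasicScenarioParams(
                    error=ErrorSpec(0.04), copies=copies, seed=seed
                )
                reads = run_basic_scenario(pool, params)
                cons = cluster_and_consensus(reads, 120, method="lsh", seed=1)
                vals.append(evaluate_clustering(cons, pool).accuracy)
            accuracies.append(np.mean(vals))
        assert accuracies[1] >= accuracies[0]
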