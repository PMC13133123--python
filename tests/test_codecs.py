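"""Codec round-trips, correction bounds, and the external adapter."""

import sys

import numpy as np
import pytest

from oligobench import (
    ArgumentError,
    BaselineCodec,
    ExternalCodecAdapter,
    FountainCodec,
    RSInnerOuterCodec,
    generate_payload,
    get_codec,
)
from oligobench.codecs import robust_soliton

ALL_PRESETS = [
    ("baseline", "max"),
    ("rs", "0.50"),
    ("rs", "1.00"),
    ("rs", "1.50"),
    ("fountain", "0.50"),
    ("fountain", "1.00"),
    ("fountain", "1.50"),
]


@pytest.mark.parametrize("name,rate", ALL_PRESETS)
def test_noiseless_round_trip(name, rate, payload_904):
    codec = get_codec(name, rate)
    pool = codec.encode(payload_904)
    result = codec.decode(pool.sequences)
    assert result.success
    assert result.payload == payload_904


@pytest.mark.parametrize("name,rate,target", [
    ("rs", "0.50", 0.50), ("rs", "1.00", 1.00), ("rs", "1.50", 1.50),
    ("fountain", "0.50", 0.50), ("fountain", "1.00", 1.00),
    ("fountain", "1.50", 1.50),
])
def test_achieved_rate_within_5pct_on_standard_payload(name, rate, target):
    payload = generate_payload(19456, seed=1).data
    pool = get_codec(name, rate).encode(payload)
    assert abs(pool.code_rate - target) / target < 0.05


class TestBaseline:
    def test_minimal_round_trip(self):
        codec = BaselineCodec(length=8, index_bytes=1)
        pool = codec.encode(b"\x00")
        assert codec.decode(pool.sequences).payload == b"\x00"

    def test_missing_sequence_fails(self, payload_904):
        codec = get_codec("baseline")
        pool = codec.encode(payload_904)
        result = codec.decode(pool.sequences[1:])
        assert not result.success
        assert result.diagnostics["missing"] == 1

    def test_single_substitution_fails_by_byte_comparison(self, payload_904):
        codec = get_codec("baseline")
        pool = codec.encode(payload_904)
        seqs = list(pool.sequences)
        # flip one base in the payload region of one sequence
        s = seqs[3]
        pos = 40
        other = "C" if s[pos] == "A" else "A"
        seqs[3] = s[:pos] + other + s[pos + 1:]
        result = codec.decode(seqs)
        assert not result.success

    def test_payload_too_large_for_index(self):
        codec = BaselineCodec(length=8, index_bytes=1)
        with pytest.raises(ArgumentError):
            codec.encode(bytes(10_000))


class TestRSInnerOuter:
    def test_dropout_exactly_at_erasure_bound(self, rs_pool, payload_904):
        codec, pool = rs_pool
        blocks = codec._blocks
        bound = codec.erasure_bound
        # drop `bound` sequences of block 0 -> success
        dropped = {p * blocks for p in range(bound)}
        seqs = [s for g, s in enumerate(pool.sequences) if g not in dropped]
        result = codec.decode(seqs)
        assert result.success and result.payload == payload_904
        assert result.diagnostics["outer_recovered"] >= bound
        # one more from the same block -> failure
        dropped = {p * blocks for p in range(bound + 1)}
        seqs = [s for g, s in enumerate(pool.sequences) if g not in dropped]
        assert not codec.decode(seqs).success

    def test_inner_code_corrects_within_radius(self, rs_pool, payload_904):
        codec, pool = rs_pool
        rng = np.random.default_rng(0)
        seqs = list(pool.sequences)
        # corrupt `inner_radius` symbols (2 nt-aligned byte flips) in one
        # sequence: inner decode must fix them all
        seq = list(seqs[0])
        for sym in rng.choice(codec.inner_n, codec.inner_radius, replace=False):
            pos = int(sym) * 4
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        seqs[0] = "".join(seq)
        result = codec.decode(seqs)
        assert result.success and result.payload == payload_904
        assert result.diagnostics["inner_corrected"] == 1

    def test_duplicate_indices_resolved_by_abundance(self, rs_pool, payload_904):
        codec, pool = rs_pool
        junk = "A" * codec.length
        # present a junk duplicate of every index with lower abundance
        seqs = list(pool.sequences) + [junk]
        abundances = [5] * len(pool.sequences) + [1]
        result = codec.decode(seqs, abundances=abundances)
        assert result.success and result.payload == payload_904

    def test_rejects_field_bound_violations(self):
        with pytest.raises(ArgumentError):
            RSInnerOuterCodec(length=152, inner_k=40, outer_n=28, outer_k=19)
        with pytest.raises(ArgumentError):
            RSInnerOuterCodec(length=152, inner_k=30, outer_n=300, outer_k=19)


class TestFountain:
    def test_small_instance_with_all_droplets(self):
        codec = FountainCodec(length=152, overhead=0.10)
        payload = generate_payload(3000, seed=2).data  # K = 101 segments
        pool = codec.encode(payload)
        result = codec.decode(pool.sequences)
        assert result.success and result.payload == payload

    def test_tolerates_60pct_droplet_loss_at_low_rate(self):
        # rate-0.50-equivalent droplet redundancy: success in >= 9/10 trials
        payload = generate_payload(4096, seed=3).data
        successes = 0
        for seed in range(10):
            codec = get_codec("fountain", "0.50")
            pool = codec.encode(payload)
            rng = np.random.default_rng(seed)
            keep = rng.random(len(pool)) > 0.60
            seqs = [s for s, k in zip(pool.sequences, keep) if k]
            result = codec.decode(seqs)
            if result.success:
                assert result.payload == payload
                successes += 1
        assert successes >= 9

    def test_corrupted_droplets_are_discarded_not_used(self):
        codec = get_codec("fountain", "1.00")
        payload = generate_payload(904, seed=4).data
        pool = codec.encode(payload)
        seqs = list(pool.sequences)
        seqs[0] = "T" * codec.length  # fails the detection parity
        result = codec.decode(seqs)
        assert result.diagnostics["discarded"] >= 1
        if result.success:
            assert result.payload == payload

    def test_never_wrong_success_under_heavy_corruption(self):
        codec = get_codec("fountain", "1.00")
        payload = generate_payload(904, seed=5).data
        pool = codec.encode(payload)
        rng = np.random.default_rng(6)
        for _ in range(5):
            seqs = [
                "".join(rng.choice(list("ACGT"), codec.length))
                for _ in range(len(pool))
            ]
            result = codec.decode(seqs)
            assert not (result.success and result.payload != payload)

    def test_rejects_negative_overhead(self):
        with pytest.raises(ArgumentError):
            FountainCodec(overhead=-0.1)

    def test_robust_soliton_normalizes(self):
        for k in (1, 2, 10, 500):
            mu = robust_soliton(k)
            assert mu.shape == (k,)
            assert mu.sum() == pytest.approx(1.0)
            assert (mu >= 0).all()


class TestExternalAdapter:
    def _roundtrip_script(self) -> tuple[str, str]:
        # a trivial external codec: payload bytes <-> one FASTA record
        # per 16-byte chunk, hex-encoded as DNA via 2-bit packing
        encode = (
            f"{sys.executable} -c \"from oligobench.codecs import BaselineCodec; "
            "from oligobench.seqio import write_fasta; "
            "data = open('{payload}','rb').read(); "
            "write_fasta(BaselineCodec().encode(data), '{fasta}')\""
        )
        decode = (
            f"{sys.executable} -c \"import sys; "
            "from oligobench.codecs import BaselineCodec; "
            "from oligobench.seqio import read_fasta; "
            "pool = read_fasta('{fasta}'); "
            "res = BaselineCodec().decode(pool.sequences); "
            "sys.exit(1) if not res.success else "
            "open('{payload}','wb').write(res.payload)\""
        )
        return encode, decode

    def test_self_adapter_matches_in_process_codec(self, payload_904):
        encode_cmd, decode_cmd = self._roundtrip_script()
        adapter = ExternalCodecAdapter(encode_cmd, decode_cmd, timeout_s=60)
        pool = adapter.encode(payload_904)
        reference = BaselineCodec().encode(payload_904)
        assert pool.sequences == reference.sequences
        result = adapter.decode(pool.sequences)
        assert result.success and result.payload == payload_904

    def test_nonzero_exit_is_a_decode_failure(self):
        adapter = ExternalCodecAdapter(
            "true", f"{sys.executable} -c \"import sys; sys.exit(3)\"",
            timeout_s=30,
        )
        result = adapter.decode(["ACGT" * 10])
        assert not result.success
        assert result.diagnostics["returncode"] == 3

    def test_timeout_is_a_decode_failure_with_diagnostic(self):
        adapter = ExternalCodecAdapter(
            "true", f"{sys.executable} -c \"import time; time.sleep(30)\"",
            timeout_s=1.0,
        )
        result = adapter.decode(["ACGT" * 10])
        assert not result.success
        assert result.diagnostics.get("timeout") is True
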