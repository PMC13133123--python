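import numpy as np
import pytest

from oligobench import ReferencePool, Read, ReadSet, generate_payload, get_codec


@pytest.fixture(scope="session")
def small_pool() -> ReferencePool:
    """Ten random 40-nt reference sequences."""
    rng = np.random.default_rng(42)
    seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(10)]
    return ReferencePool(sequences=seqs)


@pytest.fixture(scope="session")
def payload_904() -> bytes:
    return generate_payload(904, seed=1).data


@pytest.fixture(scope="session")
def rs_pool(payload_904):
    """RS codec at 0.50 bit/nt with its 96-sequence encoded pool."""
    codec = get_codec("rs", "0.50")
    pool = codec.encode(payload_904)
    return codec, pool


def perfect_readset(pool: ReferencePool, copies: int = 3) -> ReadSet:
    reads = [
        Read(sequence=seq, origin=i, abundance=copies)
        for i, seq in enumerate(pool.sequences)
    ]
    return ReadSet(reads=reads, pool_size=len(pool))
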