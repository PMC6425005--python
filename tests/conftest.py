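import random

import pytest

from prospect import CladeTree, ProteinRecord


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def tree():
    return CladeTree.default()


def random_records(rng, n, min_len=10, max_len=80, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    """Uniform-composition random protein records."""
    out = []
    for i in range(n):
        length = rng.randint(min_len, max_len)
        seq = "".join(rng.choice(alphabet) for _ in range(length))
        out.append(ProteinRecord(id=f"r{i}", sequence=seq, taxon="Gastropoda"))
    return out
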