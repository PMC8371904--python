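import random

import pytest

from ratelessdna import PacketLayout


@pytest.fixture
def rnd():
    """Seeded stdlib generator for test-side randomness (fixtures, fuzz)."""
    return random.Random(0xD0A)


@pytest.fixture
def seed2_layout():
    """The common compact layout: 2-byte seed, 4-byte chunk count, CRC-32."""
    return PacketLayout(seed_width=2)


def random_payload(rnd, size):
    return bytes(rnd.randrange(256) for _ in range(size))
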