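import numpy as np
import pytest
from hypothesis import settings

from promoscan.promoter_io import Promoter

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def make_promoter(seq: str, gene_id: str = "g1") -> Promoter:
    return Promoter(gene_id=gene_id, seq=seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140900)


@pytest.fixture
def at_background() -> str:
    # pure A/T 2-kb background for planting GC-rich fixtures
    return "AT" * 1000
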