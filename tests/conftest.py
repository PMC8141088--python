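import numpy as np
import pytest

from mitoscreen import SimConfig, simulate


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic bundle (seed 1), shared across tests."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def gff3_features(bundle):
    feats = []
    for g in bundle.reference.genes:
        feats.append({"type": "CDS", "start": g.start, "end": g.end,
                      "strand": g.strand, "attributes": {"ID": g.name}})
        feats.append({"type": "promoter", "start": g.promoter_start,
                      "end": g.promoter_end, "strand": g.strand,
                      "attributes": {"ID": f"{g.name}_promoter", "Parent": g.name}})
    return feats


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
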