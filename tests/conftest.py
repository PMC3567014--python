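import numpy as np
import pytest

from snosite import PeptideWindow, ProteinRecord, ScorerConfig
from snosite.synthetic import STRONG_ENRICHMENTS, SyntheticSpec, generate_benchmark


def window(residues: str, label: str = "unknown", protein_id: str = "p", site: int = 100):
    """Build a PeptideWindow from its literal residue string."""
    assert len(residues) % 2 == 1
    xi = len(residues) // 2
    return PeptideWindow(
        protein_id=protein_id, site=site, residues=residues, xi=xi, label=label
    )


@pytest.fixture
def mk():
    return window


@pytest.fixture
def protein():
    return ProteinRecord(id="p1", sequence="MCACK")


@pytest.fixture(scope="session")
def strong_benchmark():
    """200+200 windows with a clearly separable planted motif."""
    spec = SyntheticSpec(n_pos=200, n_neg=200, enrichments=STRONG_ENRICHMENTS, seed=7)
    return generate_benchmark(spec)


@pytest.fixture(scope="session")
def strong_model(strong_benchmark):
    from snosite import train

    pos, neg = strong_benchmark
    return train(pos, neg, ScorerConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
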