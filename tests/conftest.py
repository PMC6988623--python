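import numpy as np
import pytest

from mirbridge.dataio import (
    EdgeList,
    EntityClass,
    InteractionNetwork,
    curate,
)
from mirbridge.synthetic import SynthConfig, generate


@pytest.fixture
def toy_lnc_net() -> InteractionNetwork:
    """m1 -> {l1, l2}, m2 -> {l1}: the worked two-miRNA toy network."""
    return InteractionNetwork.from_pairs(
        [("l1", "m1"), ("l2", "m1"), ("l1", "m2")], EntityClass.LNCRNA
    )


@pytest.fixture
def toy_dataset():
    """Two disjoint mediation chains: m1: l1-p1, m2: l2-p2."""
    lnc = EdgeList([("l1", "m1"), ("l2", "m2")], EntityClass.LNCRNA)
    prot = EdgeList([("p1", "m1"), ("p2", "m2")], EntityClass.PROTEIN)
    return curate(lnc, prot)


@pytest.fixture(scope="session")
def small_synthetic():
    """A compact planted-signal dataset reused across evaluation tests."""
    cfg = SynthConfig(
        x=60,
        y=50,
        z=25,
        lnc_density=0.06,
        prot_density=0.1,
        positive_rate=0.08,
        enrichment=10.0,
        with_sequences=False,
        seed=42,
    )
    return generate(cfg)


def random_network(rng: np.random.Generator, n_entities: int, n_mirnas: int,
                   entity_class=EntityClass.LNCRNA, density: float = 0.4):
    """Random bipartite network guaranteed to have >= 1 edge."""
    adj = (rng.random((n_entities, n_mirnas)) < density).astype(np.uint8)
    if adj.sum() == 0:
        adj[rng.integers(n_entities), rng.integers(n_mirnas)] = 1
    ids = [f"e{i}" for i in range(n_entities)]
    mirnas = [f"m{j}" for j in range(n_mirnas)]
    return InteractionNetwork(ids, mirnas, adj, entity_class)
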