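import numpy as np
import pytest

import cugdyn as cd


@pytest.fixture(scope="session")
def duplex3() -> cd.RnaStructure:
    """Idealized (CUG)_3 duplex, 18 nt — the reference analysis system."""
    return cd.build_cug_duplex(3)


@pytest.fixture(scope="session")
def capped2() -> cd.RnaStructure:
    """(CUG)_2 duplex capped by C-G pairs — the U-U typing model system."""
    return cd.build_cug_duplex(2, cap="GC")


@pytest.fixture(scope="session")
def nodes_cg2(duplex3) -> cd.NodeSet:
    return cd.select_nodes(duplex3, "CG2")


@pytest.fixture(scope="session")
def anm_cg2(nodes_cg2) -> cd.ModeSet:
    """CG2 network modes of the (CUG)_3 duplex at the 9 A optimum."""
    return cd.anm_modes(nodes_cg2, cd.ForceConstant(cutoff=9.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_nodes(rng: np.random.Generator, n: int, spread: float = 8.0) -> cd.NodeSet:
    coords = rng.uniform(0.0, spread, size=(n, 3))
    labels = [("A", i + 1, "U", "P") for i in range(n)]
    return cd.NodeSet(coords, labels)
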