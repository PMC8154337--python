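import numpy as np
import pytest

from rolmp2 import (MolecularSystem, RunConfig, build_local_basis,
                    build_reference, generate_fixture)


@pytest.fixture(scope="session")
def radical_systems():
    """Small open-shell fixture molecules, split-valence basis."""
    return {s.name: s for s in generate_fixture("radical_set")}


@pytest.fixture(scope="session")
def radical_refs(radical_systems):
    cfg = RunConfig()
    return {name: build_reference(sys_, cfg)
            for name, sys_ in radical_systems.items()}


@pytest.fixture(scope="session")
def oh_ref(radical_refs):
    return radical_refs["OH"]


@pytest.fixture(scope="session")
def oh_local(oh_ref):
    return build_local_basis(oh_ref)


@pytest.fixture(scope="session")
def singlet_systems():
    return {s.name: s for s in generate_fixture("singlet_set")}


@pytest.fixture(scope="session")
def h2o_ref(singlet_systems):
    return build_reference(singlet_systems["H2O"], RunConfig())


@pytest.fixture(scope="session")
def chain6():
    """Terminal-diradical hexane chain, minimal basis, with its reference."""
    sys_ = generate_fixture("chain", basis_name="minimal", n=6)
    return sys_, build_reference(sys_, RunConfig())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
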