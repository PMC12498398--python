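import numpy as np
import pytest

from azeopatch.graph import (
    MixtureDesign,
    build_ideal_azeotrope_binary,
    build_n2c8,
)


@pytest.fixture(scope="session")
def n2c8_uniform() -> MixtureDesign:
    return build_n2c8(1.0, 1.0)


@pytest.fixture(scope="session")
def n2c8_tuned() -> MixtureDesign:
    return build_n2c8(1.35, 1.0)


@pytest.fixture(scope="session")
def ideal_design() -> MixtureDesign:
    return build_ideal_azeotrope_binary()


@pytest.fixture(scope="session")
def hs_design() -> MixtureDesign:
    """Binary tetrahedral mixture with all bonding switched off."""
    base = build_ideal_azeotrope_binary()
    return MixtureDesign(
        species=list(base.species),
        energy_matrix=np.zeros_like(base.energy_matrix),
        kf=base.kf,
    )
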