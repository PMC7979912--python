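import pytest

from crisscross.architectures import CrisscrossSlats, HexTileTube, SquareTileTube
from crisscross.design import assign_sequences, build_blueprint, generate_domain_layout
from crisscross.energies import EnergyParams


@pytest.fixture(scope="session")
def cs6():
    return CrisscrossSlats(half_coordination=6)


@pytest.fixture(scope="session")
def st3():
    return SquareTileTube(circumference=3)


@pytest.fixture(scope="session")
def ht3():
    return HexTileTube(circumference=3)


@pytest.fixture(scope="session")
def params_1um_eps2():
    """Plain (uncalibrated) 1 uM, eps = 2 parameter factory."""

    def make(n: int) -> EnergyParams:
        return EnergyParams.for_architecture(n, 2.0, concentration=1e-6)

    return make


@pytest.fixture(scope="session")
def v6_blueprint():
    """A sequence-assigned v6 full design (shared; assignment is pure)."""
    layout = generate_domain_layout(6, 10.5)
    return assign_sequences(build_blueprint(layout, "full"), rng_seed=42)
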