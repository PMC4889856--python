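import numpy as np
import pytest

from iontraj.potential import drift_gas
from iontraj.structures import _make_ion


@pytest.fixture(scope="session")
def n2_iso():
    return drift_gas("N2-iso")


@pytest.fixture(scope="session")
def n2_full():
    return drift_gas("N2")


@pytest.fixture(scope="session")
def lj_atom():
    """Neutral single-atom ion: a purely spherical Lennard-Jones scatterer."""
    return _make_ion("lj-atom", ["N"], np.zeros((1, 3)), [0.0], 0)


@pytest.fixture(scope="session")
def charged_atom():
    """Single-atom ion carrying the full +1 e charge (spherical LJ + r^-4)."""
    return _make_ion("charged-atom", ["N"], np.zeros((1, 3)), [1.0], 1)


def spherical_lj_potential(eps: float = 4.55, sig: float = 3.38):
    """V(r) for the lj_atom fixture against the N2-iso probe, meV."""

    def V(r: float) -> float:
        return 4.0 * eps * ((sig / r) ** 12 - (sig / r) ** 6)

    return V
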