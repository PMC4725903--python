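import numpy as np
import pytest

from mscl_lattice.fe_core import BilayerParams
from mscl_lattice.pair_potentials import PairTable
from mscl_lattice.shapes import ProteinShape, mscl_shape


@pytest.fixture(scope="session")
def params():
    return BilayerParams()


@pytest.fixture(scope="session")
def pent():
    return mscl_shape("pentamer", "closed")


@pytest.fixture(scope="session")
def tet():
    return mscl_shape("tetramer", "closed")


@pytest.fixture(scope="session")
def cyl():
    return mscl_shape("cylinder", "closed")


def make_toy_table(shape_a: ProteinShape, shape_b: ProteinShape | None = None,
                   depth: float = 4.0, aniso: float = 0.0,
                   d_contact: float = 5.0, d_cut: float = 10.0,
                   n_omega: int = 8, d_step: float = 0.25) -> PairTable:
    """Synthetic smooth pair table (no FE): Morse-like well in d with an
    optional anisotropic modulation favoring face-on contact.

    Used to exercise table/Monte-Carlo machinery cheaply and exactly.
    """
    shape_b = shape_b or shape_a
    n1 = 1 if shape_a.symmetry_order == 0 else n_omega
    n2 = 1 if shape_b.symmetry_order == 0 else n_omega
    w1 = np.arange(n1) * shape_a.sector / n1
    w2 = np.arange(n2) * shape_b.sector / n2
    d0 = d_contact - d_step
    d_grid = np.arange(d0, d_cut - 1.0 + 0.5 * d_step, d_step)
    W1, W2 = np.meshgrid(w1, w2, indexing="ij")
    sA, sB = max(shape_a.symmetry_order, 1), max(shape_b.symmetry_order, 1)
    # face-on (trough toward the partner) preferred when aniso > 0; the
    # form is exchange-symmetric: f(w1, w2) = f(w2 + pi, w1 + pi)
    mod = 1.0 - 0.5 * aniso * (np.cos(sA * W1) + np.cos(sB * (W2 - np.pi)))
    dmin = np.full((n1, n2), d_contact)
    E = np.full((len(d_grid), n1, n2), np.inf)
    lam = 0.9
    for k, d in enumerate(d_grid):
        x = (d - d_contact) / lam
        radial = depth * (np.exp(-2 * x) - 2 * np.exp(-x)) + 0.3 * np.exp(-x) * np.cos(np.pi * x)
        E[k] = np.where(d >= dmin, radial * mod, np.inf)
    return PairTable(
        shapeA=shape_a.with_orientation(0.0), shapeB=shape_b.with_orientation(0.0),
        params=BilayerParams(), d_grid=d_grid, omega1_grid=w1, omega2_grid=w2,
        energies=E, d_min=dmin, d_cut=d_cut, clearance=0.5,
    )


@pytest.fixture(scope="session")
def toy_disc_table():
    """Isotropic sticky-disc table (cylinder symmetry)."""
    disc = ProteinShape(symmetry_order=0, radius=2.25, mismatch=0.3, label="disc")
    return make_toy_table(disc, d_contact=5.0)


@pytest.fixture(scope="session")
def toy_tet_table(tet):
    return make_toy_table(tet, aniso=0.6, d_contact=5.2)


@pytest.fixture(scope="session")
def toy_pent_table(pent):
    return make_toy_table(pent, aniso=0.6, d_contact=5.1)
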