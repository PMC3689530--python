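import numpy as np
import pytest

from braggkit.crystal_model import (
    CrystalStructure,
    Scatterer,
    UnitCell,
    space_group_ops,
)
from braggkit.synthetic_frames import default_geometry


@pytest.fixture
def cubic_cell():
    return UnitCell(10.0, 10.0, 10.0)


@pytest.fixture
def one_carbon_p1(cubic_cell):
    """Single C at the origin, full occupancy, no displacement."""
    return CrystalStructure.p1(cubic_cell, [Scatterer("C1", "C", [0.0, 0.0, 0.0])])


@pytest.fixture
def two_atom_p1():
    """Centrosymmetric pair (C at x and -x) in P1."""
    cell = UnitCell(12.0, 14.0, 16.0)
    x = np.array([0.11, 0.23, 0.37])
    return CrystalStructure.p1(
        cell, [Scatterer("C1", "C", x), Scatterer("C2", "C", -x)]
    )


@pytest.fixture
def p21_one_atom():
    """General-position atom in P21; 0k0 reflections with odd k are absent."""
    cell = UnitCell(20.0, 25.0, 30.0, 90.0, 105.0, 90.0)
    return CrystalStructure(
        cell, space_group_ops("P 21"), [Scatterer("C1", "C", [0.13, 0.27, 0.41])], "P 21"
    )


@pytest.fixture
def p63_five_atoms():
    """Toy 5-atom structure in P63 (hexagonal cell)."""
    cell = UnitCell(20.0, 20.0, 30.0, 90.0, 90.0, 120.0)
    atoms = [
        Scatterer("C1", "C", [0.10, 0.20, 0.30]),
        Scatterer("N1", "N", [0.40, 0.10, 0.70], u_iso=0.01),
        Scatterer("O1", "O", [0.80, 0.50, 0.20], u_iso=0.02),
        Scatterer("C2", "C", [0.30, 0.60, 0.90]),
        Scatterer("S1", "S", [0.55, 0.35, 0.15], u_iso=0.03),
    ]
    return CrystalStructure(cell, space_group_ops("P 63"), atoms, "P 63")


@pytest.fixture
def geometry():
    return default_geometry()


def random_structure_in(space_group, seed, n_atoms=4):
    """Random general-position structure in a built-in space group."""
    rng = np.random.default_rng(seed)
    if space_group == "P 63":
        cell = UnitCell(20.0, 20.0, 30.0, 90.0, 90.0, 120.0)
    elif space_group in ("P 21", "C 2"):
        cell = UnitCell(20.0, 25.0, 30.0, 90.0, 105.0, 90.0)
    else:
        cell = UnitCell(20.0, 25.0, 30.0)
    scatterers = [
        Scatterer(f"C{i}", "C", 0.05 + 0.9 * rng.random(3), u_iso=0.02)
        for i in range(n_atoms)
    ]
    return CrystalStructure(cell, space_group_ops(space_group), scatterers, space_group)
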