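"""Shared fixtures: small bead structures built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from oligogrowth.core import Atom, Residue, Structure


def make_bead(serial, xyz, radius=1.7, mass=12.0, chain="A", residue_index=1, name="C", element="C"):
    return Atom(serial, name, element, np.asarray(xyz, float), mass, radius, residue_index, chain)


def bead_structure(points, radius=1.7, chain="A"):
    """All beads in one residue of one chain."""
    atoms = [make_bead(i + 1, p, radius=radius, chain=chain) for i, p in enumerate(points)]
    return Structure(residues=[Residue("GLY", 1, atoms)])


@pytest.fixture(scope="session")
def bead_ball():
    """A filled, roughly spherical bead cluster (convex reference body)."""
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(300, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= 8.0 * np.cbrt(rng.uniform(0.2, 1.0, size=(300, 1)))
    return bead_structure(pts)


def disk_lobe_pair(neck_radius, lobe_radius=12.0, spacing=2.0):
    """Two bead-filled disks joined by a cylindrical neck of given radius.

    As the neck narrows the facing disk walls are exposed, so the
    molecular surface grows while the enclosing hull barely changes -
    a controllable concavity series.
    """
    pts = []
    def cylinder(radius, z0, z1):
        for z in np.arange(z0, z1 + 1e-9, spacing):
            for x in np.arange(-radius, radius + 1e-9, spacing):
                for y in np.arange(-radius, radius + 1e-9, spacing):
                    if x * x + y * y <= radius**2:
                        pts.append((x, y, z))
    cylinder(lobe_radius, -8, -4)
    cylinder(lobe_radius, 4, 8)
    cylinder(neck_radius, -4, 4)
    return bead_structure(pts)


TOY_GLY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
"""

TWO_CHAIN_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
TER
ATOM      3  N   ALA B   1      10.000   0.000   0.000  1.00  0.00           N
ATOM      4  CA  ALA B   1      11.458   0.000   0.000  1.00  0.00           C
"""

ALTLOC_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AGLY A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CA BGLY A   1       1.600   0.000   0.000  1.00  0.00           C
ATOM      4  C   GLY A   1       2.100   1.000   0.000  1.00  0.00           C
HETATM    5  C1  D6M A   2       5.000   0.000   0.000  1.00  0.00           C
"""


@pytest.fixture
def toy_gly_pdb(tmp_path):
    p = tmp_path / "gly.pdb"
    p.write_text(TOY_GLY_PDB)
    return p


@pytest.fixture
def two_chain_pdb(tmp_path):
    p = tmp_path / "two.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(ALTLOC_PDB)
    return p
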