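"""Atomic structure model, PDB I/O, and geometric primitives.

The containers here are deliberately lightweight: an :class:`Atom` carries
coordinates, an element-inferred mass and van der Waals radius; a
:class:`Residue` groups atoms; a :class:`Structure` groups residues and
partitions them into monomers by chain identifier (one chain per monomer).
On top of these sit the geometry routines every downstream analysis uses:
radius of gyration, Shrake-Rupley solvent-accessible surface area, and a
convexity shape factor (molecular surface area over enclosing convex hull
area).
"""

from __future__ import annotations

import logging
import math

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, cKDTree
from scipy.spatial import QhullError
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 1.4  # water probe, Angstrom
DEFAULT_VDW_RADIUS = 1.7  # fallback for unknown elements, Angstrom
DEFAULT_SPHERE_POINTS = 960


class PDBFormatError(ValueError):
    """Raised when an ATOM/HETATM record cannot be parsed."""


def _load_element_table() -> dict[str, tuple[float, float]]:
    table = {}
    path = resources.files("oligogrowth").joinpath("data/elements.csv")
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, mass, rad = line.split(",")
        table[el.upper()] = (float(mass), float(rad))
    return table


ELEMENT_TABLE = _load_element_table()


@dataclass
class Atom:
    """A point atom with element-derived mass and van der Waals radius."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    mass: float
    vdw_radius: float
    residue_index: int
    chain_id: str

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if self.mass <= 0 or self.vdw_radius <= 0:
            raise ValueError("mass and vdw radius must be positive")


@dataclass
class Residue:
    """A named residue owning an ordered list of atoms."""

    name: str
    index: int
    atoms: list[Atom] = field(default_factory=list)

    @property
    def chain_id(self) -> str:
        return self.atoms[0].chain_id if self.atoms else ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class Structure:
    """Residues partitioned into monomers (chains)."""

    residues: list[Residue] = field(default_factory=list)
    title: str = ""

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r)
        return out

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def monomers(self) -> list["Structure"]:
        """One sub-structure per chain, in order of first appearance."""
        return [
            Structure(residues=res, title=f"{self.title}:{cid}")
            for cid, res in self.chains.items()
        ]


def _element_from_record(element_field: str, atom_name: str) -> str:
    el = element_field.strip().upper()
    if el:
        return el
    # infer from the atom name: skip leading digits, two-letter elements
    # only when the name starts in column 13 (rare for peptides)
    name = atom_name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _lookup_element(el: str, default_radius: float) -> tuple[float, float]:
    if el in ELEMENT_TABLE:
        return ELEMENT_TABLE[el]
    logger.warning("unknown element %r: default radius %.2f A used", el, default_radius)
    return (12.011, default_radius)


def _parse_atom_record(
    line: str, lineno: int, default_radius: float
) -> tuple[Atom, str, int, str]:
    """Parse one ATOM/HETATM line -> (atom, resname, resseq, altloc)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element_field = line[76:78] if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"unparseable ATOM/HETATM record at line {lineno}: {line!r}") from exc
    el = _element_from_record(element_field, name)
    mass, rad = _lookup_element(el, default_radius)
    atom = Atom(serial, name, el, (x, y, z), mass, rad, resseq, chain)
    return atom, resname, resseq, altloc


def read_pdb_frames(path, default_radius: float = DEFAULT_VDW_RADIUS) -> list[Structure]:
    """Read a (possibly multi-MODEL) PDB file; each MODEL is one frame.

    HETATM residues (e.g. D6M) are retained; altLoc other than blank/'A'
    is dropped; unknown elements fall back to ``default_radius``.
    """
    path = Path(path)
    frames: list[Structure] = []
    current = Structure(title=path.stem)
    in_model = False
    res_key = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            in_model = True
            current = Structure(title=path.stem)
            res_key = None
        elif rec == "ENDMDL":
            frames.append(current)
            current = Structure(title=path.stem)
            res_key = None
        elif rec in ("ATOM  ", "HETATM"):
            atom, resname, resseq, altloc = _parse_atom_record(line, lineno, default_radius)
            if altloc not in (" ", "A"):
                continue
            key = (atom.chain_id, resseq, resname)
            if key != res_key:
                current.residues.append(Residue(name=resname, index=resseq))
                res_key = key
            current.residues[-1].atoms.append(atom)
        elif rec.startswith("TITLE"):
            current.title = line[10:].strip() or current.title
    if current.residues:
        frames.append(current)
    if not frames:
        raise PDBFormatError(f"no ATOM/HETATM records found in {path}")
    if in_model and len(frames) > 1:
        # titles per frame
        for i, f in enumerate(frames):
            f.title = f"{path.stem}:frame{i}"
    return frames


def read_pdb(path, default_radius: float = DEFAULT_VDW_RADIUS) -> Structure:
    """Read the first (or only) model of a PDB file."""
    return read_pdb_frames(path, default_radius)[0]


def write_pdb(structures: Structure | Sequence[Structure], path) -> None:
    """Write one structure, or a sequence of frames as MODEL/ENDMDL blocks."""
    if isinstance(structures, Structure):
        structures = [structures]
    lines: list[str] = []
    multi = len(structures) > 1
    for imodel, s in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:4d}")
        serial = 0
        for res in s.residues:
            for atom in res.atoms:
                serial += 1
                rec = "HETATM" if res.name in ("D6M",) or len(res.name) != 3 else "ATOM  "
                lines.append(
                    f"{rec}{serial:5d} {atom.name:<4.4s} {res.name:>3.3s} "
                    f"{atom.chain_id:1.1s}{res.index:4d}    "
                    f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {atom.element:>2.2s}"
                )
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def radius_of_gyration(atoms: Iterable[Atom] | Structure, mass_weighted: bool = True) -> float:
    """Rg = sqrt( sum m_k |r_k - rbar|^2 / sum m_k ); unit masses if not weighted."""
    if isinstance(atoms, Structure):
        atoms = atoms.atoms
    atoms = list(atoms)
    if not atoms:
        raise ValueError("radius of gyration of an empty atom collection")
    coords = np.array([a.coords for a in atoms])
    m = np.array([a.mass for a in atoms]) if mass_weighted else np.ones(len(atoms))
    center = np.average(coords, axis=0, weights=m)
    d2 = np.sum((coords - center) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=m)))


def _golden_spiral_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-section spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sasa(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's accessible sphere of radius (vdw + probe) is sampled at
    ``n_sphere_points``; the exposed fraction times the sphere area is the
    per-atom SASA. Returns (per-atom areas, total), both in A^2.
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    if n_sphere_points < 32:
        raise ValueError("need at least 32 sphere points")
    coords = structure.coords()
    radii = structure.radii() + probe_radius
    n = len(coords)
    sphere = _golden_spiral_points(n_sphere_points)
    tree = cKDTree(coords)
    areas = np.zeros(n)
    max_r = radii.max()
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        # neighbours whose inflated spheres can occlude atom i
        nbrs = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        if nbrs:
            nbr_xyz = coords[nbrs]
            nbr_r = radii[nbrs]
            d2 = np.sum((pts[:, None, :] - nbr_xyz[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < nbr_r[None, :] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return areas, float(areas.sum())


@dataclass
class ShapeMetrics:
    """Molecular-surface area, enclosing-hull area, and their ratio."""

    ses_area: float
    hull_area: float
    shape_factor: float


def _molecular_surface_area(
    coords: np.ndarray, radii: np.ndarray, grid_spacing: float
) -> float:
    """Area of the outer surface of the union of spheres.

    The signed distance to the union, f(x) = min_i(|x - c_i| - R_i), is
    sampled on a regular grid and triangulated at the zero level set
    (marching cubes). Interior cavities are filled beforehand so only the
    outward-facing surface is counted.
    """
    pad = radii.max() + 2 * grid_spacing
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / grid_spacing).astype(int) + 1
    axes = [lo[d] + grid_spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack((gx.ravel(), gy.ravel(), gz.ravel()))
    tree = cKDTree(coords)
    # signed distance: for uniform-ish radii the nearest few centers suffice
    kq = min(len(coords), 8)
    dist, idx = tree.query(pts, k=kq, workers=-1)
    if kq == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    f = np.min(dist - radii[idx], axis=1).reshape(shape)
    # fill interior cavities: positive regions not connected to the boundary
    outside = f > 0
    labels, nlab = ndimage.label(outside)
    edge_labels = set(np.unique(labels[0, :, :])) | set(np.unique(labels[-1, :, :]))
    edge_labels |= set(np.unique(labels[:, 0, :])) | set(np.unique(labels[:, -1, :]))
    edge_labels |= set(np.unique(labels[:, :, 0])) | set(np.unique(labels[:, :, -1]))
    edge_labels.discard(0)
    cavity = outside & ~np.isin(labels, sorted(edge_labels))
    f[cavity] = -grid_spacing
    verts, faces, _, _ = measure.marching_cubes(
        f, level=0.0, spacing=(grid_spacing,) * 3
    )
    return float(measure.mesh_surface_area(verts, faces))


def shape_factor(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    grid_spacing: float = 0.5,
    hull_sphere_points: int = 200,
) -> ShapeMetrics:
    """Convexity shape factor: molecular-surface area / enclosing hull area.

    The molecular surface is the outer surface of the probe-inflated union
    of atom spheres (triangulated on a ``grid_spacing`` grid); the hull is
    the convex hull of the same inflated spheres. The ratio is ~1 for
    convex bodies and grows with surface concavity.
    """
    coords = structure.coords()
    if len(coords) < 4:
        raise ValueError("shape factor needs at least 4 atoms")
    if np.linalg.matrix_rank(coords - coords.mean(axis=0), tol=1e-8) < 3:
        raise ValueError("degenerate (coplanar) geometry")
    radii = structure.radii() + probe_radius
    try:
        hull_pts = (
            coords[:, None, :] + radii[:, None, None] * _golden_spiral_points(hull_sphere_points)[None, :, :]
        ).reshape(-1, 3)
        hull = ConvexHull(hull_pts)
    except QhullError as exc:
        raise ValueError("degenerate (coplanar) geometry") from exc
    ses = _molecular_surface_area(coords, radii, grid_spacing)
    return ShapeMetrics(ses_area=ses, hull_area=float(hull.area), shape_factor=ses / float(hull.area))
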