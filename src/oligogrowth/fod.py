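"""One-dimensional fuzzy-oil-drop hydrophobicity profiles.

A micelle-like assembly buries hydrophobic groups in its core and
presents polar groups at its surface. To visualise this along a single
axis, each residue is modelled as a Gaussian centred at its mean
position with a spread equal to the RMS deviation of its atoms,
weighted by its normalized Kyte-Doolittle hydrophobicity H(r) in
[-1, 1]:

    H_i(x) = sum_r H(r) * exp(-(x - mu_{r,i})^2 / (2 sigma_{r,i}^2))

Coordinates are centred at the geometric centre and scaled isotropically
so the largest |coordinate| maps to 1 (shared scale across axes, so
relative spreads are preserved). A positive core with negative edges is
the fingerprint of a hydrophobic-core / hydrophilic-surface micelle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Residue, Structure

DEFAULT_GRID_POINTS = 201
SIGMA_FLOOR = 0.02  # normalized units; keeps single-atom residues finite


@dataclass
class HydrophobicityScale:
    """Residue hydrophobicities normalized by the scale's maximum |h|."""

    raw: dict[str, float]
    max_abs: float = field(init=False)
    normalized: dict[str, float] = field(init=False)

    def __post_init__(self):
        if not self.raw:
            raise ValueError("empty hydrophobicity table")
        self.max_abs = max(abs(v) for v in self.raw.values())
        if self.max_abs == 0:
            raise ValueError("all-zero hydrophobicity table")
        self.normalized = {k.upper(): v / self.max_abs for k, v in self.raw.items()}

    def h(self, resname: str, default: float | None = None) -> float:
        key = resname.upper()
        if key in self.normalized:
            return self.normalized[key]
        if default is not None:
            return default
        raise KeyError(f"no hydrophobicity entry for residue {resname!r}")


def normalize_scale(raw: dict[str, float]) -> HydrophobicityScale:
    """H(r) = h(r) / max|h| over the table."""
    return HydrophobicityScale(raw=dict(raw))


def load_scale(path=None) -> HydrophobicityScale:
    """Load a two-column ``residue,h`` scale file; default bundled Kyte-Doolittle."""
    if path is None:
        text = resources.files("oligogrowth").joinpath("data/kyte_doolittle.csv").read_text()
    else:
        text = Path(path).read_text()
    raw = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, h = line.split(",")
        raw[name.strip().upper()] = float(h)
    return normalize_scale(raw)


AXES = {"x": 0, "y": 1, "z": 2}


def residue_spread(residue: Residue, axis: str, sigma_floor: float = 0.0) -> float:
    """RMS deviation of the residue's atom positions from their mean, one axis."""
    if residue.n_atoms < 1:
        raise ValueError("residue has no atoms")
    x = residue.coords()[:, AXES[axis]]
    return max(float(np.sqrt(np.mean((x - x.mean()) ** 2))), sigma_floor)


def _normalized_coords(structure: Structure) -> tuple[np.ndarray, float]:
    """Centre at the geometric centre, scale by the max |coordinate| (all axes)."""
    coords = structure.coords()
    if coords.size == 0:
        raise ValueError("empty structure")
    centered = coords - coords.mean(axis=0)
    scale = np.abs(centered).max()
    if scale == 0:
        scale = 1.0
    return centered / scale, float(scale)


@dataclass
class Profile:
    """A 1D hydrophobicity profile on a normalized coordinate grid."""

    axis: str  # 'x', 'y', 'z' or 'average'
    positions: np.ndarray
    values: np.ndarray


def _profile_from_gaussians(
    H: np.ndarray, mu: np.ndarray, sig: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    d = grid[None, :] - mu[:, None]
    return (H[:, None] * np.exp(-(d**2) / (2.0 * sig[:, None] ** 2))).sum(axis=0)


def hydrophobicity_profile(
    structure: Structure,
    axis: str,
    grid_points: int = DEFAULT_GRID_POINTS,
    scale: HydrophobicityScale | None = None,
    default_h: float | None = None,
    sigma_floor: float = SIGMA_FLOOR,
) -> Profile:
    """Gaussian-summed hydrophobicity along one axis of the normalized frame."""
    if grid_points < 11:
        raise ValueError("need at least 11 grid points")
    if axis not in AXES:
        raise ValueError("axis must be one of x, y, z")
    scale = scale or load_scale()
    norm, _ = _normalized_coords(structure)
    ax = AXES[axis]
    # per-residue mean and spread in the shared normalized frame
    H, mu, sig = [], [], []
    offset = 0
    for res in structure.residues:
        k = res.n_atoms
        xs = norm[offset : offset + k, ax]
        offset += k
        H.append(scale.h(res.name, default=default_h))
        mu.append(xs.mean())
        sig.append(max(float(np.sqrt(np.mean((xs - xs.mean()) ** 2))), sigma_floor))
    grid = np.linspace(-1.0, 1.0, grid_points)
    values = _profile_from_gaussians(np.array(H), np.array(mu), np.array(sig), grid)
    return Profile(axis=axis, positions=grid, values=values)


def profile_set(
    structure: Structure,
    grid_points: int = DEFAULT_GRID_POINTS,
    scale: HydrophobicityScale | None = None,
    default_h: float | None = None,
    sigma_floor: float = SIGMA_FLOOR,
) -> dict[str, Profile]:
    """x, y, z axis profiles plus their pointwise average."""
    scale = scale or load_scale()
    profs = {
        ax: hydrophobicity_profile(
            structure, ax, grid_points, scale=scale, default_h=default_h, sigma_floor=sigma_floor
        )
        for ax in ("x", "y", "z")
    }
    avg = (profs["x"].values + profs["y"].values + profs["z"].values) / 3.0
    profs["average"] = Profile("average", profs["x"].positions.copy(), avg)
    return profs


def profiles_to_frame(profs: dict[str, Profile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": profs["x"].positions,
            "Hx": profs["x"].values,
            "Hy": profs["y"].values,
            "Hz": profs["z"].values,
            "Havg": profs["average"].values,
        }
    )


@dataclass
class CoreDipDiagnostic:
    core_mean: float
    edge_mean: float
    has_central_dip: bool


def core_dip_diagnostic(profile: Profile) -> CoreDipDiagnostic:
    """Core/edge means and a central-dip flag for one profile.

    core_mean averages |x| <= 0.25, edge_mean averages |x| >= 0.7. A
    central dip is flagged when the value at x = 0 lies below both
    flanking local maxima found within |x| <= 0.5 (the shallow-peaks-
    around-a-dip motif of an assembly with internal polar contacts).
    """
    x, v = profile.positions, profile.values
    if len(x) < 21:
        raise ValueError("profile needs >= 21 grid points for the diagnostic")
    core_mean = float(v[np.abs(x) <= 0.25].mean())
    edge_mean = float(v[np.abs(x) >= 0.7].mean())
    center = float(np.interp(0.0, x, v))
    inner = np.where(np.abs(x) <= 0.5)[0]
    local_max = [
        i for i in inner[1:-1] if v[i] > v[i - 1] and v[i] > v[i + 1]
    ]
    left = [i for i in local_max if x[i] < 0]
    right = [i for i in local_max if x[i] > 0]
    has_dip = bool(left and right and center < min(v[max(left, key=lambda i: v[i])],
                                                  v[max(right, key=lambda i: v[i])]))
    return CoreDipDiagnostic(core_mean=core_mean, edge_mean=edge_mean, has_central_dip=has_dip)
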