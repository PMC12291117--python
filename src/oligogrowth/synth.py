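"""Synthetic data generators with attached ground truth.

Each generator emulates the statistical or geometric structure one of
the analyses assumes - a CCS series obeying the anisotropic growth law
with noise and minor-conformer satellites, a micelle-like bead assembly
with hydrophobic tails pointing inward, a Gaussian-mixture trajectory
in intrinsic coordinates with known state weights, and a multi-frame
assembly whose per-monomer Rg follows a prescribed drift. Every
generator is deterministic under a fixed seed and returns a
:class:`GeneratorTruth` recording the parameters used, so recovery
tests compare estimates against the truth rather than hard-coded
numbers.

The bead fixtures are coarse-grained pseudo-atoms (2.3 A radius)
written with real residue names whose Kyte-Doolittle normalized
hydrophobicities are the extremes: ILE (+1.0) for tail beads and ARG
(-1.0) for head beads. The fixtures are geometric, not energetic: no
force field is implied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import Atom, Residue, Structure
from .growth import CCSMeasurement, CCSSeries, predict_ccs
from .landscape import ProjectedTrajectory

BEAD_RADIUS = 2.3  # CG-like pseudo-atom radius, Angstrom
BEAD_MASS = 72.0  # roughly four heavy atoms per bead, Da
MIN_BEAD_SEPARATION = 3.5  # between beads of different monomers, Angstrom
TAIL_RESNAME = "ILE"  # normalized hydrophobicity +1.0
HEAD_RESNAME = "ARG"  # normalized hydrophobicity -1.0


@dataclass
class GeneratorTruth:
    """Parameters and seed behind a generated dataset."""

    generator: str
    seed: int
    parameters: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"generator": self.generator, "seed": self.seed, "parameters": self.parameters},
            indent=2, default=_jsonable,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# CCS series
# ---------------------------------------------------------------------------


def synth_ccs_series(
    sigma_fn: Callable[[int], float] | float,
    omega0: float = 439.7,
    n_range: Sequence[int] = range(2, 17),
    noise_cv: float = 0.0,
    minor_conformers: dict | None = None,
    charge_fn: Callable[[int], int] | None = None,
    seed: int = 0,
    label: str = "synthetic",
) -> tuple[CCSSeries, GeneratorTruth]:
    """CCS series following CCS = sigma(n) * Omega0 * n^(2/3) with noise.

    ``sigma_fn`` is a constant or a per-n callable. The main conformer
    per n gets multiplicative Gaussian noise of coefficient of variation
    ``noise_cv`` and unit intensity. ``minor_conformers`` optionally adds
    trailing satellites per n: a dict with ``count`` (default 1),
    ``ccs_inflation`` (CCS multiplier per satellite step, default 1.1)
    and ``intensity_frac`` (default 0.1), emulating low-abundance
    extended species above the main trendline.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    sf = sigma_fn if callable(sigma_fn) else (lambda n, s=float(sigma_fn): s)
    rng = np.random.default_rng(seed)
    charge = charge_fn or (lambda n: max(1, round(0.5 * n + 1.5)))
    ms = []
    for n in n_range:
        base = predict_ccs(n, sf(n), omega0)
        eps = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
        ms.append(CCSMeasurement(n=n, z=charge(n), ccs=base * (1.0 + eps), intensity=1.0))
        if minor_conformers:
            count = minor_conformers.get("count", 1)
            infl = minor_conformers.get("ccs_inflation", 1.1)
            frac = minor_conformers.get("intensity_frac", 0.1)
            for k in range(1, count + 1):
                eps = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
                ms.append(
                    CCSMeasurement(
                        n=n, z=charge(n), ccs=base * infl**k * (1.0 + eps),
                        intensity=frac**k,
                    )
                )
    truth = GeneratorTruth(
        "synth_ccs_series", seed,
        {
            "sigma": {int(n): sf(n) for n in n_range},
            "omega0": omega0,
            "noise_cv": noise_cv,
            "minor_conformers": minor_conformers or {},
        },
    )
    return CCSSeries(measurements=ms, label=label), truth


# ---------------------------------------------------------------------------
# micelle-like bead assembly
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def synth_micelle(
    n_monomers: int = 14,
    beads_per_monomer: int = 8,
    axis_folds: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
    inner_radius: float = 6.0,
    bead_spacing: float = 3.8,
    tail_fraction: float = 0.6,
    jitter: float = 0.6,
    max_retries: int = 50,
) -> tuple[Structure, GeneratorTruth]:
    """A micelle-like assembly: radial bead chains on an ellipsoidal shell.

    Monomers are straight bead chains pointing outward from the centre
    along near-uniform directions; the inner ``tail_fraction`` of beads
    form the hydrophobic tail residue (ILE, normalized H = +1), the rest
    the polar head residue (ARG, H = -1). The whole assembly is scaled
    anisotropically to axis folds (1, i, j). Placement retries with
    shrinking angular jitter until no two beads of different monomers
    are closer than the minimum separation.
    """
    if n_monomers < 1 or beads_per_monomer < 2:
        raise ValueError("need >= 1 monomer and >= 2 beads per monomer")
    i_fold, j_fold = axis_folds
    if i_fold < 1 or j_fold < 1:
        raise ValueError("axis folds must be >= 1")
    rng = np.random.default_rng(seed)
    dirs0 = _fibonacci_sphere(n_monomers)
    n_tail = max(1, int(round(tail_fraction * beads_per_monomer)))
    radii = inner_radius + bead_spacing * np.arange(beads_per_monomer)
    scale = np.array([1.0, i_fold, j_fold])

    for attempt in range(max_retries):
        jit = jitter * 0.8**attempt
        dirs = dirs0 + rng.normal(0.0, jit / max(inner_radius, 1.0), size=dirs0.shape)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        beads = (dirs[:, None, :] * radii[None, :, None]) * scale[None, None, :]
        if n_monomers == 1:
            break
        flat = beads.reshape(-1, 3)
        owner = np.repeat(np.arange(n_monomers), beads_per_monomer)
        d = np.linalg.norm(flat[:, None, :] - flat[None, :, :], axis=2)
        d[owner[:, None] == owner[None, :]] = np.inf
        if d.min() >= MIN_BEAD_SEPARATION:
            break
    else:
        raise RuntimeError(
            "could not pack monomers at the minimum bead separation; try fewer monomers"
        )

    structure = Structure(title=f"synthetic micelle n={n_monomers}")
    chain_ids = [chr(ord("A") + m % 26) + ("" if m < 26 else str(m // 26)) for m in range(n_monomers)]
    serial = 0
    for m in range(n_monomers):
        cid = chain_ids[m]
        tail = Residue(name=TAIL_RESNAME, index=1)
        head = Residue(name=HEAD_RESNAME, index=2)
        for b in range(beads_per_monomer):
            serial += 1
            atom = Atom(
                serial=serial, name="BB", element="C", coords=beads[m, b],
                mass=BEAD_MASS, vdw_radius=BEAD_RADIUS, residue_index=1 if b < n_tail else 2,
                chain_id=cid,
            )
            (tail if b < n_tail else head).atoms.append(atom)
        structure.residues.extend([tail, head])
    truth = GeneratorTruth(
        "synth_micelle", seed,
        {
            "n_monomers": n_monomers,
            "beads_per_monomer": beads_per_monomer,
            "axis_folds": list(axis_folds),
            "inner_radius": inner_radius,
            "bead_spacing": bead_spacing,
            "n_tail_beads": n_tail,
            "tail_resname": TAIL_RESNAME,
            "head_resname": HEAD_RESNAME,
        },
    )
    return structure, truth


# ---------------------------------------------------------------------------
# 2D Gaussian-mixture trajectory
# ---------------------------------------------------------------------------


def synth_trajectory2d(
    mixture: Sequence[tuple[float, Sequence[float], np.ndarray]],
    n_points: int = 50_000,
    seed: int = 0,
) -> tuple[ProjectedTrajectory, GeneratorTruth]:
    """I.i.d. samples from a 2D Gaussian mixture, shuffled into pseudo-time.

    ``mixture`` is a list of (weight, mean, covariance); weights must
    sum to 1. The known weights make Boltzmann basin depths exactly
    computable: ddG between two states = k_B T ln(w1/w2).
    """
    weights = np.array([m[0] for m in mixture], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_points, weights)
    chunks = []
    for (w, mean, cov), k in zip(mixture, counts):
        chunks.append(rng.multivariate_normal(np.asarray(mean, float), np.asarray(cov, float), size=k))
    pts = np.vstack(chunks)
    rng.shuffle(pts, axis=0)
    times = np.arange(n_points, dtype=float)
    truth = GeneratorTruth(
        "synth_trajectory2d", seed,
        {
            "weights": weights,
            "means": [np.asarray(m[1], float) for m in mixture],
            "covariances": [np.asarray(m[2], float) for m in mixture],
            "n_points": n_points,
        },
    )
    return ProjectedTrajectory(points=pts, times=times), truth


# ---------------------------------------------------------------------------
# assembly trajectory with prescribed monomer-Rg drift
# ---------------------------------------------------------------------------


def _chain_for_rg(target_rg: float, n_beads: int, direction: np.ndarray, origin: np.ndarray):
    """Collinear equal-mass bead positions with exactly the target Rg."""
    spacing = target_rg * math.sqrt(12.0 / (n_beads**2 - 1))
    offsets = (np.arange(n_beads) - (n_beads - 1) / 2.0) * spacing
    return origin[None, :] + offsets[:, None] * direction[None, :]


def synth_assembly_trajectory(
    n_monomers: int = 14,
    n_frames: int = 20,
    rg_drift: dict | None = None,
    beads_per_monomer: int = 10,
    seed: int = 0,
) -> tuple[list[Structure], GeneratorTruth]:
    """Frames of an assembly whose per-monomer Rg follows a drift spec.

    ``rg_drift`` keys: ``kind`` in {'constant', 'monotone_rise',
    'drop_then_rise'}; ``rg_start``/``rg_end`` (A, defaults 10.5/13.0);
    ``spread_start``/``spread_end`` (A, defaults 1.5/1.5). Monomers are
    straight bead chains with exactly solvable Rg; per-monomer offsets
    are fixed symmetric quantiles times the per-frame spread, so the
    frame mean and standard deviation follow the spec exactly.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    spec = dict(rg_drift or {})
    kind = spec.get("kind", "constant")
    rg_a = spec.get("rg_start", 10.5)
    rg_b = spec.get("rg_end", 13.0)
    sp_a = spec.get("spread_start", 1.5)
    sp_b = spec.get("spread_end", 1.5)
    t = np.linspace(0.0, 1.0, n_frames)
    if kind == "constant":
        mean = np.full(n_frames, rg_a)
    elif kind == "monotone_rise":
        mean = rg_a + (rg_b - rg_a) * t
    elif kind == "drop_then_rise":
        dip = spec.get("dip_frac", 0.15)
        t0 = spec.get("dip_at", 0.1)
        mean = np.where(
            t < t0,
            rg_a - (rg_a * dip) * (t / t0),
            rg_a * (1 - dip) + (rg_b - rg_a * (1 - dip)) * ((t - t0) / (1 - t0)),
        )
    else:
        raise ValueError(f"unknown drift kind {kind!r}")
    spread = sp_a + (sp_b - sp_a) * t

    # fixed zero-mean, unit-sd monomer offsets
    if n_monomers > 1:
        q = np.linspace(-1.0, 1.0, n_monomers)
        q = (q - q.mean()) / q.std(ddof=0)
    else:
        q = np.zeros(1)

    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_monomers, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    grid = int(np.ceil(n_monomers ** (1 / 3)))
    cell = 60.0
    origins = np.array(
        [(m % grid, (m // grid) % grid, m // grid**2) for m in range(n_monomers)], float
    ) * cell

    frames = []
    times = 50.0 * np.arange(n_frames)
    for f in range(n_frames):
        s = Structure(title=f"synthetic assembly frame {f}")
        serial = 0
        for m in range(n_monomers):
            rg_m = max(mean[f] + q[m] * spread[f], 0.5)
            beads = _chain_for_rg(rg_m, beads_per_monomer, dirs[m], origins[m])
            cid = chr(ord("A") + m % 26) + ("" if m < 26 else str(m // 26))
            res = Residue(name="GLY", index=m + 1)
            for b in range(beads_per_monomer):
                serial += 1
                res.atoms.append(
                    Atom(serial=serial, name="BB", element="C", coords=beads[b],
                         mass=BEAD_MASS, vdw_radius=BEAD_RADIUS,
                         residue_index=m + 1, chain_id=cid)
                )
            s.residues.append(res)
        frames.append(s)
    truth = GeneratorTruth(
        "synth_assembly_trajectory", seed,
        {
            "n_monomers": n_monomers,
            "n_frames": n_frames,
            "kind": kind,
            "mean_rg_A": mean,
            "spread_A": spread,
            "monomer_offsets": q,
            "times_ns": times,
        },
    )
    return frames, truth
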