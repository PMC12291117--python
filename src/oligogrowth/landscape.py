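"""Free-energy surfaces from projected 2D trajectories.

A trajectory projected onto two intrinsic coordinates samples the
conformational populations; Boltzmann inversion of the estimated density
gives relative free energies,

    dG(x, y) = -k_B T ln( rho(x, y) / rho_ref ),

with k_B = 0.0019872 kcal/(mol K). Density is estimated by a two-stage
adaptive (Abramson) kernel density estimator: a fixed-bandwidth pilot
(Scott's rule) sets per-point bandwidths proportional to the local
density to the power -1/2, normalized to unit geometric mean, so sparse
regions are smoothed more than well-sampled basins. Optional total-
variation denoising stabilises plateaus, and bootstrap resampling gives
per-cell confidence bands. Only free-energy *differences* are
identifiable from populations, so surfaces are reported relative to a
reference (global minimum by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.restoration import denoise_tv_chambolle

logger = logging.getLogger(__name__)

KB_KCAL = 0.0019872  # kcal / (mol K)
DEFAULT_TEMPERATURE = 300.0
DENSITY_FLOOR_FRAC = 1e-6
GREEK = "αβγδεζηθικλμνξ"


@dataclass
class ProjectedTrajectory:
    """(x, y) samples of a trajectory in intrinsic coordinates."""

    points: np.ndarray  # (N, 2)
    times: np.ndarray | None = None  # ns
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (N, 2)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("trajectory coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)


def read_trajectory(path) -> ProjectedTrajectory:
    """Read delimited ``time_ns,x,y[,weight]`` with '#' comments."""
    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    pts = df[[cols["x"], cols["y"]]].to_numpy(float)
    times = df[cols["time_ns"]].to_numpy(float) if "time_ns" in cols else None
    weights = df[cols["weight"]].to_numpy(float) if "weight" in cols else None
    return ProjectedTrajectory(points=pts, times=times, weights=weights)


@dataclass
class Grid2D:
    """A regular 2D lattice given by its cell-centre coordinate vectors."""

    xc: np.ndarray
    yc: np.ndarray

    @property
    def dx(self) -> float:
        return float(self.xc[1] - self.xc[0])

    @property
    def dy(self) -> float:
        return float(self.yc[1] - self.yc[0])

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.xc), len(self.yc))

    @classmethod
    def from_points(cls, points: np.ndarray, nx: int = 100, ny: int = 100, pad: float = 0.05):
        lo = points.min(axis=0)
        hi = points.max(axis=0)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        lo = lo - pad * span
        hi = hi + pad * span
        return cls(np.linspace(lo[0], hi[0], nx), np.linspace(lo[1], hi[1], ny))


def adaptive_kde(
    traj: ProjectedTrajectory,
    grid: Grid2D | None = None,
    alpha: float = 0.5,
    n_bandwidth_levels: int = 32,
    min_points: int = 100,
) -> tuple[np.ndarray, Grid2D]:
    """Two-stage adaptive KDE of the trajectory density on a grid.

    Stage 1: fixed-bandwidth pilot with Scott's-rule bandwidths
    h_d = std_d * n^(-1/6) (2D). Stage 2: per-point bandwidth factors
    lambda_k = (f_pilot(x_k) / g)^(-alpha) with g the geometric mean
    pilot density, so the geometric mean of lambda_k is 1 (alpha = 0.5,
    Abramson). Points are binned to the grid and each bandwidth level is
    applied by Gaussian filtering of its sub-histogram, which keeps the
    cost independent of sample size. The returned density integrates to
    1 over the grid.
    """
    if len(traj) < min_points:
        raise ValueError(f"need at least {min_points} points for density estimation")
    pts = traj.points
    w = traj.weights if traj.weights is not None else np.ones(len(pts))
    w = w / w.sum()
    if grid is None:
        grid = Grid2D.from_points(pts)
    nx, ny = grid.shape
    n = len(pts)
    std = pts.std(axis=0, ddof=1)
    span = np.array([grid.xc[-1] - grid.xc[0], grid.yc[-1] - grid.yc[0]])
    floor = 1e-3 * span
    h = np.maximum(std * n ** (-1.0 / 6.0), floor)  # Scott, 2D

    # bin points onto the grid (cell-centre assignment)
    ix = np.clip(np.round((pts[:, 0] - grid.xc[0]) / grid.dx).astype(int), 0, nx - 1)
    iy = np.clip(np.round((pts[:, 1] - grid.yc[0]) / grid.dy).astype(int), 0, ny - 1)

    def _filtered_hist(weights, sx, sy):
        hist = np.zeros((nx, ny))
        np.add.at(hist, (ix, iy), weights)
        return ndimage.gaussian_filter(hist, sigma=(sx, sy), mode="constant", truncate=6.0)

    # pilot density at the data points
    pilot = _filtered_hist(w, h[0] / grid.dx, h[1] / grid.dy)
    pilot /= pilot.sum() * grid.dx * grid.dy
    f_at_pts = np.maximum(pilot[ix, iy], 1e-300)
    g = np.exp(np.mean(np.log(f_at_pts)))
    lam = (f_at_pts / g) ** (-alpha)

    # quantize bandwidth factors into geometric levels and filter per level
    lam = np.clip(lam, np.exp(-3), np.exp(3))
    edges = np.geomspace(lam.min() / 1.001, lam.max() * 1.001, n_bandwidth_levels + 1)
    level = np.clip(np.searchsorted(edges, lam) - 1, 0, n_bandwidth_levels - 1)
    density = np.zeros((nx, ny))
    for L in np.unique(level):
        sel = level == L
        lam_L = np.exp(np.mean(np.log(lam[sel])))
        density += _filtered_hist(np.where(sel, w, 0.0), lam_L * h[0] / grid.dx, lam_L * h[1] / grid.dy)
    total = density.sum() * grid.dx * grid.dy
    if total <= 0:
        raise ValueError("degenerate density estimate")
    return density / total, grid


def total_variation(u: np.ndarray) -> float:
    """Isotropic discrete total variation of a 2D array."""
    gx = np.diff(u, axis=0)
    gy = np.diff(u, axis=1)
    return float(np.sqrt(gx[:, :-1] ** 2 + gy[:-1, :] ** 2).sum())


def tv_denoise(density: np.ndarray, lambda_tv: float, eps: float = 1e-6) -> np.ndarray:
    """Rudin-Osher-Fatemi denoising of a density grid (Chambolle projection).

    Minimises 0.5*||u - density||^2 + lambda_tv*TV(u); lambda_tv = 0
    returns the input untouched. The output is renormalised to the same
    integral as the input (clipped at zero first).
    """
    if lambda_tv < 0:
        raise ValueError("lambda_tv must be non-negative")
    if lambda_tv == 0:
        return density
    scale = density.max()
    if scale <= 0:
        return density
    u = denoise_tv_chambolle(density / scale, weight=lambda_tv, eps=eps, max_num_iter=500)
    u = np.clip(u * scale, 0.0, None)
    if u.sum() <= 0:
        warnings.warn("TV denoising removed all density; returning input")
        return density
    return u * (density.sum() / u.sum())


@dataclass
class EnergySurface:
    """Gridded relative free energy with optional bootstrap bounds."""

    grid: Grid2D
    delta_g: np.ndarray  # kcal/mol; NaN on masked (unsampled) cells
    temperature: float = DEFAULT_TEMPERATURE
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        X, Y = np.meshgrid(self.grid.xc, self.grid.yc, indexing="ij")
        data = {"x": X.ravel(), "y": Y.ravel(), "delta_g": self.delta_g.ravel()}
        if self.ci_low is not None:
            data["ci_low"] = self.ci_low.ravel()
            data["ci_high"] = self.ci_high.ravel()
        return pd.DataFrame(data)


def boltzmann_invert(
    density: np.ndarray,
    grid: Grid2D,
    temperature: float = DEFAULT_TEMPERATURE,
    reference: str = "min_g",
    floor_frac: float = DENSITY_FLOOR_FRAC,
) -> EnergySurface:
    """dG = -k_B T ln(rho / rho_ref); cells below the density floor are masked.

    reference='min_g' anchors the global minimum at 0;
    reference='max_density' anchors the most populated cell at 0 (same
    surface up to the constant).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kt = KB_KCAL * temperature
    floor = floor_frac * density.max()
    masked = density < floor
    with np.errstate(divide="ignore"):
        g = -kt * np.log(np.where(masked, np.nan, density))
    if reference == "min_g":
        g = g - np.nanmin(g)
    elif reference == "max_density":
        g = g - g[np.unravel_index(np.nanargmax(density), density.shape)]
    else:
        raise ValueError("reference must be 'min_g' or 'max_density'")
    return EnergySurface(grid=grid, delta_g=g, temperature=temperature)


def estimate_surface(
    traj: ProjectedTrajectory,
    grid: Grid2D | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    lambda_tv: float = 0.0,
    reference: str = "min_g",
) -> EnergySurface:
    """adaptive KDE (+ optional TV denoising) + Boltzmann inversion."""
    density, grid = adaptive_kde(traj, grid=grid)
    density = tv_denoise(density, lambda_tv)
    return boltzmann_invert(density, grid, temperature=temperature, reference=reference)


def bootstrap_uncertainty(
    traj: ProjectedTrajectory,
    n_boot: int = 100,
    seed: int = 0,
    grid: Grid2D | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    lambda_tv: float = 0.0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> EnergySurface:
    """Percentile bootstrap confidence bands for the free-energy surface.

    Resamples trajectory points with replacement, reruns the full
    KDE(+TV)+inversion pipeline, and reports per-cell percentiles. The
    point estimate is the full-sample surface on the same grid.
    """
    if n_boot < 50:
        raise ValueError("need n_boot >= 50")
    if grid is None:
        grid = Grid2D.from_points(traj.points)
    base = estimate_surface(traj, grid=grid, temperature=temperature, lambda_tv=lambda_tv)
    rng = np.random.default_rng(seed)
    n = len(traj)
    stack = np.empty((n_boot,) + grid.shape)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bt = ProjectedTrajectory(
            points=traj.points[idx],
            weights=None if traj.weights is None else traj.weights[idx],
        )
        stack[b] = estimate_surface(bt, grid=grid, temperature=temperature, lambda_tv=lambda_tv).delta_g
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        lo = np.nanpercentile(stack, ci[0], axis=0)
        hi = np.nanpercentile(stack, ci[1], axis=0)
    base.ci_low, base.ci_high = lo, hi
    return base


@dataclass
class Minimum:
    """A labelled local minimum of the energy surface."""

    label: str
    location: tuple[float, float]
    delta_g: float
    cell: tuple[int, int]
    depth: float  # persistence: saddle level at basin merge minus dG


def find_minima(
    surface: EnergySurface,
    min_depth: float = 0.0,
    min_separation: int = 1,
) -> list[Minimum]:
    """Persistence-filtered local minima of the free-energy surface.

    Strict 8-neighbourhood minima are ranked by basin persistence
    (union-find sweep in ascending dG: a basin's depth is the level at
    which it merges into a deeper one, minus its minimum). Minima
    shallower than ``min_depth`` or within ``min_separation`` cells of a
    deeper minimum are dropped; survivors are labelled by Greek letters
    in ascending dG.
    """
    g = surface.delta_g
    valid = np.isfinite(g)
    nx, ny = g.shape
    order = np.argsort(np.where(valid, g, np.inf), axis=None)
    order = order[: valid.sum()]
    parent = {}
    basin_min = {}  # root -> (g_min, cell)
    depth = {}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    minima_cells = []
    for flat in order:
        i, j = divmod(int(flat), ny)
        nbrs = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and (a, b) in parent:
                    nbrs.append(find((a, b)))
        parent[(i, j)] = (i, j)
        roots = sorted(set(nbrs), key=lambda r: basin_min[r][0])
        if not roots:
            basin_min[(i, j)] = (g[i, j], (i, j))
            minima_cells.append((i, j))
        else:
            main = roots[0]
            parent[(i, j)] = main
            for r in roots[1:]:
                # shallower basin r merges into main at level g[i, j]
                depth[basin_min[r][1]] = g[i, j] - basin_min[r][0]
                parent[r] = main
    # surviving roots persist to the top of the surface
    top = np.nanmax(np.where(valid, g, np.nan))
    for c in minima_cells:
        if c not in depth:
            depth[c] = top - g[c]
    # strictness: drop plateau "minima" that tie a neighbour
    out = []
    for c in minima_cells:
        i, j = c
        nb = [
            g[a, b]
            for a in range(max(0, i - 1), min(nx, i + 2))
            for b in range(max(0, j - 1), min(ny, j + 2))
            if (a, b) != c and np.isfinite(g[a, b])
        ]
        if nb and all(g[i, j] < v for v in nb) and depth[c] >= min_depth and depth[c] > 0:
            out.append(c)
    out.sort(key=lambda c: g[c])
    kept: list[tuple[int, int]] = []
    for c in out:
        if all(max(abs(c[0] - k[0]), abs(c[1] - k[1])) > min_separation for k in kept):
            kept.append(c)
    return [
        Minimum(
            label=GREEK[k] if k < len(GREEK) else f"min{k}",
            location=(float(surface.grid.xc[c[0]]), float(surface.grid.yc[c[1]])),
            delta_g=float(g[c]),
            cell=c,
            depth=float(depth[c]),
        )
        for k, c in enumerate(kept)
    ]
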