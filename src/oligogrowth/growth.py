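"""Anisotropic growth model for oligomer collision cross-sections.

For a densely packed, convex aggregate of ``n`` identical subunits the
rotationally averaged projected area (the CCS measured by ion mobility)
follows

    CCS(n) = sigma * Omega0 * n**(2/3)

where ``Omega0`` is the monomer CCS and ``sigma`` is a dimensionless
distortion factor: 1 for spherical growth, larger for increasingly
ellipsoidal assemblies. Writing the assembly as an ellipsoid whose
semi-axes are i-fold and j-fold its shortest axis (and the monomer
likewise i0-, j0-fold), sigma has the closed form implemented in
:func:`distortion_factor`, built on the Knud Thomsen power-mean
approximation of the ellipsoid surface area (exponent p = 1.6075) and
Cauchy's theorem (mean shadow of a convex body = surface area / 4).

This module provides the forward model, least-squares trendline fitting
against measured CCS series, inversion of the sigma contour (which
axis-ratio combinations produce a given sigma), and a Monte-Carlo
projected-area oracle used to validate the ellipsoid algebra.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares, minimize_scalar
from scipy.special import ellipeinc, ellipkinc

KNUD_THOMSEN_P = 1.6075


class FitError(ValueError):
    """Raised when a CCS series cannot support the requested fit."""


# ---------------------------------------------------------------------------
# ellipsoid geometry
# ---------------------------------------------------------------------------


def knud_thomsen_area(a: float, b: float, c: float, p: float = KNUD_THOMSEN_P) -> float:
    """Power-mean approximation of the ellipsoid surface area.

    S ~= 4*pi*((a^p b^p + a^p c^p + b^p c^p)/3)^(1/p); exact for a sphere,
    within ~1.1% of the true area for all axis ratios at p = 1.6075.
    """
    if a <= 0 or b <= 0 or c <= 0:
        raise ValueError("semi-axes must be positive")
    return 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


def ellipsoid_area_exact(a: float, b: float, c: float) -> float:
    """Exact ellipsoid surface area via Legendre incomplete elliptic integrals."""
    if a <= 0 or b <= 0 or c <= 0:
        raise ValueError("semi-axes must be positive")
    a, b, c = sorted((a, b, c), reverse=True)
    if a - c < 1e-12 * a:
        return 4.0 * np.pi * a * a
    if b - c < 1e-12 * b:  # prolate spheroid closed form avoids m=1 edge
        e = np.sqrt(1.0 - (c / a) ** 2)
        return 2.0 * np.pi * c * c * (1.0 + (a / (c * e)) * np.arcsin(e))
    phi = np.arccos(c / a)
    m = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))
    s = np.sin(phi)
    return float(
        2.0 * np.pi * c * c
        + (2.0 * np.pi * a * b / s)
        * (ellipeinc(phi, m) * s * s + ellipkinc(phi, m) * np.cos(phi) ** 2)
    )


def optimal_power_exponent(
    ratio_max: float = 1e4,
    n_grid: int = 60,
    bounds: tuple[float, float] = (1.3, 2.0),
    xatol: float = 1e-8,
) -> tuple[float, float]:
    """Minimax-optimal exponent for the three-term power-mean area formula.

    Scans semi-axis ratios (a=1, b, c geometrically spaced in
    [1, ratio_max]) and finds the scalar exponent p minimizing the
    worst-case relative error of :func:`knud_thomsen_area` against the
    exact area. Returns (p, max relative error at p). The default wide
    domain covers the full ellipsoid shape family to convergence and
    reproduces the canonical constant p = 1.6075 (max error ~1.061%);
    restricting ratio_max trades the exponent for a smaller worst-case
    error on the restricted family (e.g. ratio_max=10 gives ~1.602,
    max error ~0.83%).
    """
    bs = np.geomspace(1.0, ratio_max, n_grid)
    grid = [(1.0, b, c) for k, b in enumerate(bs) for c in bs[k:]]
    exact = np.array([ellipsoid_area_exact(*g) for g in grid])

    def max_rel_err(p: float) -> float:
        approx = np.array([knud_thomsen_area(*g, p=p) for g in grid])
        return float(np.max(np.abs(approx / exact - 1.0)))

    res = minimize_scalar(max_rel_err, bounds=bounds, method="bounded", options={"xatol": xatol})
    return float(res.x), float(res.fun)


@dataclass
class EllipsoidShape:
    """Axis-ratio description of assembly (i, j) and monomer (i0, j0) ellipsoids."""

    i: float
    j: float
    i0: float = 1.0
    j0: float = 1.0
    p: float = KNUD_THOMSEN_P

    def __post_init__(self):
        if min(self.i, self.j, self.i0, self.j0) <= 0:
            raise ValueError("axis folds must be positive")
        if self.p <= 1:
            raise ValueError("power-mean exponent must exceed 1")


def distortion_factor(
    i: float, j: float, i0: float = 1.0, j0: float = 1.0, p: float = KNUD_THOMSEN_P
) -> float:
    """Distortion factor sigma of an (1, i, j) assembly built from (1, i0, j0) monomers.

    sigma = (i0*j0/(i*j))**(2/3)
            * (i**p + j**p + (i*j)**p)**(1/p)
            / (i0**p + j0**p + (i0*j0)**p)**(1/p)

    Equals 1 for spheres assembling into a sphere and exceeds 1 for any
    aspherical assembly of spherical monomers.
    """
    shape = EllipsoidShape(i=i, j=j, i0=i0, j0=j0, p=p)
    i, j, i0, j0, p = shape.i, shape.j, shape.i0, shape.j0, shape.p
    num = (i**p + j**p + (i * j) ** p) ** (1.0 / p)
    den = (i0**p + j0**p + (i0 * j0) ** p) ** (1.0 / p)
    return float((i0 * j0 / (i * j)) ** (2.0 / 3.0) * num / den)


def mean_projected_area_mc(
    a: float, b: float, c: float, n_orientations: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo rotationally averaged shadow area of an ellipsoid.

    For a direction u the shadow of the ellipsoid diag(a,b,c) is the
    ellipse of area pi*sqrt((b c u_x)^2 + (a c u_y)^2 + (a b u_z)^2);
    averaging over uniform u on the sphere gives the CCS-style mean
    projected area. Returns (mean, standard error). By Cauchy's theorem
    the mean equals surface area / 4, making this an independent oracle
    for the power-mean surface formula.
    """
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    if n_orientations < 100:
        raise ValueError("need at least 100 orientations")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_orientations, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    shadows = np.pi * np.sqrt(
        (b * c * u[:, 0]) ** 2 + (a * c * u[:, 1]) ** 2 + (a * b * u[:, 2]) ** 2
    )
    return float(shadows.mean()), float(shadows.std(ddof=1) / np.sqrt(n_orientations))


# ---------------------------------------------------------------------------
# CCS series and trendline fitting
# ---------------------------------------------------------------------------


@dataclass
class CCSMeasurement:
    """One ion-mobility point: oligomer number, charge, CCS, relative intensity."""

    n: int
    z: int
    ccs: float
    intensity: float = 1.0

    def __post_init__(self):
        if self.n < 1 or self.z < 1:
            raise ValueError("oligomer number and charge must be >= 1")
        if self.ccs <= 0:
            raise ValueError("CCS must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass
class CCSSeries:
    """A labelled collection of CCS measurements across oligomer numbers."""

    measurements: list[CCSMeasurement] = field(default_factory=list)
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.n, m.z, m.ccs, m.intensity) for m in self.measurements],
            columns=["n", "z", "ccs_A2", "intensity"],
        )

    def most_abundant(self) -> "CCSSeries":
        """Per oligomer number, keep the highest-intensity measurement."""
        best: dict[int, CCSMeasurement] = {}
        for m in self.measurements:
            if m.n not in best or m.intensity > best[m.n].intensity:
                best[m.n] = m
        return CCSSeries(
            measurements=[best[n] for n in sorted(best)], label=self.label
        )

    def restrict_n(self, n_min: int, n_max: int) -> "CCSSeries":
        return CCSSeries(
            measurements=[m for m in self.measurements if n_min <= m.n <= n_max],
            label=self.label,
        )

    def monomer_ccs(self) -> float | None:
        """Most abundant n=1 CCS, or None if no monomer point exists."""
        ones = [m for m in self.measurements if m.n == 1]
        if not ones:
            return None
        return max(ones, key=lambda m: m.intensity).ccs


def read_ccs_series(path, label: str | None = None) -> CCSSeries:
    """Read a delimited CCS table with header ``n,z,ccs_A2,intensity``; '#' comments."""
    df = pd.read_csv(path, comment="#")
    required = {"n", "z", "ccs_A2", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"CCS series file must have columns {sorted(required)}")
    ms = [
        CCSMeasurement(int(r.n), int(r.z), float(r.ccs_A2), float(r.intensity))
        for r in df.itertuples()
    ]
    return CCSSeries(measurements=ms, label=label or Path(str(path)).stem)


def write_ccs_series(series: CCSSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def predict_ccs(n, sigma: float, omega0: float):
    """CCS(n) = sigma * Omega0 * n^(2/3)."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("oligomer number must be >= 1")
    if sigma <= 0 or omega0 <= 0:
        raise ValueError("sigma and Omega0 must be positive")
    out = sigma * omega0 * n ** (2.0 / 3.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class GrowthFit:
    """Result of fitting a growth trendline to a CCS series."""

    model: str
    sigma: float | None = None
    omega0: float | None = None
    slope: float | None = None
    intercept: float | None = None
    residuals: np.ndarray | None = None
    rmse: float = float("nan")
    n_points: int = 0

    def predict(self, n):
        n = np.asarray(n, dtype=float)
        if self.model == "linear":
            return self.slope * n + self.intercept
        return predict_ccs(n, self.sigma if self.model == "anisotropic" else 1.0, self.omega0)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "sigma": self.sigma,
            "omega0": self.omega0,
            "slope": self.slope,
            "intercept": self.intercept,
            "rmse": self.rmse,
            "n_points": self.n_points,
        }


def fit_growth(
    series: CCSSeries,
    model: str = "anisotropic",
    omega0: float | str | None = None,
    selection: str = "most_abundant",
    n_range: tuple[int, int] | None = None,
    weighted: bool = False,
    omega0_bound_frac: float = 0.2,
) -> GrowthFit:
    """Least-squares fit of a growth trendline to measured CCS values.

    model:
      'linear'       CCS = slope*n + intercept
      'isotropic'    CCS = Omega0 * n^(2/3)           (sigma fixed at 1)
      'anisotropic'  CCS = sigma * Omega0 * n^(2/3)

    omega0 (anisotropic only): a number fixes the monomer CCS and leaves
    sigma as the single free parameter; None uses the series' measured
    n=1 point if present (error otherwise); 'free' co-fits both with
    Omega0 bounded to +-omega0_bound_frac of the monomer reference.

    selection='most_abundant' keeps, per oligomer number, only the
    highest-intensity conformer before fitting; 'all' keeps everything.
    """
    if selection == "most_abundant":
        work = series.most_abundant()
    elif selection == "all":
        work = CCSSeries(measurements=list(series.measurements), label=series.label)
    else:
        raise ValueError("selection must be 'most_abundant' or 'all'")
    if n_range is not None:
        work = work.restrict_n(*n_range)
    pts = work.measurements
    if not pts:
        raise FitError("no measurements after selection")
    n = np.array([m.n for m in pts], dtype=float)
    y = np.array([m.ccs for m in pts])
    w = np.array([m.intensity for m in pts]) if weighted else np.ones(len(pts))
    distinct = len(set(int(v) for v in n))

    def _rmse(res):
        return float(np.sqrt(np.mean(res**2)))

    if model == "linear":
        if distinct < 2:
            raise FitError("linear fit needs >= 2 distinct oligomer numbers")
        A = np.column_stack((n, np.ones_like(n))) * np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(A, y * np.sqrt(w), rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
        res = y - (slope * n + intercept)
        return GrowthFit("linear", slope=slope, intercept=intercept,
                         residuals=res, rmse=_rmse(res), n_points=len(pts))

    x = n ** (2.0 / 3.0)
    if model == "isotropic":
        if distinct < 1:
            raise FitError("isotropic fit needs >= 1 point")
        om = float(np.sum(w * x * y) / np.sum(w * x * x))
        res = y - om * x
        return GrowthFit("isotropic", sigma=1.0, omega0=om,
                         residuals=res, rmse=_rmse(res), n_points=len(pts))

    if model != "anisotropic":
        raise ValueError("model must be 'linear', 'isotropic' or 'anisotropic'")
    if distinct < 1:
        raise FitError("anisotropic fit needs >= 1 point")

    if omega0 == "free":
        ref = series.monomer_ccs()
        if ref is None:
            raise FitError("omega0='free' needs a measured n=1 point as reference")
        lo, hi = ref * (1 - omega0_bound_frac), ref * (1 + omega0_bound_frac)
        # sigma and Omega0 only enter through their product, so the
        # co-fit is a ridge; a weak anchor pulls Omega0 toward the
        # measured monomer CCS to pick a unique point on it.
        anchor = 1e-3 * np.sqrt(np.sum(w * y**2))

        def resid(theta):
            s, om = theta
            return np.append(np.sqrt(w) * (y - s * om * x), anchor * (om / ref - 1.0))

        sol = least_squares(resid, x0=[1.0, ref], bounds=([1e-6, lo], [np.inf, hi]))
        sig, om = float(sol.x[0]), float(sol.x[1])
    else:
        if omega0 is None:
            omega0 = series.monomer_ccs()
            if omega0 is None:
                raise FitError("no n=1 point in series; pass omega0 explicitly")
        om = float(omega0)
        sig = float(np.sum(w * x * y) / np.sum(w * x * x)) / om
    res = y - sig * om * x
    return GrowthFit("anisotropic", sigma=sig, omega0=om,
                     residuals=res, rmse=_rmse(res), n_points=len(pts))


# ---------------------------------------------------------------------------
# sigma contour inversion
# ---------------------------------------------------------------------------


def solve_axis_ratios(
    sigma_target: float,
    i_grid: Sequence[float],
    i0: float = 1.0,
    j0: float = 1.0,
    p: float = KNUD_THOMSEN_P,
    j_max: float = 50.0,
    tol: float = 1e-10,
) -> list[tuple[float, float]]:
    """All (i, j) axis-ratio pairs on the sigma contour, per i in i_grid.

    For each fixed i, sigma(i, j) over j in [1, j_max] has a single
    interior minimum; a root is bracketed and bisected on each monotone
    branch. Pairs are verified by re-evaluation to |d sigma| < 1e-8;
    branches on which the target is unattainable simply contribute no
    pair. The sigma = 1 contour of spherical monomers degenerates to the
    single point (1, 1).
    """
    out: list[tuple[float, float]] = []
    for i in i_grid:
        if i < 1:
            raise ValueError("i grid values must be >= 1")
        f = lambda j: distortion_factor(i, j, i0=i0, j0=j0, p=p) - sigma_target
        mres = minimize_scalar(
            lambda j: distortion_factor(i, j, i0=i0, j0=j0, p=p),
            bounds=(1.0, j_max), method="bounded",
        )
        j_min = float(mres.x)
        for lo, hi in ((1.0, j_min), (j_min, j_max)):
            if hi - lo < 1e-12:
                continue
            flo, fhi = f(lo), f(hi)
            if abs(flo) < tol:
                root = lo
            elif abs(fhi) < tol:
                root = hi
            elif flo * fhi < 0:
                root = brentq(f, lo, hi, xtol=1e-12)
            else:
                continue
            pair = (float(i), float(root))
            if abs(distortion_factor(*pair, i0=i0, j0=j0, p=p) - sigma_target) < 1e-8:
                if not any(abs(pair[1] - q[1]) < 1e-4 and abs(pair[0] - q[0]) < 1e-4 for q in out):
                    out.append(pair)
    return out


def eccentricity_from_sigma(
    sigma_target: float, family: str = "prolate", p: float = KNUD_THOMSEN_P
) -> float:
    """Eccentricity of the spheroid with distortion factor sigma.

    family='prolate' solves sigma(1, j) = target (axes 1:1:j);
    family='oblate' solves sigma(i, i) = target (axes 1:i:i).
    Utility for relating sigma to the familiar spheroid eccentricity;
    general triaxial shapes are not reducible to one eccentricity.
    """
    if sigma_target < 1:
        raise ValueError("sigma must be >= 1 for spherical monomers")
    if sigma_target == 1:
        return 0.0
    if family == "prolate":
        f = lambda j: distortion_factor(1.0, j, p=p) - sigma_target
        j = brentq(f, 1.0 + 1e-9, 1e3)
        return float(np.sqrt(1.0 - 1.0 / j**2))
    if family == "oblate":
        f = lambda i: distortion_factor(i, i, p=p) - sigma_target
        i = brentq(f, 1.0 + 1e-9, 1e3)
        return float(np.sqrt(1.0 - 1.0 / i**2))
    raise ValueError("family must be 'prolate' or 'oblate'")
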