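"""Monomer conformation analysis: per-monomer Rg, clustering, PCA.

Monomer compactness is tracked by the mass-weighted radius of gyration,
computed per monomer (chain) per trajectory frame. Free-monomer
ensembles are partitioned by 1D k-means on Rg into compact / extended /
twisted / unfolded classes (ascending centroid order, k = 4), and
monomers inside oligomers - too few per frame to cluster reliably - are
classified against the fixed boundaries halfway between consecutive
centroids. Trajectory PCA over superposed residue-centre coordinates
yields the 2D intrinsic coordinates used for free-energy landscapes,
and the squared loadings of the leading eigenvectors give per-residue
contributions to the collective assembly motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import Structure, radius_of_gyration

CLASS_NAMES_K4 = ("compact", "extended", "twisted", "unfolded")


# ---------------------------------------------------------------------------
# per-monomer Rg
# ---------------------------------------------------------------------------


def per_monomer_rg(
    frames: Sequence[Structure],
    times: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Mass-weighted Rg of every monomer (chain) in every frame.

    All frames must share the same monomer partition (chain ids). Returns
    a tidy frame with columns ``frame, time_ns, monomer, rg_A``.
    """
    if not frames:
        raise ValueError("no frames")
    partition = list(frames[0].chains.keys())
    rows = []
    for f, s in enumerate(frames):
        if list(s.chains.keys()) != partition:
            raise ValueError(f"monomer partition changes at frame {f}")
        t = times[f] if times is not None else float(f)
        for cid, mono in zip(partition, s.monomers()):
            rows.append((f, t, cid, radius_of_gyration(mono)))
    return pd.DataFrame(rows, columns=["frame", "time_ns", "monomer", "rg_A"])


def frame_rg_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Per-frame mean and standard deviation of monomer Rg."""
    g = records.groupby("frame")["rg_A"]
    out = pd.DataFrame({"mean_rg_A": g.mean(), "sd_rg_A": g.std(ddof=0)})
    out["time_ns"] = records.groupby("frame")["time_ns"].first()
    return out.reset_index()


# ---------------------------------------------------------------------------
# clustering and classification
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """1D k-means model on Rg with fixed midpoint class boundaries."""

    k: int
    centroids: np.ndarray  # ascending, Angstrom
    boundaries: np.ndarray  # k-1 midpoints
    abundances: np.ndarray  # fractions, sum 1
    class_names: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "centroids_A": self.centroids.tolist(),
            "boundaries_A": self.boundaries.tolist(),
            "abundances": self.abundances.tolist(),
            "class_names": list(self.class_names),
        }


def cluster_free_monomer(
    rg_values: Sequence[float],
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterModel:
    """1D k-means (k-means++, ``n_init`` restarts) over free-monomer Rg values.

    Clusters are sorted by centroid; for k = 4 they are named compact,
    extended, twisted, unfolded. Boundaries are consecutive-centroid
    midpoints, which is what fixed-boundary classification uses.
    """
    rg = np.asarray(rg_values, dtype=float).reshape(-1, 1)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(rg)) < k:
        raise ValueError("fewer distinct Rg values than clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(rg)
    centroids = km.cluster_centers_.ravel()
    order = np.argsort(centroids)
    centroids = centroids[order]
    counts = np.array([(labels == c).sum() for c in order], dtype=float)
    names = CLASS_NAMES_K4 if k == 4 else tuple(f"class{c}" for c in range(k))
    return ClusterModel(
        k=k,
        centroids=centroids,
        boundaries=(centroids[:-1] + centroids[1:]) / 2.0,
        abundances=counts / counts.sum(),
        class_names=names,
    )


def classify_by_boundaries(rg: float, model: ClusterModel) -> str:
    """Class of the boundary interval containing rg; boundary ties go low."""
    idx = int(np.searchsorted(model.boundaries, rg, side="left"))
    return model.class_names[idx]


def classify_records(records: pd.DataFrame, model: ClusterModel) -> pd.DataFrame:
    out = records.copy()
    out["class"] = [classify_by_boundaries(v, model) for v in out["rg_A"]]
    return out


def class_fractions(records: pd.DataFrame, model: ClusterModel) -> pd.DataFrame:
    """Per-frame fraction of monomers in each conformational class."""
    labelled = classify_records(records, model)
    frac = (
        labelled.groupby("frame")["class"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    for name in model.class_names:
        if name not in frac.columns:
            frac[name] = 0.0
    return frac[list(model.class_names)].reset_index()


# ---------------------------------------------------------------------------
# trajectory PCA
# ---------------------------------------------------------------------------


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation minimising RMSD of P (centred) onto Q (centred)."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def residue_center_coords(structure: Structure) -> np.ndarray:
    """One geometric-centre position per residue, (n_residues, 3)."""
    return np.array([r.coords().mean(axis=0) for r in structure.residues])


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # (3R, n_modes) columns
    projection: np.ndarray  # (n_frames, 2)
    mean: np.ndarray
    n_sites: int


def trajectory_pca(
    frames: Sequence[Structure],
    selection: str = "residue_centers",
    superpose: bool = True,
) -> PCAResult:
    """Covariance PCA of superposed Cartesian coordinates across frames.

    selection='residue_centers' uses one site per residue (robust to
    coarse or atomistic input); 'atoms' uses every atom. Frames are
    least-squares superposed (Kabsch) to the first frame to remove
    rigid-body motion before the covariance is formed. The projection is
    onto the top two eigenvectors - the intrinsic coordinates consumed
    by the landscape module.
    """
    if len(frames) < 3:
        raise ValueError("need at least 3 frames for PCA")
    if selection == "residue_centers":
        coord_sets = [residue_center_coords(s) for s in frames]
    elif selection == "atoms":
        coord_sets = [s.coords() for s in frames]
    else:
        raise ValueError("selection must be 'residue_centers' or 'atoms'")
    nsite = coord_sets[0].shape[0]
    if any(c.shape[0] != nsite for c in coord_sets):
        raise ValueError("site count changes between frames")
    ref = coord_sets[0] - coord_sets[0].mean(axis=0)
    X = np.empty((len(frames), nsite * 3))
    for f, c in enumerate(coord_sets):
        if superpose:
            cc = c - c.mean(axis=0)
            if f > 0:
                cc = cc @ _kabsch(cc, ref).T
        else:
            cc = c  # raw coordinates: caller controls the frame
        X[f] = cc.ravel()
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (len(frames) - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    proj = Xc @ vecs[:, :2]
    return PCAResult(eigenvalues=vals, eigenvectors=vecs, projection=proj, mean=mean, n_sites=nsite)


@dataclass
class ContributionTable:
    """Per-residue percentage contributions to the leading PCA modes."""

    contributions: dict[int, float]  # residue index -> %
    eigenvalues: np.ndarray
    n_components: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.contributions.items()), columns=["residue", "contribution_pct"]
        )


def residue_contributions(
    pca: PCAResult,
    residue_of_site: Sequence[int] | None = None,
    n_components: int = 2,
) -> ContributionTable:
    """Eigenvalue-weighted squared loadings, aggregated per residue.

    contribution(r) = sum_{k<=K} lambda_k * sum_{coords in r} v_{k,c}^2
                      / sum_{k<=K} lambda_k * 100%.

    ``residue_of_site`` maps each PCA site to a residue index (identity
    by default, matching 'residue_centers' selection). Contributions sum
    to 100%.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if residue_of_site is None:
        residue_of_site = list(range(pca.n_sites))
    if len(residue_of_site) != pca.n_sites:
        raise ValueError("residue mapping does not cover all PCA sites")
    lam = pca.eigenvalues[:n_components]
    V = pca.eigenvectors[:, :n_components]  # (3R, K)
    per_coord = (V**2) * lam[None, :]  # weight each mode
    per_site = per_coord.reshape(pca.n_sites, 3, -1).sum(axis=(1, 2))
    total = per_site.sum()
    if total <= 0:
        raise ValueError("no variance in the requested components")
    contrib: dict[int, float] = {}
    for site, res in enumerate(residue_of_site):
        contrib[res] = contrib.get(res, 0.0) + float(per_site[site] / total * 100.0)
    return ContributionTable(contributions=contrib, eigenvalues=pca.eigenvalues, n_components=n_components)
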