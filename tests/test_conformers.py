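"""Monomer conformation tracking, clustering, PCA, residue contributions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oligogrowth.conformers import (
    classify_by_boundaries,
    class_fractions,
    cluster_free_monomer,
    frame_rg_stats,
    per_monomer_rg,
    residue_contributions,
    trajectory_pca,
)
from oligogrowth.core import Residue, Structure, radius_of_gyration
from oligogrowth.synth import synth_assembly_trajectory

from conftest import make_bead


def chain_structure(chains):
    """chains: dict chain_id -> list of points; one residue per chain."""
    residues = []
    serial = 0
    for idx, (cid, pts) in enumerate(chains.items(), start=1):
        atoms = []
        for p in pts:
            serial += 1
            atoms.append(make_bead(serial, p, chain=cid, residue_index=idx))
        residues.append(Residue("GLY", idx, atoms))
    return Structure(residues=residues)


class TestPerMonomerRg:
    def test_identical_monomers_zero_sd(self):
        pts = [(0, 0, 0), (2, 0, 0), (4, 0, 0)]
        shifted = [(10, 10, 10), (12, 10, 10), (14, 10, 10)]
        s = chain_structure({"A": pts, "B": shifted})
        rec = per_monomer_rg([s, s])
        stats = frame_rg_stats(rec)
        assert np.allclose(stats["sd_rg_A"], 0.0)
        assert stats["mean_rg_A"].iloc[0] == pytest.approx(
            radius_of_gyration(s.monomers()[0])
        )

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        frames = []
        for _ in range(2):
            frames.append(
                chain_structure({"A": rng.normal(size=(5, 3)), "B": rng.normal(size=(5, 3)) * 2})
            )
        rec = per_monomer_rg(frames)
        for f, s in enumerate(frames):
            for cid, mono in zip(["A", "B"], s.monomers()):
                expect = radius_of_gyration(mono)
                got = rec[(rec.frame == f) & (rec.monomer == cid)]["rg_A"].iloc[0]
                assert got == pytest.approx(expect, rel=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        pts = {"A": rng.normal(size=(6, 3)), "B": rng.normal(size=(6, 3))}
        s0 = chain_structure(pts)
        R = Rotation.random(random_state=3).as_matrix()
        s1 = chain_structure({k: v @ R.T for k, v in pts.items()})
        r0 = per_monomer_rg([s0, s0])
        r1 = per_monomer_rg([s1, s1])
        np.testing.assert_allclose(r0["rg_A"], r1["rg_A"], rtol=1e-10)

    def test_partition_mismatch_rejected(self):
        s1 = chain_structure({"A": [(0, 0, 0), (1, 0, 0)]})
        s2 = chain_structure({"B": [(0, 0, 0), (1, 0, 0)]})
        with pytest.raises(ValueError, match="partition"):
            per_monomer_rg([s1, s2])


class TestClustering:
    def test_two_well_separated_groups(self):
        model = cluster_free_monomer([1, 1, 1, 10, 10, 10], k=2, seed=0)
        np.testing.assert_allclose(model.centroids, [1.0, 10.0])
        np.testing.assert_allclose(model.boundaries, [5.5])
        np.testing.assert_allclose(model.abundances, [0.5, 0.5])

    def test_four_gaussian_recovery_against_truth(self):
        rng = np.random.default_rng(5)
        means = np.array([9.0, 11.0, 13.0, 16.0])
        weights = np.array([0.4557, 0.3451, 0.1237, 0.0755])
        counts = rng.multinomial(1000, weights)
        vals = np.concatenate(
            [rng.normal(m, 0.3, k) for m, k in zip(means, counts)]
        )
        model = cluster_free_monomer(vals, k=4, seed=0, n_init=10)
        np.testing.assert_allclose(model.centroids, means, atol=0.2)
        np.testing.assert_allclose(model.abundances, counts / 1000, atol=0.03)
        assert model.class_names == ("compact", "extended", "twisted", "unfolded")

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(10, 2, 300)
        a = cluster_free_monomer(vals, k=4, seed=7)
        b = cluster_free_monomer(vals, k=4, seed=7)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        np.testing.assert_array_equal(a.abundances, b.abundances)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            cluster_free_monomer([1.0, 1.0, 2.0], k=3)


class TestClassification:
    def model(self):
        return cluster_free_monomer([9] * 10 + [11] * 10 + [13] * 10 + [16] * 10, k=4, seed=0)

    def test_below_first_boundary_is_compact(self):
        assert classify_by_boundaries(8.0, self.model()) == "compact"

    def test_boundary_tie_goes_to_lower_class(self):
        m = self.model()
        assert classify_by_boundaries(float(m.boundaries[0]), m) == "compact"
        assert classify_by_boundaries(float(m.boundaries[0]) + 1e-9, m) == "extended"

    def test_fractions_sum_to_one_per_frame(self):
        frames, _ = synth_assembly_trajectory(8, 6, rg_drift={"kind": "monotone_rise", "rg_start": 9.0, "rg_end": 16.0}, seed=2)
        rec = per_monomer_rg(frames)
        frac = class_fractions(rec, self.model())
        sums = frac[list(self.model().class_names)].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_extended_fraction_nondecreasing_on_drifting_assembly(self):
        """As monomers extend during assembly, the beyond-compact fraction
        must not decrease (drift built into the generator)."""
        m = self.model()
        frames, _ = synth_assembly_trajectory(
            12, 8, rg_drift={"kind": "monotone_rise", "rg_start": 9.0, "rg_end": 16.0, "spread_start": 0.5, "spread_end": 0.5}, seed=3
        )
        rec = per_monomer_rg(frames)
        frac = class_fractions(rec, m)
        beyond_compact = 1.0 - frac["compact"].to_numpy()
        assert np.all(np.diff(beyond_compact) >= -1e-12)


class TestTrajectoryPCA:
    def line_motion_frames(self, n=6):
        """Frames differing only by stretching along x of one site."""
        frames = []
        for f in range(n):
            pts = {"A": [(0.0, 0, 0), (3.0 + 0.5 * f, 0, 0), (0, 3, 0), (0, 0, 3)]}
            frames.append(chain_structure(pts))
        return frames

    def test_rank_one_motion(self):
        pca = trajectory_pca(self.line_motion_frames(), selection="atoms", superpose=False)
        assert pca.eigenvalues[0] > 0
        np.testing.assert_allclose(pca.eigenvalues[1:], 0.0, atol=1e-18)

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(4)
        frames = [chain_structure({"A": rng.normal(size=(5, 3))}) for _ in range(8)]
        pca = trajectory_pca(frames, selection="atoms", superpose=False)
        Xc = np.array([f.coords().ravel() for f in frames])
        Xc -= Xc.mean(axis=0)
        total_var = (Xc**2).sum() / (len(frames) - 1)
        assert pca.eigenvalues.sum() == pytest.approx(total_var, rel=1e-9)

    def test_interpolated_trajectory_projects_to_segment(self):
        a = np.array([(0, 0, 0), (4, 0, 0), (0, 4, 0), (0, 0, 4)], float)
        b = a + np.array([(0, 0, 0), (2, 1, 0), (1, 0, 2), (0, 2, 1)], float)
        frames = [chain_structure({"A": a + t * (b - a)}) for t in np.linspace(0, 1, 7)]
        pca = trajectory_pca(frames, selection="atoms", superpose=False)
        # second projection coordinate is ~0: motion is one-dimensional
        assert np.abs(pca.projection[:, 1]).max() < 1e-9 * np.abs(pca.projection[:, 0]).max() + 1e-12
        d = np.diff(pca.projection[:, 0])
        assert np.allclose(d, d[0], rtol=1e-6)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            trajectory_pca(self.line_motion_frames(2))


class TestResidueContributions:
    def frames_with_one_moving_residue(self):
        frames = []
        for f in range(6):
            residues = []
            serial = 0
            for ridx in range(1, 4):
                atoms = []
                base = np.array([ridx * 10.0, 0, 0])
                wiggle = np.array([0.0, 0.5 * f if ridx == 2 else 0.0, 0.0])
                for k in range(2):
                    serial += 1
                    atoms.append(make_bead(serial, base + wiggle + [0, 0, k], residue_index=ridx))
                residues.append(Residue("GLY", ridx, atoms))
            frames.append(Structure(residues=residues))
        return frames

    def test_localized_mode_dominates(self):
        pca = trajectory_pca(self.frames_with_one_moving_residue(), superpose=False)
        table = residue_contributions(pca, n_components=1)
        assert table.contributions[1] > 99.0
        assert sum(table.contributions.values()) == pytest.approx(100.0, abs=1e-6)

    def test_two_residue_amplitude_ratio(self):
        # amplitudes 2:1 in a single mode -> squared contributions 80/20
        frames = []
        for f in range(7):
            t = float(f)
            residues = []
            serial = 0
            for ridx, amp in ((1, 2.0), (2, 1.0)):
                serial += 1
                atoms = [make_bead(serial, (ridx * 20.0 + amp * t, 0, 0), residue_index=ridx)]
                residues.append(Residue("GLY", ridx, atoms))
            frames.append(Structure(residues=residues))
        pca = trajectory_pca(frames, selection="atoms", superpose=False)
        table = residue_contributions(pca, n_components=1)
        assert table.contributions[0] == pytest.approx(80.0, abs=0.5)
        assert table.contributions[1] == pytest.approx(20.0, abs=0.5)

    def test_permutation_equivariance(self):
        pca = trajectory_pca(self.frames_with_one_moving_residue(), superpose=False)
        t1 = residue_contributions(pca, residue_of_site=[0, 1, 2], n_components=2)
        t2 = residue_contributions(pca, residue_of_site=[2, 0, 1], n_components=2)
        assert t1.contributions[1] == pytest.approx(t2.contributions[0], rel=1e-12)

    def test_contributions_always_sum_to_100(self):
        rng = np.random.default_rng(8)
        frames = [
            chain_structure({c: rng.normal(size=(2, 3)) + off for c, off in
                             zip("ABCD", [(0, 0, 0), (10, 0, 0), (0, 10, 0), (0, 0, 10)])})
            for _ in range(9)
        ]
        pca = trajectory_pca(frames)
        for k in (1, 2, 3):
            t = residue_contributions(pca, n_components=k)
            assert sum(t.contributions.values()) == pytest.approx(100.0, abs=1e-6)

    def test_bad_mapping_rejected(self):
        pca = trajectory_pca(self.frames_with_one_moving_residue(), superpose=False)
        with pytest.raises(ValueError):
            residue_contributions(pca, residue_of_site=[0, 1])
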