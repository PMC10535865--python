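"""Hydrogen-bond geometry, occupancy bookkeeping and RMSD."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from pgpkit.trajectory import (
    Trajectory,
    TrajectoryError,
    detect_hbonds,
    hbond_count_series,
    hbond_occupancy,
    rmsd,
    rmsd_series,
)

from conftest import toy_trajectory


def _single_geometry(d_a: float, angle_deg: float) -> Trajectory:
    """One D-H/A triplet at a prescribed D-A distance and D-H...A angle."""
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    # place A in the xy-plane at the requested angle from H
    theta = np.radians(180.0 - angle_deg)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # choose |H->A| so that |D->A| = d_a
    from scipy.optimize import brentq

    def f(r):
        return np.linalg.norm(h + r * direction) - d_a

    r = brentq(f, 1e-6, 10.0)
    a = h + r * direction
    atoms = pd.DataFrame(
        {
            "serial": [1, 2, 3],
            "name": ["N", "H", "O"],
            "resname": ["GLN", "GLN", "LIG"],
            "resid": [725, 725, 1],
        }
    )
    coords = np.stack([d, h, a])[None, :, :]
    return Trajectory(atoms=atoms, coords=coords, donors=[(1, 2)], acceptors=[3])


class TestDetectHbonds:
    def test_clear_bond_detected(self):
        traj = _single_geometry(2.8, 180.0)
        assert detect_hbonds(traj, 0) == [(1, 2, 3)]

    def test_distance_criterion(self):
        assert detect_hbonds(_single_geometry(3.6, 180.0), 0) == []
        assert detect_hbonds(_single_geometry(3.49, 180.0), 0) == [(1, 2, 3)]

    def test_angle_criterion(self):
        assert detect_hbonds(_single_geometry(2.8, 100.0), 0) == []
        assert detect_hbonds(_single_geometry(2.8, 121.0), 0) == [(1, 2, 3)]

    def test_distance_only_definition_ignores_angle(self):
        traj = _single_geometry(2.8, 100.0)
        got = detect_hbonds(traj, 0, angle_definition="distance-only")
        assert got == [(1, 2, 3)]


class TestOccupancy:
    def test_planted_fraction(self):
        frames = [[(0, 0)] if f < 65 else [] for f in range(100)]
        traj = toy_trajectory(frames, n_pairs=1)
        table = hbond_occupancy(traj)
        assert len(table) == 1
        assert table["occupancy"].iloc[0] == 65.0

    def test_unformed_bond_suppressed_by_default(self):
        traj = toy_trajectory([[] for _ in range(20)], n_pairs=1)
        assert hbond_occupancy(traj).empty
        full = hbond_occupancy(traj, include_all=True)
        assert list(full["occupancy"]) == [0.0]

    def test_below_30pct_suppressed(self):
        frames = [[(0, 0)] if f < 29 else [] for f in range(100)]
        traj = toy_trajectory(frames, n_pairs=1)
        assert hbond_occupancy(traj).empty
        assert hbond_occupancy(traj, include_all=True)["occupancy"].iloc[0] == 29.0

    def test_residue_grouping_sums_atom_pairs(self):
        # two donors of one residue, each bonded in every frame
        frames = [[(0, 0), (1, 1)] for _ in range(100)]
        traj = toy_trajectory(
            frames, n_pairs=2, residue_of_donor={0: ("GLU", 476), 1: ("GLU", 476)}
        )
        by_residue = hbond_occupancy(traj, grouping="residue-pair")
        assert len(by_residue) == 1
        assert by_residue["occupancy"].iloc[0] == 200.0
        by_atom = hbond_occupancy(traj, grouping="atom-pair")
        assert by_residue["occupancy"].iloc[0] == by_atom["occupancy"].sum()

    def test_atom_pair_occupancy_bounded(self):
        rng = np.random.default_rng(5)
        frames = [[(0, 0)] if rng.random() < 0.5 else [] for _ in range(50)]
        traj = toy_trajectory(frames, n_pairs=1)
        occ = hbond_occupancy(traj, include_all=True)["occupancy"]
        assert ((occ >= 0) & (occ <= 100)).all()

    def test_reported_distance_is_hydrogen_acceptor(self):
        traj = toy_trajectory([[(0, 0)]], n_pairs=1)
        table = hbond_occupancy(traj, min_occupancy=0.0)
        assert table["distance_mean"].iloc[0] == pytest.approx(1.81, abs=0.01)


class TestCountSeries:
    def test_constant_count(self):
        frames = [[(0, 0), (1, 1), (2, 2)] for _ in range(10)]
        traj = toy_trajectory(frames, n_pairs=3)
        assert hbond_count_series(traj) == (3.0, 0.0)

    def test_alternating_counts(self):
        frames = []
        for f in range(100):
            frames.append([(0, 0)] if f % 2 == 0 else [(0, 0), (1, 1), (2, 2)])
        traj = toy_trajectory(frames, n_pairs=3)
        mean, sd = hbond_count_series(traj)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.005, abs=5e-4)  # sample SD, n = 100

    def test_no_donors(self):
        atoms = pd.DataFrame(
            {"serial": [1], "name": ["O"], "resname": ["LIG"], "resid": [1]}
        )
        traj = Trajectory(atoms=atoms, coords=np.zeros((5, 1, 3)), donors=[], acceptors=[1])
        assert hbond_count_series(traj) == (0.0, 0.0)


class TestRmsd:
    def test_identity(self):
        a = np.random.default_rng(0).normal(size=(10, 3))
        assert rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed_by_superposition(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 3))
        rot = Rotation.from_euler("zyx", [40.0, -25.0, 100.0], degrees=True)
        b = rot.apply(a) + np.array([5.0, -3.0, 11.0])
        assert rmsd(a, b, superpose=True) <= 1e-9
        assert rmsd(a, b, superpose=False) > 1.0

    def test_symmetry_and_superposition_bound(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(8, 3))
        b = a + rng.normal(scale=0.3, size=(8, 3))
        assert rmsd(a, b) == pytest.approx(rmsd(b, a), rel=1e-9)
        assert rmsd(a, b, superpose=True) <= rmsd(a, b, superpose=False) + 1e-12

    def test_three_atom_toy_matches_grid_search_oracle(self):
        # brute-force oracle: minimize raw RMSD over a refined rotation grid
        rng = np.random.default_rng(3)
        a = rng.normal(size=(3, 3))
        b = a + rng.normal(scale=0.4, size=(3, 3))
        got = rmsd(a, b, superpose=True)

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def best_on_grid(center, span, steps):
            angles = [np.linspace(c - span, c + span, steps) for c in center]
            best, arg = np.inf, center
            for x in angles[0]:
                for y in angles[1]:
                    mats = Rotation.from_euler(
                        "zyx",
                        [(x, y, z) for z in angles[2]],
                        degrees=True,
                    ).as_matrix()
                    rotated = np.einsum("nij,kj->nki", mats, bc)
                    vals = np.sqrt(np.mean(np.sum((rotated - ac) ** 2, axis=2), axis=1))
                    i = int(np.argmin(vals))
                    if vals[i] < best:
                        best, arg = float(vals[i]), (x, y, float(angles[2][i]))
            return best, arg

        best, arg = best_on_grid((0.0, 0.0, 0.0), 180.0, 37)
        for span, steps in ((10.0, 21), (1.0, 21), (0.1, 21)):
            best, arg = best_on_grid(arg, span, steps)
        assert got == pytest.approx(best, abs=1e-3)

    def test_cross_check_against_mdanalysis(self):
        mda_rms = pytest.importorskip("MDAnalysis.analysis.rms")
        rng = np.random.default_rng(4)
        a = rng.normal(size=(20, 3))
        b = a + rng.normal(scale=0.5, size=(20, 3))
        ours = rmsd(a, b, superpose=True)
        theirs = mda_rms.rmsd(b, a, center=True, superposition=True)
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(TrajectoryError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


def test_rmsd_series_starts_at_zero():
    traj = toy_trajectory([[(0, 0)], [], [(0, 0)]], n_pairs=1)
    series = rmsd_series(traj)
    assert series[0] == pytest.approx(0.0, abs=1e-12)
    assert series.shape == (3,)


def test_trajectory_validation():
    atoms = pd.DataFrame(
        {"serial": [1, 1], "name": ["N", "H"], "resname": ["A", "A"], "resid": [1, 1]}
    )
    with pytest.raises(TrajectoryError, match="unique"):
        Trajectory(atoms=atoms, coords=np.zeros((1, 2, 3)))
    atoms = pd.DataFrame(
        {"serial": [1, 2], "name": ["N", "H"], "resname": ["A", "A"], "resid": [1, 1]}
    )
    with pytest.raises(TrajectoryError, match="roster"):
        Trajectory(atoms=atoms, coords=np.zeros((1, 3, 3)))
    with pytest.raises(TrajectoryError, match="finite"):
        Trajectory(atoms=atoms, coords=np.full((1, 2, 3), np.nan))
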