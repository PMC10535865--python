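"""Multi-frame coordinate analysis: hydrogen-bond geometry, occupancy
statistics and least-squares (Kabsch) RMSD.

A :class:`Trajectory` is a constant atom roster with per-frame Cartesian
coordinates plus donor/acceptor annotations.  A hydrogen bond D-H...A is
counted in a frame when the donor-acceptor distance is below 3.5 A and
the D-H...A angle exceeds 120 deg (the standard geometric criterion; a
distance-only variant is available for rosters without explicit
hydrogens).  Occupancy is the percentage of frames in which a bond is
formed; residue-pair grouping sums the occupancies of all atom pairs
between two residues, so grouped values above 100% indicate multiple
simultaneous bonds between the partners.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation


class TrajectoryError(ValueError):
    """Invalid trajectory or annotation input."""


@dataclass
class Trajectory:
    """Constant atom roster + (n_frames, n_atoms, 3) coordinates in Angstrom.

    ``atoms`` needs columns serial, name, resname, resid (chain optional);
    ``donors`` lists (donor_serial, hydrogen_serial) pairs and ``acceptors``
    lists acceptor serials.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    donors: list = field(default_factory=list)
    acceptors: list = field(default_factory=list)

    def __post_init__(self) -> None:
        need = {"serial", "name", "resname", "resid"}
        missing = need - set(self.atoms.columns)
        if missing:
            raise TrajectoryError(f"atom table missing columns: {sorted(missing)}")
        if self.atoms["serial"].duplicated().any():
            raise TrajectoryError("atom serials must be unique")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise TrajectoryError("coordinate columns must match the atom roster")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("coordinates must be finite")
        self._index = {int(s): i for i, s in enumerate(self.atoms["serial"])}
        for d, h in self.donors:
            if int(d) not in self._index or int(h) not in self._index:
                raise TrajectoryError(f"donor pair ({d}, {h}) not in the atom roster")
        for a in self.acceptors:
            if int(a) not in self._index:
                raise TrajectoryError(f"acceptor {a} not in the atom roster")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def atom_index(self, serial: int) -> int:
        return self._index[int(serial)]

    def atom_label(self, serial: int) -> str:
        row = self.atoms.iloc[self.atom_index(serial)]
        return f"{self.residue_label(serial)}:{row['name']}"

    def residue_label(self, serial: int) -> str:
        row = self.atoms.iloc[self.atom_index(serial)]
        return f"{row['resname']}{row['resid']}"


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle a-vertex-b in degrees (broadcast over leading axes)."""
    v1 = a - vertex
    v2 = b - vertex
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _bond_events(
    traj: Trajectory,
    distance_cutoff: float,
    angle_cutoff: float,
    angle_definition: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame bond matrix and H...A distances.

    Returns ``bonded`` (n_frames, n_donors, n_acceptors) booleans and the
    matching hydrogen-acceptor distances (donor-acceptor when the
    distance-only criterion is used).
    """
    if angle_definition not in ("dha", "distance-only"):
        raise TrajectoryError("angle_definition must be 'dha' or 'distance-only'")
    if not traj.donors or not traj.acceptors:
        shape = (traj.n_frames, len(traj.donors), len(traj.acceptors))
        return np.zeros(shape, dtype=bool), np.zeros(shape)
    d_idx = np.array([traj.atom_index(d) for d, _ in traj.donors])
    h_idx = np.array([traj.atom_index(h) for _, h in traj.donors])
    a_idx = np.array([traj.atom_index(a) for a in traj.acceptors])

    D = traj.coords[:, d_idx][:, :, None, :]  # (F, nd, 1, 3)
    H = traj.coords[:, h_idx][:, :, None, :]
    A = traj.coords[:, a_idx][:, None, :, :]  # (F, 1, na, 3)

    dist_da = np.linalg.norm(D - A, axis=-1)
    same_atom = d_idx[:, None] == a_idx[None, :]
    bonded = (dist_da < distance_cutoff) & ~same_atom[None, :, :]
    if angle_definition == "dha":
        ang = _angle_deg(D, H, A)
        bonded &= ang > angle_cutoff
        dist = np.linalg.norm(H - A, axis=-1)
    else:
        dist = dist_da
    return bonded, dist


def detect_hbonds(
    traj: Trajectory,
    frame: int,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
    angle_definition: str = "dha",
) -> list[tuple[int, int, int]]:
    """Hydrogen bonds present in one frame as (donor, hydrogen, acceptor) serials."""
    bonded, _ = _bond_events(traj, distance_cutoff, angle_cutoff, angle_definition)
    out = []
    for i, (d, h) in enumerate(traj.donors):
        for j, a in enumerate(traj.acceptors):
            if bonded[frame, i, j]:
                out.append((int(d), int(h), int(a)))
    return out


def hbond_occupancy(
    traj: Trajectory,
    grouping: str = "atom-pair",
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
    angle_definition: str = "dha",
    min_occupancy: float = 30.0,
    include_all: bool = False,
) -> pd.DataFrame:
    """Occupancy table over the trajectory.

    Atom-pair occupancy is 100 * (bonded frames) / n_frames; residue-pair
    grouping sums the atom-pair occupancies between the two residues (so
    values above 100% are legal).  Records below ``min_occupancy`` percent
    are suppressed unless ``include_all``.  Distances are hydrogen-acceptor
    means +/- SD over bonded frames.
    """
    if traj.n_frames < 1:
        raise TrajectoryError("trajectory has no frames")
    bonded, dist = _bond_events(traj, distance_cutoff, angle_cutoff, angle_definition)
    n_frames = traj.n_frames
    rows = []
    for i, (d, _h) in enumerate(traj.donors):
        for j, a in enumerate(traj.acceptors):
            n_bonded = int(bonded[:, i, j].sum())
            dists = dist[:, i, j][bonded[:, i, j]]
            rows.append(
                {
                    "donor": traj.atom_label(d),
                    "acceptor": traj.atom_label(a),
                    "donor_residue": traj.residue_label(d),
                    "acceptor_residue": traj.residue_label(a),
                    "occupancy": 100.0 * n_bonded / n_frames,
                    "n_bonded": n_bonded,
                    "distance_mean": float(dists.mean()) if n_bonded else float("nan"),
                    "distance_sd": float(dists.std(ddof=1)) if n_bonded > 1 else 0.0,
                    "_dist_sum": float(dists.sum()),
                    "_dist_sqsum": float((dists**2).sum()),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "donor",
            "acceptor",
            "donor_residue",
            "acceptor_residue",
            "occupancy",
            "n_bonded",
            "distance_mean",
            "distance_sd",
            "_dist_sum",
            "_dist_sqsum",
        ],
    )

    if grouping == "residue-pair":
        grouped = []
        for (dres, ares), grp in table.groupby(["donor_residue", "acceptor_residue"]):
            n = int(grp["n_bonded"].sum())
            if n > 0:
                mean = grp["_dist_sum"].sum() / n
                var = grp["_dist_sqsum"].sum() / n - mean**2
                sd = math.sqrt(max(var, 0.0) * n / (n - 1)) if n > 1 else 0.0
            else:
                mean, sd = float("nan"), 0.0
            grouped.append(
                {
                    "donor_residue": dres,
                    "acceptor_residue": ares,
                    "occupancy": float(grp["occupancy"].sum()),
                    "n_bonded": n,
                    "distance_mean": mean,
                    "distance_sd": sd,
                }
            )
        out = pd.DataFrame(
            grouped,
            columns=[
                "donor_residue",
                "acceptor_residue",
                "occupancy",
                "n_bonded",
                "distance_mean",
                "distance_sd",
            ],
        )
    elif grouping == "atom-pair":
        out = table.drop(columns=["_dist_sum", "_dist_sqsum"])
    else:
        raise TrajectoryError("grouping must be 'atom-pair' or 'residue-pair'")

    if not include_all:
        out = out[out["occupancy"] >= min_occupancy]
    return out.sort_values("occupancy", ascending=False).reset_index(drop=True)


def hbond_count_series(
    traj: Trajectory,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
    angle_definition: str = "dha",
) -> tuple[float, float]:
    """Mean +/- sample SD of the per-frame hydrogen-bond count."""
    if traj.n_frames < 2:
        raise TrajectoryError("need at least two frames for a count series")
    bonded, _ = _bond_events(traj, distance_cutoff, angle_cutoff, angle_definition)
    counts = bonded.reshape(traj.n_frames, -1).sum(axis=1).astype(float)
    return float(counts.mean()), float(counts.std(ddof=1))


def rmsd(
    reference: np.ndarray,
    frame: np.ndarray,
    superpose: bool = True,
) -> float:
    """Root-mean-square deviation (Angstrom) between matched coordinate sets.

    With ``superpose`` the frame is first optimally translated and rotated
    onto the reference (least-squares orthogonal superposition, proper
    rotation only); otherwise the raw deviation is returned.
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(frame, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise TrajectoryError("coordinate sets must be matched (n, 3) arrays")
    n = a.shape[0]
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    with warnings.catch_warnings():
        # collinear/planar sets leave the optimal rotation non-unique, but
        # every optimum gives the same (correct) minimal deviation
        warnings.filterwarnings(
            "ignore", message="Optimal rotation is not uniquely"
        )
        rot, _rssd = Rotation.align_vectors(ac, bc)
    diff = rot.apply(bc) - ac
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD against one reference frame of the trajectory."""
    ref = traj.coords[reference_frame]
    return np.array([rmsd(ref, traj.coords[i], superpose) for i in range(traj.n_frames)])
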