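import numpy as np
import pandas as pd
import pytest

from pgpkit.kinetics import AssayConditions, FluorescenceTrace, TransportParams
from pgpkit.trajectory import Trajectory

# bulk rate constants (1/s) spanning the assay's observed range:
# passive uptake V_+ of 1.6-2.7 nM/s at C_T = 1 uM, pump/leak ratio ~1-3
K_PLUS_RHO_GRID = (1.6e-3, 2.2e-3, 2.7e-3)
K_ACT_RHO_GRID = (1.6e-3, 3.2e-3, 4.8e-3)


@pytest.fixture
def conditions() -> AssayConditions:
    """Standard assay: 1 uM THP, 2e6 cells, 2 mL."""
    return AssayConditions()


@pytest.fixture
def rho(conditions) -> float:
    return conditions.cell_density


def params_for(kpr: float, kar: float, rho: float) -> TransportParams:
    """TransportParams from bulk rate constants k_plus*rho, k_act*rho (1/s)."""
    return TransportParams(k_plus=kpr / rho, k_act=kar / rho)


def plateau_trace(
    f0: float,
    fn: float,
    fN: float | None = None,
    background: float = 0.0,
) -> FluorescenceTrace:
    """Piecewise-constant trace with known F0/Fn/FN plateaus.

    Starts at f0, steps to fn at 100 s and, when fN is given, to fN at the
    1600 s permeabilization mark.
    """
    t = np.arange(0.0, 2001.0)
    f = np.full(t.size, float(f0))
    f[t >= 100] = fn
    events = {"drug_added": 0.0, "steady_state_window": (1280.0, 1600.0)}
    if fN is not None:
        f[t > 1600] = fN
        events["permeabilization"] = 1600.0
    return FluorescenceTrace(times=t, intensities=f + background, events=events)


def toy_trajectory(
    bonds_per_frame: list[list[tuple[int, int]]],
    n_pairs: int,
    residue_of_donor=None,
) -> Trajectory:
    """Hand-built trajectory with explicit per-frame bond placement.

    ``bonds_per_frame[f]`` lists (donor_index, acceptor_index) pairs bonded
    in frame ``f``; pair *i* uses donor/hydrogen serials 3i+1, 3i+2 and
    acceptor serial 3i+3.  ``residue_of_donor`` optionally maps a donor
    index to a (resname, resid) pair so several donors can share a residue.
    """
    atoms = []
    donors, acceptors = [], []
    for i in range(n_pairs):
        resname, resid = ("ASP", 100 + i)
        if residue_of_donor and i in residue_of_donor:
            resname, resid = residue_of_donor[i]
        atoms += [
            {"serial": 3 * i + 1, "name": "N", "resname": resname, "resid": resid},
            {"serial": 3 * i + 2, "name": "H", "resname": resname, "resid": resid},
            {"serial": 3 * i + 3, "name": f"O{i}", "resname": "LIG", "resid": 900},
        ]
        donors.append((3 * i + 1, 3 * i + 2))
        acceptors.append(3 * i + 3)

    n_frames = len(bonds_per_frame)
    coords = np.zeros((n_frames, 3 * n_pairs, 3))
    u = np.array([np.cos(np.radians(10.0)), np.sin(np.radians(10.0)), 0.0])
    for f, bonded in enumerate(bonds_per_frame):
        bonded = set(bonded)
        for i in range(n_pairs):
            base = np.array([40.0 * i, 0.0, 0.0])
            coords[f, 3 * i] = base
            coords[f, 3 * i + 1] = base + [1.0, 0.0, 0.0]
            if (i, i) in bonded:
                coords[f, 3 * i + 2] = base + [1.0, 0.0, 0.0] + 1.81 * u
            else:
                coords[f, 3 * i + 2] = base + [4.5, 0.0, 0.0]
    return Trajectory(
        atoms=pd.DataFrame(atoms), coords=coords, donors=donors, acceptors=acceptors
    )
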