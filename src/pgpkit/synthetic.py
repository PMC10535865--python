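"""Seeded generators for every input the analyses consume.

Each generator is a pure function of its spec (seed included): identical
specs give bit-identical output, and every dataset carries its ground
truth so round-trip tests need no hard-coded numbers.

Defaults emulate the study conditions of the live-cell efflux assay
(1 uM pirarubicin on 2e6 K562/ADR cells in 2 mL, steady state by ~1600 s,
Triton permeabilization at 1600 s, 1 s sampling over 2000 s), of CCK-8
dose-response experiments (8-point titrations in triplicate), of MM-GBSA
per-frame component tables (1000 frames x 3 replicas) and of toy
trajectories with planted hydrogen-bond schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .energetics import interaction_entropy
from .kinetics import (
    AssayConditions,
    FluorescenceTrace,
    TransportParams,
    simulate_uptake,
)
from .resistance import DoseResponseData
from .trajectory import Trajectory


class GeneratorError(ValueError):
    """Invalid generator spec."""


# default transport constants: bulk passive rate k_plus*rho = 1.6e-3 /s
# reproduces the control uptake rate V_+ = 1.6 nM/s at C_T = 1 uM, and the
# pump/leak ratio k_act/k_plus = 3 matches the control assay.
_DEFAULT_CONDITIONS = AssayConditions()
_RHO = _DEFAULT_CONDITIONS.cell_density
DEFAULT_K_PLUS = 1.6e-3 / _RHO
DEFAULT_K_ACT = 3.0 * DEFAULT_K_PLUS


@dataclass(frozen=True)
class UptakeSpec:
    """Scenario for one synthetic uptake assay."""

    seed: int = 0
    params: TransportParams = field(
        default_factory=lambda: TransportParams(k_plus=DEFAULT_K_PLUS, k_act=DEFAULT_K_ACT)
    )
    conditions: AssayConditions = field(default_factory=AssayConditions)
    dt: float = 1.0
    t_end: float = 2000.0
    t_perm: Optional[float] = 1600.0
    noise_sd: float = 0.5  # a.u.; 0.5% of the default F0 scale
    f0_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise GeneratorError("noise_sd must be >= 0")
        if self.dt <= 0 or self.t_end <= self.dt:
            raise GeneratorError("need dt > 0 and t_end > dt")


def gen_uptake_trace(spec: UptakeSpec) -> tuple[FluorescenceTrace, TransportParams]:
    """Simulated fluorescence trace with additive Gaussian noise + ground truth."""
    grid = np.arange(0.0, spec.t_end + 0.5 * spec.dt, spec.dt)
    trace = simulate_uptake(
        spec.params, spec.conditions, grid, permeabilization_time=spec.t_perm,
        f0_scale=spec.f0_scale,
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = trace.intensities + rng.normal(0.0, spec.noise_sd, trace.intensities.size)
        trace = FluorescenceTrace(
            times=trace.times,
            intensities=np.clip(noisy, 0.0, None),
            events=dict(trace.events),
        )
    return trace, spec.params


@dataclass(frozen=True)
class DoseResponseSpec:
    """Scenario for one synthetic viability titration (doses in uM)."""

    seed: int = 0
    ic50: float = 4.54
    hill: float = 1.2
    top: float = 100.0
    bottom: float = 0.0
    doses: tuple = (0.0, 0.05, 0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0)
    n_replicates: int = 3
    noise_sd: float = 5.0  # viability points

    def __post_init__(self) -> None:
        if len([d for d in self.doses if d >= 0]) != len(self.doses):
            raise GeneratorError("doses must be >= 0")
        if len(set(self.doses)) < 4:
            raise GeneratorError("need at least 4 distinct doses")
        if self.noise_sd < 0 or self.n_replicates < 1:
            raise GeneratorError("invalid noise_sd or n_replicates")


def gen_dose_response(spec: DoseResponseSpec) -> tuple[DoseResponseData, dict]:
    """Hill-model viabilities with replicate noise + ground-truth parameters."""
    doses = np.repeat(np.asarray(spec.doses, dtype=float), spec.n_replicates)
    with np.errstate(divide="ignore"):
        ratio = np.where(doses > 0, (doses / spec.ic50) ** spec.hill, 0.0)
    viab = spec.bottom + (spec.top - spec.bottom) / (1.0 + ratio)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        viab = viab + rng.normal(0.0, spec.noise_sd, viab.size)
    truth = {
        "ic50": spec.ic50,
        "hill": spec.hill,
        "top": spec.top,
        "bottom": spec.bottom,
    }
    return DoseResponseData(doses=doses, viability=viab), truth


@dataclass(frozen=True)
class EnergyFramesSpec:
    """Scenario for synthetic per-frame MM-GBSA component tables.

    Component means default to a verapamil-like substrate-site complex;
    per-frame SDs are typical frame-to-frame fluctuations.
    """

    seed: int = 0
    means: Mapping[str, float] = field(
        default_factory=lambda: {
            "e_vdw": -57.36,
            "e_elect": -9.45,
            "g_polar": 31.87,
            "g_nonpolar": -8.21,
        }
    )
    sds: Mapping[str, float] = field(
        default_factory=lambda: {
            "e_vdw": 2.5,
            "e_elect": 2.0,
            "g_polar": 2.0,
            "g_nonpolar": 0.3,
        }
    )
    n_frames: int = 1000
    n_replicas: int = 3
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.n_frames < 2 or self.n_replicas < 1:
            raise GeneratorError("need n_frames >= 2 and n_replicas >= 1")
        if any(v < 0 for v in self.sds.values()):
            raise GeneratorError("component SDs must be >= 0")


def gen_energy_frames(spec: EnergyFramesSpec) -> tuple[pd.DataFrame, dict]:
    """Per-frame component draws + exact truth (configured means, realized IE)."""
    rng = np.random.default_rng(spec.seed)
    cols = ("e_vdw", "e_elect", "g_polar", "g_nonpolar")
    tables = []
    ie_per_replica = []
    for r in range(spec.n_replicas):
        data = {"replica": f"rep{r + 1}", "frame": np.arange(spec.n_frames)}
        for c in cols:
            data[c] = rng.normal(spec.means[c], spec.sds[c], spec.n_frames)
        df = pd.DataFrame(data)
        tables.append(df)
        ie_per_replica.append(
            interaction_entropy(
                (df["e_vdw"] + df["e_elect"]).to_numpy(), temperature=spec.temperature
            )
        )
    frames = pd.concat(tables, ignore_index=True)
    truth = {
        "means": dict(spec.means),
        "ie_per_replica": ie_per_replica,
        "temperature": spec.temperature,
    }
    return frames, truth


@dataclass(frozen=True)
class PlantedBond:
    """One donor-hydrogen/acceptor pair with the frames in which it bonds."""

    donor_resname: str
    donor_resid: int
    acceptor_resname: str
    acceptor_resid: int
    bonded_frames: tuple
    donor_name: str = "N"
    hydrogen_name: str = "H"
    acceptor_name: str = "O"


@dataclass(frozen=True)
class ToyTrajectorySpec:
    """Scenario for a toy trajectory with a planted hydrogen-bond schedule.

    Bonded geometry: donor-acceptor distance 2.8 A with a 170 deg D-H...A
    angle; unbonded pairs sit at 4.5 A.  Coordinates carry Gaussian jitter
    of ``jitter`` A (small against the 3.5 A / 120 deg criteria).
    """

    seed: int = 0
    n_frames: int = 100
    bonds: tuple = ()
    jitter: float = 0.02

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise GeneratorError("need at least one frame")
        if self.jitter < 0 or self.jitter > 0.05:
            raise GeneratorError("jitter must lie in [0, 0.05] A")
        for b in self.bonds:
            bad = [f for f in b.bonded_frames if not (0 <= f < self.n_frames)]
            if bad:
                raise GeneratorError(f"bonded frame(s) {bad} outside [0, n_frames)")


def gen_toy_trajectory(spec: ToyTrajectorySpec) -> tuple[Trajectory, dict]:
    """Trajectory realizing a planted schedule + the schedule as ground truth.

    Each planted pair lives in its own 30 A-spaced region so pairs cannot
    bond across the schedule.  In bonded frames the acceptor sits 2.8 A
    from the donor at a 170 deg D-H...A angle; in unbonded frames it is
    moved to 4.5 A along the donor-hydrogen axis.
    """
    rng = np.random.default_rng(spec.seed)
    n_pairs = len(spec.bonds)
    atoms = []
    donors = []
    acceptors = []
    serial = 1
    base_positions = []
    for i, bond in enumerate(spec.bonds):
        base = np.array([30.0 * i, 0.0, 0.0])
        base_positions.append(base)
        atoms.append(
            {"serial": serial, "name": bond.donor_name,
             "resname": bond.donor_resname, "resid": bond.donor_resid}
        )
        atoms.append(
            {"serial": serial + 1, "name": bond.hydrogen_name,
             "resname": bond.donor_resname, "resid": bond.donor_resid}
        )
        atoms.append(
            {"serial": serial + 2, "name": bond.acceptor_name,
             "resname": bond.acceptor_resname, "resid": bond.acceptor_resid}
        )
        donors.append((serial, serial + 1))
        acceptors.append(serial + 2)
        serial += 3

    if n_pairs == 0:
        raise GeneratorError("schedule lists no donor/acceptor pairs")

    # acceptor direction for a 170 deg angle at the hydrogen, d(D, A) = 2.8 A
    u = np.array([np.cos(np.radians(10.0)), np.sin(np.radians(10.0)), 0.0])
    r_bond = 1.81  # |H->A| solving |D->A| = 2.8 with |D->H| = 1.0
    coords = np.zeros((spec.n_frames, 3 * n_pairs, 3))
    for i, bond in enumerate(spec.bonds):
        base = base_positions[i]
        d_pos = base
        h_pos = base + np.array([1.0, 0.0, 0.0])
        a_bonded = h_pos + r_bond * u
        a_free = base + np.array([4.5, 0.0, 0.0])
        bonded = np.zeros(spec.n_frames, dtype=bool)
        bonded[list(bond.bonded_frames)] = True
        coords[:, 3 * i, :] = d_pos
        coords[:, 3 * i + 1, :] = h_pos
        coords[:, 3 * i + 2, :] = np.where(bonded[:, None], a_bonded, a_free)
    if spec.jitter > 0:
        coords = coords + rng.normal(0.0, spec.jitter, coords.shape)

    traj = Trajectory(
        atoms=pd.DataFrame(atoms),
        coords=coords,
        donors=donors,
        acceptors=acceptors,
    )
    truth = {
        "schedule": {
            (f"{b.donor_resname}{b.donor_resid}:{b.donor_name}",
             f"{b.acceptor_resname}{b.acceptor_resid}:{b.acceptor_name}"):
                sorted(b.bonded_frames)
            for b in spec.bonds
        },
        "n_frames": spec.n_frames,
    }
    return traj, truth
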