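"""Readers and writers for the tabular formats the analyses consume.

All tables are plain CSV with documented headers; malformed input is
reported with the offending column and line number.  Writers round-trip
bit-identically through the matching reader on canonical files.

Schemas
-------
trace            time_s,intensity
events           event,time_s          (drug_added, steady_window_start,
                                        steady_window_end, triton)
dose_response    dose,unit,replicate,viability_pct
qpcr             sample,gene,ct
energy           replica,frame,e_vdw,e_elect,g_polar,g_nonpolar
decomposition    residue,energy
trajectory       frame,serial,name,resname,resid,x,y,z
annotations      serial,role           (role: donor | hydrogen-of:<serial>
                                        | acceptor)
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .kinetics import FluorescenceTrace
from .trajectory import Trajectory

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def _read_csv_strict(
    path: PathLike,
    required: tuple,
    numeric: tuple,
    allow_extra: bool = False,
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: empty input file")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}; "
                          f"expected header {','.join(required)}")
    if not allow_extra:
        extra = set(df.columns) - set(required)
        if extra:
            raise SchemaError(f"{path}: unknown column(s) {sorted(extra)}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line and 1-based numbering
            line = int(bad.idxmax()) + 2
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise SchemaError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = coerced
    return df


# -- fluorescence traces -----------------------------------------------------

TRACE_COLUMNS = ("time_s", "intensity")


def read_trace_csv(path: PathLike, events: Optional[dict] = None) -> FluorescenceTrace:
    df = _read_csv_strict(path, TRACE_COLUMNS, TRACE_COLUMNS)
    return FluorescenceTrace(
        times=df["time_s"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        events=events or {},
    )


def write_trace_csv(trace: FluorescenceTrace, path: PathLike) -> None:
    pd.DataFrame({"time_s": trace.times, "intensity": trace.intensities}).to_csv(
        path, index=False
    )


def read_events(source: Union[PathLike, dict]) -> dict:
    """Event markers from a config mapping or an ``event,time_s`` CSV.

    Config keys: ``drug_added_s``, ``steady_window_s`` ([start, end]) and
    ``triton_s`` (optional).
    """
    if isinstance(source, dict):
        cfg = source
        if "drug_added_s" not in cfg or "steady_window_s" not in cfg:
            raise SchemaError("event config needs drug_added_s and steady_window_s")
        events = {
            "drug_added": float(cfg["drug_added_s"]),
            "steady_state_window": tuple(float(x) for x in cfg["steady_window_s"]),
        }
        if cfg.get("triton_s") is not None:
            events["permeabilization"] = float(cfg["triton_s"])
        return events
    df = _read_csv_strict(source, ("event", "time_s"), ("time_s",))
    table = dict(zip(df["event"], df["time_s"]))
    for key in ("drug_added", "steady_window_start", "steady_window_end"):
        if key not in table:
            raise SchemaError(f"{source}: missing event {key!r}")
    events = {
        "drug_added": float(table["drug_added"]),
        "steady_state_window": (
            float(table["steady_window_start"]),
            float(table["steady_window_end"]),
        ),
    }
    if "triton" in table:
        events["permeabilization"] = float(table["triton"])
    return events


# -- dose-response and qPCR --------------------------------------------------

DOSE_COLUMNS = ("dose", "unit", "replicate", "viability_pct")


def read_dose_response_csv(path: PathLike) -> pd.DataFrame:
    df = _read_csv_strict(path, DOSE_COLUMNS, ("dose", "viability_pct"))
    units = df["unit"].unique()
    if len(units) > 1:
        raise SchemaError(f"{path}: mixed dose units {sorted(units)}")
    return df


def read_qpcr_csv(path: PathLike) -> pd.DataFrame:
    df = _read_csv_strict(path, ("sample", "gene", "ct"), ("ct",))
    bad = ~df["ct"].between(0, 45, inclusive="neither")
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise SchemaError(f"{path}: Ct outside (0, 45) at line {line}")
    return df


# -- energies ----------------------------------------------------------------

ENERGY_CSV_COLUMNS = ("replica", "frame", "e_vdw", "e_elect", "g_polar", "g_nonpolar")


def read_energy_csv(path: PathLike) -> pd.DataFrame:
    return _read_csv_strict(
        path, ENERGY_CSV_COLUMNS, ENERGY_CSV_COLUMNS[1:]
    )


def read_decomposition_csv(path: PathLike) -> pd.DataFrame:
    return _read_csv_strict(path, ("residue", "energy"), ("energy",))


# -- trajectories ------------------------------------------------------------

TRAJ_COLUMNS = ("frame", "serial", "name", "resname", "resid", "x", "y", "z")


def read_trajectory_csv(coords_path: PathLike, annotations_path: PathLike) -> Trajectory:
    df = _read_csv_strict(
        coords_path, TRAJ_COLUMNS, ("frame", "serial", "resid", "x", "y", "z")
    )
    frames = np.sort(df["frame"].unique())
    first = df[df["frame"] == frames[0]].sort_values("serial")
    atoms = first[["serial", "name", "resname", "resid"]].reset_index(drop=True)
    atoms["serial"] = atoms["serial"].astype(int)
    atoms["resid"] = atoms["resid"].astype(int)
    n_atoms = len(atoms)
    coords = np.empty((frames.size, n_atoms, 3))
    for k, fr in enumerate(frames):
        sub = df[df["frame"] == fr].sort_values("serial")
        if len(sub) != n_atoms or not np.array_equal(
            sub["serial"].to_numpy(), atoms["serial"].to_numpy()
        ):
            raise SchemaError(
                f"{coords_path}: atom roster changes at frame {fr} "
                "(must be identical across frames)"
            )
        coords[k] = sub[["x", "y", "z"]].to_numpy()
    donors, acceptors = read_annotations_csv(annotations_path)
    return Trajectory(atoms=atoms, coords=coords, donors=donors, acceptors=acceptors)


def read_annotations_csv(path: PathLike) -> tuple[list, list]:
    df = _read_csv_strict(path, ("serial", "role"), ("serial",))
    hydrogens: dict[int, int] = {}
    donors_plain: list[int] = []
    acceptors: list[int] = []
    for row in df.itertuples(index=False):
        role = str(row.role)
        serial = int(row.serial)
        if role == "donor":
            donors_plain.append(serial)
        elif role == "acceptor":
            acceptors.append(serial)
        elif role.startswith("hydrogen-of:"):
            hydrogens[int(role.split(":", 1)[1])] = serial
        else:
            raise SchemaError(f"{path}: unknown role {role!r} for serial {serial}")
    donors = []
    for d in donors_plain:
        if d not in hydrogens:
            raise SchemaError(f"{path}: donor {d} has no hydrogen-of:{d} row")
        donors.append((d, hydrogens[d]))
    return donors, acceptors


def write_trajectory_csv(
    traj: Trajectory, coords_path: PathLike, annotations_path: PathLike
) -> None:
    rows = []
    for fr in range(traj.n_frames):
        for i, atom in traj.atoms.iterrows():
            x, y, z = traj.coords[fr, i]
            rows.append(
                {
                    "frame": fr,
                    "serial": int(atom["serial"]),
                    "name": atom["name"],
                    "resname": atom["resname"],
                    "resid": int(atom["resid"]),
                    "x": x,
                    "y": y,
                    "z": z,
                }
            )
    pd.DataFrame(rows, columns=list(TRAJ_COLUMNS)).to_csv(coords_path, index=False)
    ann = [{"serial": d, "role": "donor"} for d, _ in traj.donors]
    ann += [{"serial": h, "role": f"hydrogen-of:{d}"} for d, h in traj.donors]
    ann += [{"serial": a, "role": "acceptor"} for a in traj.acceptors]
    pd.DataFrame(ann, columns=["serial", "role"]).to_csv(annotations_path, index=False)


def read_trajectory_pdb(
    pdb_path: PathLike, annotations_path: PathLike
) -> Trajectory:
    """Multi-MODEL PDB reader (ATOM/HETATM records) for frame coordinates."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(pdb_path))
    stack = f.get_structure(model=None)  # AtomArrayStack
    first = stack[0]
    serials = (
        first.get_annotation("atom_id")
        if "atom_id" in first.get_annotation_categories()
        else np.arange(1, first.array_length() + 1)
    )
    atoms = pd.DataFrame(
        {
            "serial": np.asarray(serials, dtype=int),
            "name": first.atom_name,
            "resname": first.res_name,
            "resid": first.res_id.astype(int),
        }
    )
    donors, acceptors = read_annotations_csv(annotations_path)
    return Trajectory(
        atoms=atoms, coords=np.asarray(stack.coord, dtype=float),
        donors=donors, acceptors=acceptors,
    )


# -- result tables -----------------------------------------------------------


def write_tsv(df: pd.DataFrame, path: PathLike, metadata: Optional[dict] = None) -> None:
    """TSV with a one-line ``#`` metadata header (JSON payload)."""
    path = Path(path)
    buf = _io.StringIO()
    if metadata:
        buf.write("# " + json.dumps(metadata, sort_keys=True) + "\n")
    df.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue())


def read_tsv(path: PathLike) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    text = path.read_text()
    metadata: dict = {}
    if text.startswith("#"):
        header, _, rest = text.partition("\n")
        metadata = json.loads(header[1:].strip())
        text = rest
    return pd.read_csv(_io.StringIO(text), sep="\t"), metadata
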