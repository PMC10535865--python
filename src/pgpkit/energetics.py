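"""MM-GBSA bookkeeping: free-energy aggregation, interaction entropy,
replica statistics and per-residue decomposition filtering.

Per-frame component energies (complex-minus-parts differences, kcal/mol)
are consumed as input; force-field evaluation and GB solvation happen
upstream.  The binding free energy is assembled as

    dH      = dE_vdw + dE_elect + dG_polar + dG_nonpolar
    dG_bind = dH + (-T dS)

where the conformational-entropy penalty -T dS is estimated from the
fluctuations of the gas-phase interaction energy E_int = E_vdw + E_elect
by the interaction-entropy (IE) formula

    -T dS = (1/beta) * ln < exp(beta * (E_int - <E_int>)) >,

a non-negative quantity (Jensen) that vanishes only for a constant series.
Replica means are reported as mean +/- SEM across independent copies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

KB_KCAL_PER_MOL_K = 0.0019872041  # Boltzmann constant, kcal/(mol K)

ENERGY_COLUMNS = ("e_vdw", "e_elect", "g_polar", "g_nonpolar")


class EnergeticsError(ValueError):
    """Invalid input to an energetics operation."""


@dataclass
class GBSASummary:
    """Aggregated MM-GBSA terms (kcal/mol) with optional per-term SEMs."""

    dE_vdw: float
    dE_elect: float
    dG_polar: float
    dG_nonpolar: float
    minus_TdS: float
    dH: float
    dG_bind: float
    sem: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "dE_vdw": self.dE_vdw,
            "dE_elect": self.dE_elect,
            "dG_polar": self.dG_polar,
            "dG_nonpolar": self.dG_nonpolar,
            "minus_TdS": self.minus_TdS,
            "dH": self.dH,
            "dG_bind": self.dG_bind,
        }
        for k, v in self.sem.items():
            out[f"sem_{k}"] = v
        return out


def mmgbsa_total(
    dE_vdw: float,
    dE_elect: float,
    dG_polar: float,
    dG_nonpolar: float,
    minus_TdS: float,
    sem: Optional[Mapping[str, float]] = None,
) -> GBSASummary:
    """Assemble dH and dG_bind from component means and the entropy penalty."""
    vals = (dE_vdw, dE_elect, dG_polar, dG_nonpolar, minus_TdS)
    if not all(math.isfinite(v) for v in vals):
        raise EnergeticsError("all energy components must be finite")
    if minus_TdS < 0:
        raise EnergeticsError("-TdS is an additive penalty and must be >= 0")
    dH = dE_vdw + dE_elect + dG_polar + dG_nonpolar
    return GBSASummary(
        dE_vdw=dE_vdw,
        dE_elect=dE_elect,
        dG_polar=dG_polar,
        dG_nonpolar=dG_nonpolar,
        minus_TdS=minus_TdS,
        dH=dH,
        dG_bind=dH + minus_TdS,
        sem=dict(sem) if sem else {},
    )


def interaction_entropy(
    e_int_series: Sequence[float],
    temperature: float = 310.0,
) -> float:
    """-T dS (kcal/mol) from per-frame gas-phase interaction energies.

    Computed with a log-sum-exp so strongly fluctuating series cannot
    overflow; a warning flags series whose estimate is dominated by a
    single frame (the IE estimator is unreliable there).
    """
    e = np.asarray(e_int_series, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise EnergeticsError("need at least two frames")
    if not np.all(np.isfinite(e)):
        raise EnergeticsError("interaction energies must be finite")
    if not (temperature > 0):
        raise EnergeticsError("temperature must be > 0")
    beta = 1.0 / (KB_KCAL_PER_MOL_K * temperature)
    fluct = beta * (e - e.mean())
    if fluct.max() > 40.0:
        warnings.warn(
            "interaction-entropy estimate dominated by rare frames "
            f"(max beta*dE = {fluct.max():.1f}); value is numerically unstable",
            stacklevel=2,
        )
    log_mean = logsumexp(fluct) - np.log(e.size)
    return float(max(log_mean / beta, 0.0))


def replica_summary(per_replica_values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error over replica copies (SEM = SD/sqrt(n))."""
    vals = np.asarray(per_replica_values, dtype=float)
    if vals.size == 0:
        raise EnergeticsError("need at least one replica value")
    if not np.all(np.isfinite(vals)):
        raise EnergeticsError("replica values must be finite")
    if vals.size == 1:
        warnings.warn("single replica: SEM reported as 0", stacklevel=2)
        return float(vals[0]), 0.0
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(vals.size))


def validate_energy_frames(frames: pd.DataFrame) -> pd.DataFrame:
    """Check an EnergyFrameTable: required columns, finite, unique frames."""
    need = {"replica", "frame", *ENERGY_COLUMNS}
    missing = need - set(frames.columns)
    if missing:
        raise EnergeticsError(f"energy table missing columns: {sorted(missing)}")
    for col in ENERGY_COLUMNS:
        if not np.all(np.isfinite(frames[col].to_numpy(dtype=float))):
            raise EnergeticsError(f"non-finite values in column {col!r}")
    dup = frames.duplicated(subset=["replica", "frame"])
    if dup.any():
        raise EnergeticsError(
            f"duplicate frame indices within a replica (first at row {int(dup.idxmax())})"
        )
    return frames


def gbsa_from_frames(
    frames: pd.DataFrame,
    temperature: float = 310.0,
) -> tuple[GBSASummary, pd.DataFrame]:
    """Replica-wise MM-GBSA summary from a per-frame component table.

    For each replica the component means are taken over frames and the
    entropy penalty from the IE formula on E_int = e_vdw + e_elect; the
    headline numbers are replica means with SEMs.  Returns the pooled
    summary and the per-replica table.
    """
    frames = validate_energy_frames(frames)
    rows = []
    for replica, grp in frames.groupby("replica", sort=True):
        e_int = (grp["e_vdw"] + grp["e_elect"]).to_numpy(dtype=float)
        minus_tds = interaction_entropy(e_int, temperature=temperature)
        summ = mmgbsa_total(
            float(grp["e_vdw"].mean()),
            float(grp["e_elect"].mean()),
            float(grp["g_polar"].mean()),
            float(grp["g_nonpolar"].mean()),
            minus_tds,
        )
        row = summ.as_dict()
        row["replica"] = replica
        rows.append(row)
    per_replica = pd.DataFrame(rows).set_index("replica")

    terms = ["dE_vdw", "dE_elect", "dG_polar", "dG_nonpolar", "minus_TdS"]
    means, sems = {}, {}
    for term in terms + ["dH", "dG_bind"]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            means[term], sems[term] = replica_summary(per_replica[term].to_numpy())
    pooled = mmgbsa_total(*(means[t] for t in terms), sem=sems)
    return pooled, per_replica.reset_index()


def decompose_filter(
    decomposition: Union[pd.DataFrame, Mapping[str, float]],
    threshold: float = -0.5,
) -> pd.DataFrame:
    """Residues contributing binding energy strictly below ``threshold``.

    Returns a residue/energy table sorted ascending by energy (strongest
    contributors first).  Residue labels must be unique.
    """
    if isinstance(decomposition, Mapping):
        df = pd.DataFrame(
            {"residue": list(decomposition.keys()), "energy": list(decomposition.values())}
        )
    else:
        df = decomposition.copy()
    if not {"residue", "energy"}.issubset(df.columns):
        raise EnergeticsError("decomposition needs 'residue' and 'energy' columns")
    if df["residue"].duplicated().any():
        raise EnergeticsError("residue labels must be unique")
    kept = df[df["energy"] < threshold]
    return kept.sort_values("energy", kind="mergesort").reset_index(drop=True)
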