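"""MM-GBSA bookkeeping: published component tables and synthetic replicas.

Part 1 assembles dG_bind from the published per-complex component means
(van der Waals, electrostatic, polar/non-polar solvation, entropy penalty)
and checks the additivity identity.  Part 2 generates per-frame component
tables for three replicas, runs the full aggregation path (component means
+ interaction-entropy penalty per replica, then replica mean +/- SEM) and
filters a per-residue decomposition at the -0.5 kcal/mol threshold.
Writes results/gbsa_published.tsv, results/gbsa_replicas.tsv and
results/decomposition_filtered.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from pgpkit import io as pio
from pgpkit.energetics import decompose_filter, gbsa_from_frames, mmgbsa_total
from pgpkit.synthetic import EnergyFramesSpec, gen_energy_frames

OUT = Path(__file__).resolve().parent.parent / "results"

# published component means (kcal/mol): vdw, elect, polar, nonpolar, -TdS
PUBLISHED = {
    "verapamil (substrate site)": (-57.36, -9.45, 31.87, -8.21, 9.28),
    "tariquidar (substrate site)": (-76.09, -25.31, 56.04, -10.30, 10.02),
    "PGG (substrate site)": (-85.52, -87.62, 115.17, -14.20, 29.10),
    "PGG (ATP site)": (-84.72, -65.65, 75.80, -13.31, 16.44),
    "ATP (ATP site)": (-41.73, -519.36, 495.84, -6.55, 50.60),
}

# per-residue decomposition of the substrate-site complex (kcal/mol)
DECOMPOSITION = {
    "F343": -3.66, "F728": -3.49, "F952": -3.38, "Y310": -2.62,
    "Q725": -1.80, "Q990": -1.06, "L65": -0.9, "W232": -0.7,
    "A229": -0.45, "G872": -0.3,
}


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    rows = []
    for label, comps in PUBLISHED.items():
        s = mmgbsa_total(*comps)
        rows.append({"complex": label, **s.as_dict()})
        print(f"{label:<28s} dH = {s.dH:8.2f}  -TdS = {s.minus_TdS:6.2f}  "
              f"dG_bind = {s.dG_bind:8.2f} kcal/mol")
    pio.write_tsv(pd.DataFrame(rows), OUT / "gbsa_published.tsv")
    print("the modulator binds both sites more tightly than the ATP-site "
          "native ligand (-71.45 vs -21.21 kcal/mol at the ATP site).\n")

    frames, truth = gen_energy_frames(EnergyFramesSpec(seed=seed))
    summary, per_replica = gbsa_from_frames(frames, temperature=truth["temperature"])
    pio.write_tsv(per_replica, OUT / "gbsa_replicas.tsv", metadata={"seed": seed})
    print(f"synthetic verapamil-like complex, {per_replica.shape[0]} replicas x "
          f"{frames.groupby('replica').size().iloc[0]} frames:")
    print(f"  dG_bind = {summary.dG_bind:.2f} +/- {summary.sem['dG_bind']:.2f} "
          f"kcal/mol (mean +/- SEM)")
    print(f"  interaction-entropy penalty -TdS = {summary.minus_TdS:.2f} "
          f"+/- {summary.sem['minus_TdS']:.2f} kcal/mol")

    kept = decompose_filter(DECOMPOSITION)
    pio.write_tsv(kept, OUT / "decomposition_filtered.tsv")
    print(f"\nper-residue decomposition: {len(kept)} of {len(DECOMPOSITION)} residues "
          f"contribute below -0.5 kcal/mol; strongest: "
          + ", ".join(f"{r.residue} ({r.energy})" for r in kept.head(3).itertuples()))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
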