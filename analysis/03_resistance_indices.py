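"""Dose-response fits and the resistance/reversal index table.

Two parts: (1) a synthetic CCK-8 titration is generated and refitted to
demonstrate IC50 recovery and IC-level extraction; (2) the published IC50
values of the sensitive and resistant lines (with and without modulator)
are turned into the resistance/reversal index table under the
rounded-intermediate convention.  Writes results/doseresponse_fit.tsv and
results/resistance_table.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from pgpkit import io as pio
from pgpkit.resistance import (
    fit_dose_response,
    ic_level,
    resistance_reversal_table,
)
from pgpkit.synthetic import DoseResponseSpec, gen_dose_response

OUT = Path(__file__).resolve().parent.parent / "results"

# measured IC50s (uM) of doxorubicin: sensitive line 0.64; resistant line
# alone and under 12.5/25/50 ug/mL of the modulator
IC50_SENSITIVE = 0.64
RESISTANT_SERIES = [
    ("DOX", 0.0, 4.54),
    ("DOX+PGG12.5", 12.5, 3.30),
    ("DOX+PGG25", 25.0, 0.95),
    ("DOX+PGG50", 50.0, 0.22),
]


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    spec = DoseResponseSpec(seed=seed, noise_sd=5.0)
    data, truth = gen_dose_response(spec)
    fit = fit_dose_response(data, fix_top=100.0, fix_bottom=0.0)
    fit_row = {
        **vars(fit),
        "true_ic50": truth["ic50"],
        "ic50_err_pct": 100 * (fit.ic50 / truth["ic50"] - 1),
        "ic10": ic_level(fit, 10.0),
        "ic20": ic_level(fit, 20.0),
        "ic30": ic_level(fit, 30.0),
    }
    pio.write_tsv(pd.DataFrame([fit_row]), OUT / "doseresponse_fit.tsv",
                  metadata={"seed": seed})
    print(f"4PL fit of the synthetic titration (true IC50 {truth['ic50']} uM, "
          f"noise sd {spec.noise_sd} points, {spec.n_replicates} replicates):")
    print(f"  IC50 = {fit.ic50:.3f} uM ({fit_row['ic50_err_pct']:+.1f}% vs truth), "
          f"slope h = {fit.hill_slope:.2f}")
    print(f"  sub-lethal doses: IC10 = {fit_row['ic10']:.2f}, "
          f"IC20 = {fit_row['ic20']:.2f}, IC30 = {fit_row['ic30']:.2f} uM")

    table = resistance_reversal_table(IC50_SENSITIVE, RESISTANT_SERIES)
    pio.write_tsv(table, OUT / "resistance_table.tsv")
    print("\nresistance/reversal indices from the measured IC50s "
          "(rounded-intermediate convention):")
    print(table.to_string(index=False))
    print("\nat the highest modulator dose the resistance index collapses from "
          f"{table['resistance_index'].iloc[0]} to {table['resistance_index'].iloc[-1]} "
          f"(reversal index {table['reversal_index'].iloc[-1]}).")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
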