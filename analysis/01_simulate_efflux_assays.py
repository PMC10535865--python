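"""Simulate the live-cell efflux assay series: a control and a titration of
pump inhibition, as measured by THP fluorescence quenching.

Emulates the spectrofluorometric protocol (1 uM THP on 2e6 K562/ADR cells
in 2 mL, 1 s sampling, Triton X-100 at 1600 s) for an untreated control and
four inhibitor doses that progressively block the efflux pump.  Writes the
traces and the generating ground truth under results/assays/.
"""

import json
import sys
from pathlib import Path

from pgpkit import io as pio
from pgpkit.kinetics import TransportParams
from pgpkit.synthetic import DEFAULT_K_ACT, DEFAULT_K_PLUS, UptakeSpec, gen_uptake_trace

# traces are bulky regenerable intermediates: keep them out of results/
OUT = Path(__file__).resolve().parent.parent / "scratch" / "assays"

# fraction of pump activity remaining at each inhibitor dose (ug/mL);
# the control column is 1.0 by definition
DOSE_SERIES = {0.0: 1.0, 6.25: 0.8, 12.5: 0.75, 25.0: 0.7, 50.0: 0.37}
NOISE_SD = 0.5  # a.u., 0.5% of the 100 a.u. initial intensity


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = {}
    for dose, remaining in DOSE_SERIES.items():
        params = TransportParams(
            k_plus=DEFAULT_K_PLUS, k_act=remaining * DEFAULT_K_ACT
        )
        spec = UptakeSpec(seed=seed, params=params, noise_sd=NOISE_SD)
        trace, _ = gen_uptake_trace(spec)
        name = f"trace_pgg{dose:g}.csv"
        pio.write_trace_csv(trace, OUT / name)
        truth[f"{dose:g}"] = {
            "k_plus": params.k_plus,
            "k_act": params.k_act,
            "pump_fraction_remaining": remaining,
            "file": name,
            "events": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in trace.events.items()},
        }
        print(f"dose {dose:>6g} ug/mL: pump at {remaining:.0%}, wrote {name}")
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    print(f"\n{len(DOSE_SERIES)} assays simulated; ground truth in {OUT/'truth.json'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
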