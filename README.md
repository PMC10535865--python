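# pgpkit

Quantitative toolkit for P-glycoprotein (P-gp) inhibition studies in
multidrug-resistant cancer cells: efflux kinetics from live-cell
fluorescence-quenching assays, drug-resistance reversal statistics, and
post-molecular-dynamics binding-energetics bookkeeping.  Written for
pharmacology and computational-chemistry groups who characterize candidate
P-gp modulators (polyphenols such as pentagalloyl glucose, classical
inhibitors such as verapamil or tariquidar) against resistant lines like
K562/ADR.

## What it computes

**Efflux kinetics** (`pgpkit.kinetics`).  Pirarubicin (THP) fluoresces in
solution and is quenched when it intercalates into nuclear DNA, so the
590 nm signal of a stirred cell suspension reports drug transport in real
time.  A three-pool compartmental model (extracellular free C_e, cytosolic
free, nuclear-bound C_n; symmetric passive permeation k₊, active efflux by
the pump k_a, saturable DNA binding) is both forward-simulated and
inverted.  From a trace with its event markers the package recovers

- C_n = C_T (F₀ − F_n)/F₀ and C_N = C_T (F₀ − F_N)/F₀ — nuclear-bound drug
  at steady state and after Triton X-100 permeabilization,
- V₊ and k₊ = V₊/(C_T·ρ) — initial passive uptake rate and per-cell
  permeation coefficient (ρ = cell density),
- C_i = C_n (C_T − C_N)/C_N — free intracellular drug via a linear
  intercalation isotherm,
- V_a = k₊ρ(C_e − C_i) and k_a = V_a/(C_i·ρ) — active efflux rate and
  per-cell pump coefficient from the steady-state flux balance,
- r = k_a(inhibitor)/k_a(control) — the inhibition ratio (1 = pump
  untouched, 0 = fully blocked).

**Resistance metrics** (`pgpkit.resistance`).  Four-parameter logistic
(Hill) fits of viability titrations, v(c) = bottom + (top − bottom)/(1 +
(c/IC₅₀)^h), with IC-level extraction; the resistance index
IC₅₀(resistant)/IC₅₀(sensitive) and the reversal index RI(no
modulator)/RI(modulator), computed on one-decimal rounded intermediates as
printed tables in this field are; 2^(−ΔΔCt) relative expression for qPCR;
fold drug accumulation.

**Binding energetics** (`pgpkit.energetics`, `pgpkit.trajectory`).
MM-GBSA aggregation ΔG_bind = ΔE_vdw + ΔE_elect + ΔG_polar + ΔG_nonpolar +
(−TΔS) from per-frame component tables, with the entropy penalty from the
interaction-entropy formula −TΔS = β⁻¹ ln⟨exp(β ΔE_int)⟩ and replica
mean ± SEM; per-residue decomposition filtering at −0.5 kcal/mol; geometric
hydrogen-bond detection (donor–acceptor < 3.5 Å, D–H···A angle > 120°) with
atom-pair and residue-pair occupancy (residue grouping sums atom pairs, so
values above 100% flag multiple simultaneous bonds); Kabsch-superposed RMSD.

**Synthetic data** (`pgpkit.synthetic`).  Seeded generators for every input
kind — uptake traces with ground-truth transport parameters, Hill-curve
titrations, per-frame energy tables, toy trajectories with planted
hydrogen-bond schedules — so each stage is testable without instrument data.

## Worked example

```python
import numpy as np
from pgpkit.kinetics import AssayConditions, TransportParams, analyze_trace, inhibition_ratio
from pgpkit.synthetic import UptakeSpec, gen_uptake_trace

cond = AssayConditions()            # 1 uM THP, 2e6 cells, 2 mL
rho = cond.cell_density
control = TransportParams(k_plus=1.6e-12, k_act=4.8e-12)     # L/cell/s
treated = TransportParams(k_plus=1.6e-12, k_act=0.37 * 4.8e-12)

est0 = analyze_trace(gen_uptake_trace(UptakeSpec(seed=1, params=control))[0], cond)
esti = analyze_trace(gen_uptake_trace(UptakeSpec(seed=1, params=treated))[0], cond)
print(f"control:  V+ = {est0.V_plus:.2f} nM/s, k_a = {est0.k_a:.2e} L/cell/s")
print(f"treated:  V+ = {esti.V_plus:.2f} nM/s, k_a = {esti.k_a:.2e} L/cell/s")
print(f"inhibition ratio r = {inhibition_ratio(esti.k_a, est0.k_a).ratio:.3f}")
```

prints

```
control:  V+ = 1.65 nM/s, k_a = 4.89e-12 L/cell/s
treated:  V+ = 1.65 nM/s, k_a = 1.87e-12 L/cell/s
inhibition ratio r = 0.383
```

The control uptake rate of ~1.6 nM/s matches the untreated assay; blocking
63% of the pump in the generator is read back as r ≈ 0.38, i.e. 38% of the
efflux activity remaining.

The numbered drivers under `analysis/` run the complete studies (simulated
assay titration, kinetic table with inhibition ratios, resistance/reversal
indices, MM-GBSA summaries, hydrogen-bond occupancy) and write their tables
under `results/`:

```sh
python analysis/01_simulate_efflux_assays.py
python analysis/02_fit_efflux_kinetics.py
...
```

A `pgpkit` command-line interface wraps the same functions
(`pgpkit synth|kinetics|doseresponse|qpcr|mmgbsa|hbonds|traj|run --help`).

## Layout

- `src/pgpkit/` — library: `kinetics`, `resistance`, `energetics`,
  `trajectory`, `synthetic`, `io`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite (unit, property and end-to-end checks)
- `docs/methods.md` — model assumptions, parameter choices, limitations
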