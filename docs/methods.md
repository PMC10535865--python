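# Methods

## Efflux-kinetics model

The live-cell assay adds a fluorescent P-gp substrate (pirarubicin, THP) to
a stirred suspension and follows the 590 nm emission.  THP fluoresces while
free in solution or cytosol and is quenched once intercalated in nuclear
DNA, so the observable is

    F(t) = background + F0_scale · (C_T − C_n(t)) / C_T ,

with C_T the total drug and C_n(t) the DNA-bound pool.  The model tracks
three pools as solution-volume-referred concentrations (nM), which makes
mass conservation C_e + C_c + C_n = C_T exact:

- dC_c/dt = k₊ρ(C_e − c_c) − k_aρ·c_c − [k_on·c_c·(B_max − C_n) − k_off·C_n]
- dC_n/dt = k_on·c_c·(B_max − C_n) − k_off·C_n
- C_e = C_T − C_c − C_n

Here ρ is the cell density (cells/L), k₊ and k_a are per-cell permeation
and pump coefficients (L/cell/s), and c_c = C_c/φ is the *actual* cytosolic
free concentration, with φ = n_cells·v_cell/V the volume fraction the cell
interiors occupy.  This volume bookkeeping is essential: 2×10⁶ cells of
~1 pL in 2 mL occupy φ ≈ 10⁻³ of the cuvette, so at equal free
concentrations inside and outside the cytosolic pool holds a negligible
share of the drug.  It is what makes the assay's closure formulas exact in
the linear-binding regime:

- C_e,ss = C_T − C_n (free drug outside the nucleus),
- C_i = C_n(C_T − C_N)/C_N (linear intercalation isotherm: the bound/free
  ratio at steady state equals the ratio after permeabilization), which
  reduces to C_i = C_e,ss when the pump is off,
- V_a = k₊ρ(C_e,ss − C_i) (steady-state flux balance: net passive influx
  equals pump efflux), k_a = V_a/(C_i·ρ).

Permeabilization (Triton X-100) is modelled as removal of the membrane
barrier: the cytosolic pool merges with the medium and the remaining free
drug re-equilibrates with DNA binding with the pump off, reproducing the
further fluorescence decline seen after the detergent step.

Integration uses `scipy.solve_ivp` (LSODA; the φ⁻¹ factor makes the
cytosolic equation stiff) with rtol = atol = 1e−9.  Since C_e is eliminated
by the mass balance, conservation holds to rounding error at every output
time.

### Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| C_T | 1000 | nM | protocol: 1 µM THP |
| n_cells / V | 2×10⁶ / 2×10⁻³ | cells, L | protocol |
| v_cell | 1×10⁻¹² | L | K562-sized cell (~1 pL) → φ = 10⁻³ |
| k₊ρ | 1.6×10⁻³ | 1/s | reproduces the control uptake rate V₊ = 1.6 nM/s |
| k_aρ | 4.8×10⁻³ | 1/s | control pump/leak ratio k_a/k₊ ≈ 3 |
| k_on | 2×10⁻⁵ | 1/(nM·s) | with B_max gives binding rate k_on·B_max = 1 s⁻¹, fast against permeation, as DNA intercalation is |
| k_off | 0.5 | 1/s | partition ratio K = k_on·B_max/k_off = 2 → about two-thirds of the drug ends up DNA-bound after permeabilization, the visible fluorescence drop |
| B_max | 5×10⁴ | nM | nuclear intercalation capacity far above C_T, so the isotherm stays linear (≤1.2% saturation) and the C_i closure is exact to ~1% |

k_on, k_off and B_max close the model but are not separately identified by
the assay; only their combinations (binding speed, partition ratio,
linearity) matter for the estimators, which is why they are fixed defaults
rather than fitted quantities.

### Estimators

**Initial influx.**  V₊ = (C_T/F₀)·max(−dF/dt) near drug addition.  The
default derivative estimator fits a single exponential B + A·e^(−λt) to the
first 300 s and takes its analytic slope Aλ at t = 0.  A sliding-window
alternative (steepest 20 s linear-regression slope, box-car smoothed) is
available as `method="window"`, but it is dominated by two biases the
global fit avoids: short regression windows under-read a curving decline
(−5…−14% across the parameter grid, measured on noise-free traces), and
taking a maximum over ~100 noisy window slopes biases V₊ upward by 1–2
standard errors.  A simulation study across the grid below gave the
exponential fit a noise-free bias ≤1.3% and a worst-case error of ~11% over
20 noise realizations at 0.5% intensity noise.

**Steady-state levels.**  F_n is the mean over the steady-state window
(default: the final 20% of the pre-permeabilization record), F_N the mean
over the last quarter after the Triton event.  Concentrations are clamped
to [0, C_T] with a warning — measurement noise can push the formula output
slightly out of range and this should not abort a batch.

**Pump coefficient and inhibition ratio.**  V_a and k_a from the closures
above; estimated V_a < 0 (possible under noise when the pump is genuinely
off) is clamped to 0 with a warning, so a fully blocked pump reads exactly
r = 0.  r is invariant to rescaling all intensities because every step is
a ratio of fluorescence levels.

### What the synthetic assays do and do not emulate

The generator produces the protocol's shape — 1 s sampling over 2000 s,
Triton at 1600 s, decline to steady state on the observed time scale,
uptake rates in the measured 1.6–2.7 nM/s range, pump strengths spanning
control to strongly inhibited — with independent additive Gaussian noise
(default sd 0.5% of F₀).  It does not emulate photobleaching, inner-filter
effects, lamp drift, drug metabolism, or correlated instrument noise.
Parameter-recovery results therefore demonstrate the estimators' geometry
and noise behaviour, not robustness to systematic instrument artifacts.
Absolute per-cell coefficients of the published kinetic table are not
reproducible from printed quantities alone (the raw traces are not
deposited); units and trends are honored instead, and the recovery studies
use the bulk rates k₊ρ ∈ {1.6, 2.2, 2.7}×10⁻³ s⁻¹, k_aρ ∈ {1.6, 3.2,
4.8}×10⁻³ s⁻¹ spanning the assay's observed range.  One caveat: with the
pump fully off, equilibration is slowest, and at 1600 s the system is
measurably short of steady state; closure checks for that limit therefore
use a longer simulated record (permeabilization at 5000 s).

## Dose-response and indices

Viability titrations are fitted with the four-parameter logistic by
least squares (lmfit).  When no tested dose brings mean viability below
50% of control the IC50 is not bracketed: the fit reports the largest
tested dose as a lower bound with `converged = False`.  For noisy
triplicate data the 100/0-anchored fit (viability is normalized to
untreated control; full kill at saturating dose) roughly halves the IC50
sampling error relative to the free fit; whether the original tables used
constrained or free fits is not stated, so both are exposed.

IC_level inverts the fitted curve at absolute viability 100 − level, so
IC₁₀/IC₂₀/IC₃₀ are sub-lethal doses in the usual sense.

Resistance and reversal indices divide IC50s and resistance indices
respectively, rounding half-up to one decimal *on the intermediates* by
default: printed tables in this field are only self-consistent under that
convention (7.1/0.3 = 23.7, whereas unrounded quotients give 20.6).
`decimals=None` gives exact arithmetic.  2^(−ΔΔCt) follows the standard
sign convention (a typographically garbled "−2ΔΔCt" in some sources is the
same statistic).

## Binding energetics

Per-frame MM-GBSA component energies are inputs — force-field evaluation,
GB solvation and frame selection happen upstream (dielectric settings and
snapshot choices are recorded as metadata only).  The package aggregates:
ΔH = ΔE_vdw + ΔE_elect + ΔG_polar + ΔG_nonpolar, ΔG_bind = ΔH + (−TΔS),
with −TΔS stored as the additive non-negative penalty exactly as such
tables print it.

The interaction-entropy estimate is −TΔS = β⁻¹ ln⟨e^(βΔE_int)⟩ over frames,
with ΔE_int = E_vdw + E_elect and β = 1/k_BT (k_B = 0.0019872041
kcal/mol/K, T defaulting to the simulation temperature 310 K).  It is
computed through a log-sum-exp, so wildly fluctuating series cannot
overflow; a warning is emitted when a single frame dominates (β·max
fluctuation > 40), where the estimator is known to be unreliable.  The
quantity is non-negative by Jensen's inequality, zero only for a constant
series, and approaches βσ²/2 for Gaussian fluctuations.  No block-averaging
or segmenting is applied; replica-to-replica scatter is reported instead as
mean ± SEM (SD/√n) across independent copies.

Per-residue decomposition filtering keeps residues strictly below the
−0.5 kcal/mol threshold, sorted by energy.

## Hydrogen bonds and RMSD

A bond D–H···A is counted when the donor–acceptor distance is < 3.5 Å and
the D–H···A angle is > 120°.  The angle criterion printed in such tables as
a "donor–acceptor angle" is interpreted as the standard donor–hydrogen–
acceptor geometric angle; a distance-only variant exists for rosters
without explicit hydrogens.  Reported distances are hydrogen–acceptor
means ± SD over bonded frames (the 1.7–2.9 Å range such tables show is an
H···A distance, not D···A).

Occupancy is 100 × bonded frames / total frames per atom pair.  Residue-
pair grouping *sums* the atom-pair occupancies between two residues — the
only convention under which occupancies above 100% (e.g. a glutamate
accepting two simultaneous hydroxyls) are meaningful.  Records under 30%
are suppressed by default, matching the usual reporting threshold.  Whether
the original analyses summed atom pairs or counted multi-bond frames is
unstated; the summing convention is adopted because it reproduces the
published >100% values.

RMSD uses least-squares rigid superposition (proper rotation via
`scipy.spatial.transform.Rotation.align_vectors`, i.e. the Kabsch
solution) after centering; the deviation is computed from the explicitly
rotated coordinates rather than the solver's residual, which loses
precision near zero.  Collinear or planar sets leave the optimal rotation
non-unique; every optimum gives the same minimal deviation, so the
degeneracy warning is suppressed.

## Synthetic-data design

All generators are pure functions of their spec (seed included; NumPy
`default_rng`), and every dataset carries machine-readable ground truth so
round-trip tests contain no hard-coded expectations.  Noise models are
independent Gaussians — the minimal assumption consistent with
mean ± SD triplicate reporting — with configurable sd.  Toy trajectories
place bonded pairs at 2.8 Å / 170° and unbonded pairs at 4.5 Å with ≤0.05 Å
jitter, leaving wide margins to the 3.5 Å / 120° criteria so planted
schedules are recovered exactly; separate pairs sit 30 Å apart so the
schedule cannot cross-bond.

## Problem sizes

Default study sizes: 2000-sample traces, 9-point dose grids in triplicate,
1000 frames × 3 replicas for energy tables, 100–200-frame toy trajectories,
10⁵-sample series for the Gaussian interaction-entropy limit.  The full
test suite runs in a few seconds; `scripts/acceptance.py` in ~2 s.

## Known limitations

- The kinetic closure assumes a linear intercalation isotherm; strongly
  saturated nuclear binding (C_n approaching B_max) would bias C_i and k_a.
- The exponential initial-slope estimator assumes a monotone early decline;
  traces with mixing artifacts in the first seconds should use an explicit
  window start.
- The interaction-entropy estimator has the usual heavy-tail sensitivity;
  for β·fluctuations beyond ~2 the reported value depends on rare frames
  (a warning is emitted, not a correction).
- CSV/PDB readers validate schema and roster constancy but do not attempt
  to repair malformed coordinate files.
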