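"""Compartmental kinetics of P-glycoprotein-mediated anthracycline efflux.

Live K562/ADR cells are stirred in buffer, pirarubicin (THP) is added at
t = 0, and its fluorescence (590 nm) is followed over time.  THP that
intercalates into nuclear DNA is quenched, so the decline of the signal
reports nuclear accumulation.  Once a steady state is reached the membranes
are permeabilized with Triton X-100, which removes the permeation barrier
and lets the remaining free drug equilibrate with the DNA.

The forward model tracks three pools, all expressed as solution-volume
referred concentrations (nM) so that mass is conserved exactly:

* ``C_e`` — free drug in the extracellular medium,
* ``C_c`` — free drug in the cytosol (amount per solution volume; the
  actual cytosolic concentration is ``C_c / phi`` with ``phi`` the tiny
  volume fraction occupied by the cells),
* ``C_n`` — drug intercalated in nuclear DNA (quenched).

Passive permeation is symmetric and driven by the difference between the
extracellular and the actual cytosolic free concentration; the P-gp pump
exports cytosolic free drug; nuclear binding is saturable
(on-rate ``k_on``, off-rate ``k_off``, capacity ``B_max``).

From a measured trace the inverse path recovers the quantities the assay
reports: the three fluorescence levels F0 / Fn / FN, the nuclear
concentrations ``C_n = C_T (F0 - Fn)/F0`` and ``C_N = C_T (F0 - FN)/F0``,
the initial passive uptake rate ``V_+`` with its per-cell coefficient
``k_+``, the active efflux rate ``V_a`` with coefficient ``k_a``, and the
inhibition ratio ``r = k_a(inhibitor) / k_a(control)`` (1 = pump untouched,
0 = pump fully blocked).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp


class KineticsError(ValueError):
    """Invalid input to a kinetics operation."""


class SolverError(RuntimeError):
    """The ODE integrator failed to produce a solution."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayConditions:
    """Physical set-up of one uptake assay.

    Defaults follow the standard protocol: 1 uM THP added to 2e6 cells
    suspended in 2 mL of buffer.

    Parameters
    ----------
    total_drug : total THP added, nM (``C_T``).
    n_cells : number of cells in the cuvette.
    solution_volume : cuvette volume, litres.
    background_intensity : fluorescence of the drug-free suspension, a.u.
    cell_volume : volume of a single cell, litres (K562 cells ~1 pL).
    inhibitor_label, inhibitor_concentration : annotation of the modulator
        present (concentration in ug/mL; 0 = control).
    """

    total_drug: float = 1000.0
    n_cells: float = 2.0e6
    solution_volume: float = 2.0e-3
    background_intensity: float = 0.0
    cell_volume: float = 1.0e-12
    inhibitor_label: str = "control"
    inhibitor_concentration: float = 0.0

    def __post_init__(self) -> None:
        if not (self.total_drug > 0):
            raise KineticsError("total_drug must be > 0")
        if not (self.n_cells > 0):
            raise KineticsError("n_cells must be > 0")
        if not (self.solution_volume > 0):
            raise KineticsError("solution_volume must be > 0")
        if not (self.cell_volume > 0):
            raise KineticsError("cell_volume must be > 0")

    @property
    def cell_density(self) -> float:
        """Cells per litre of solution (rho)."""
        return self.n_cells / self.solution_volume

    @property
    def cytosol_fraction(self) -> float:
        """Fraction of the solution volume occupied by cell interiors."""
        return self.n_cells * self.cell_volume / self.solution_volume


@dataclass(frozen=True)
class TransportParams:
    """Ground-truth kinetic constants of the forward model.

    ``k_plus`` and ``k_act`` are per-cell coefficients in L/cell/s, so the
    corresponding bulk rate constants are ``k_plus * rho`` and
    ``k_act * rho`` (1/s) at cell density ``rho``.  ``k_on`` (1/nM/s),
    ``k_off`` (1/s) and ``b_max`` (nM, solution-volume referred) describe
    saturable intercalation into nuclear DNA.
    """

    k_plus: float
    k_act: float
    k_on: float = 2.0e-5
    k_off: float = 0.5
    b_max: float = 50_000.0

    def __post_init__(self) -> None:
        vals = (self.k_plus, self.k_act, self.k_on, self.k_off, self.b_max)
        if not all(math.isfinite(v) for v in vals):
            raise KineticsError("transport parameters must be finite")
        if any(v < 0 for v in vals[:4]):
            raise KineticsError("rate constants must be >= 0")
        if not (self.b_max > 0):
            raise KineticsError("b_max must be > 0")


@dataclass
class FluorescenceTrace:
    """One recorded uptake assay: times (s), intensities (a.u.), events.

    ``events`` may contain ``drug_added`` (s), ``steady_state_window``
    ((start, end) in s) and ``permeabilization`` (s).
    """

    times: np.ndarray
    intensities: np.ndarray
    events: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise KineticsError("times and intensities must be 1-D and equal length")
        if self.times.size < 2:
            raise KineticsError("a trace needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise KineticsError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise KineticsError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise KineticsError("intensities must be >= 0")
        t0 = self.events.get("drug_added")
        win = self.events.get("steady_state_window")
        tp = self.events.get("permeabilization")
        if t0 is not None and win is not None and not (t0 < win[0]):
            raise KineticsError("drug_added must precede the steady-state window")
        if win is not None and tp is not None and not (win[1] <= tp):
            raise KineticsError("steady-state window must end by permeabilization")


@dataclass
class KineticEstimates:
    """Quantities recovered from one trace (unknown fields stay ``None``).

    Fluorescence levels are background-subtracted; concentrations in nM,
    rates in nM/s, per-cell coefficients in L/cell/s.
    """

    F0: Optional[float] = None
    Fn: Optional[float] = None
    FN: Optional[float] = None
    C_n: Optional[float] = None
    C_N: Optional[float] = None
    C_i: Optional[float] = None
    C_e_ss: Optional[float] = None
    V_plus: Optional[float] = None
    k_plus: Optional[float] = None
    V_a: Optional[float] = None
    k_a: Optional[float] = None


@dataclass(frozen=True)
class InhibitionResult:
    """Pump activity remaining under an inhibitor: r = k_a(i) / k_a(0)."""

    k_a_control: float
    k_a_inhibited: float

    @property
    def ratio(self) -> float:
        return self.k_a_inhibited / self.k_a_control


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def simulate_concentrations(
    params: TransportParams,
    conditions: AssayConditions,
    time_grid: Sequence[float],
    permeabilization_time: Optional[float] = None,
    rtol: float = 1e-9,
    atol: float = 1e-9,
) -> np.ndarray:
    """Integrate the three-pool model; returns an (n, 3) array [C_e, C_c, C_n].

    The grid starts at drug addition (C_e = C_T, C_c = C_n = 0).  At
    ``permeabilization_time`` the membrane barrier is removed: the cytosolic
    pool merges with the medium and the remaining free drug re-equilibrates
    with nuclear binding (pump off).
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or not np.all(np.diff(t) > 0):
        raise KineticsError("time_grid must be 1-D and strictly increasing")
    ct = conditions.total_drug
    rho = conditions.cell_density
    phi = conditions.cytosol_fraction
    kp = params.k_plus * rho
    ka = params.k_act * rho
    k_on, k_off, b_max = params.k_on, params.k_off, params.b_max

    def rhs_intact(_t, y):
        c_c, c_n = y
        cc_act = c_c / phi  # actual cytosolic free concentration
        c_e = ct - c_c - c_n
        perm = kp * (c_e - cc_act)
        pump = ka * cc_act
        bind = k_on * cc_act * (b_max - c_n) - k_off * c_n
        return (perm - pump - bind, bind)

    def rhs_permeabilized(_t, y):
        (c_n,) = y
        free = ct - c_n
        return (k_on * free * (b_max - c_n) - k_off * c_n,)

    t_perm = permeabilization_time
    out = np.empty((t.size, 3))

    if t_perm is None or t_perm >= t[-1]:
        pre, post = t, t[:0]
    else:
        if t_perm <= t[0]:
            raise KineticsError("permeabilization_time must lie inside the grid")
        pre = t[t <= t_perm]
        post = t[t > t_perm]

    sol = solve_ivp(
        rhs_intact,
        (t[0], pre[-1]),
        (0.0, 0.0),
        t_eval=pre,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(f"integration failed before permeabilization: {sol.message}")
    c_c, c_n = sol.y
    out[: pre.size, 0] = ct - c_c - c_n
    out[: pre.size, 1] = c_c
    out[: pre.size, 2] = c_n

    if post.size:
        # membranes removed: cytosolic free drug joins the medium
        c_n0 = c_n[-1]
        sol2 = solve_ivp(
            rhs_permeabilized,
            (t_perm if t_perm is not None else pre[-1], post[-1]),
            (c_n0,),
            t_eval=post,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol2.success:
            raise SolverError(f"integration failed after permeabilization: {sol2.message}")
        c_n_post = sol2.y[0]
        out[pre.size :, 0] = ct - c_n_post
        out[pre.size :, 1] = 0.0
        out[pre.size :, 2] = c_n_post

    return out


def simulate_uptake(
    params: TransportParams,
    conditions: AssayConditions,
    time_grid: Sequence[float],
    permeabilization_time: Optional[float] = None,
    f0_scale: float = 100.0,
) -> FluorescenceTrace:
    """Forward-simulate a noise-free uptake trace.

    The observable is ``F(t) = background + f0_scale * (C_T - C_n(t)) / C_T``:
    only DNA-intercalated drug is quenched.  Events are populated with the
    drug-addition time, a default steady-state window (last 20% of the
    pre-permeabilization record) and the permeabilization time.
    """
    conc = simulate_concentrations(params, conditions, time_grid, permeabilization_time)
    t = np.asarray(time_grid, dtype=float)
    ct = conditions.total_drug
    f = conditions.background_intensity + f0_scale * (ct - conc[:, 2]) / ct
    t_end = permeabilization_time if permeabilization_time is not None else t[-1]
    events = {
        "drug_added": float(t[0]),
        "steady_state_window": (
            float(t[0] + 0.8 * (t_end - t[0])),
            float(t_end),
        ),
    }
    if permeabilization_time is not None:
        events["permeabilization"] = float(permeabilization_time)
    return FluorescenceTrace(times=t, intensities=f, events=events)


def steady_state_concentrations(
    params: TransportParams, conditions: AssayConditions
) -> np.ndarray:
    """Algebraic fixed point [C_e, C_c, C_n] of the intact-cell model."""
    ct = conditions.total_drug
    rho = conditions.cell_density
    phi = conditions.cytosol_fraction
    kp = params.k_plus * rho
    ka = params.k_act * rho
    if kp == 0:
        return np.array([ct, 0.0, 0.0])
    # at stationarity: kp (C_e - cc) = ka cc  and  k_on cc (B - C_n) = k_off C_n
    # with mass balance C_e + phi*cc + C_n = C_T; reduce to one equation in cc.
    from scipy.optimize import brentq

    def resid(cc):
        c_e = cc * (kp + ka) / kp
        c_n = params.k_on * cc * params.b_max / (params.k_off + params.k_on * cc)
        return c_e + phi * cc + c_n - ct

    cc = brentq(resid, 0.0, ct, xtol=1e-12 * ct)
    c_e = cc * (kp + ka) / kp
    c_n = params.k_on * cc * params.b_max / (params.k_off + params.k_on * cc)
    return np.array([c_e, phi * cc, c_n])


# ---------------------------------------------------------------------------
# inverse path
# ---------------------------------------------------------------------------


def _window_mean(trace: FluorescenceTrace, window: Sequence[float]) -> float:
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise KineticsError("window start must precede window end")
    if lo < trace.times[0] or hi > trace.times[-1]:
        raise KineticsError(
            f"window [{lo}, {hi}] s lies outside the trace "
            f"[{trace.times[0]}, {trace.times[-1]}] s"
        )
    mask = (trace.times >= lo) & (trace.times <= hi)
    if not mask.any():
        raise KineticsError(f"no samples fall inside window [{lo}, {hi}] s")
    return float(trace.intensities[mask].mean())


def concentrations_from_trace(
    trace: FluorescenceTrace,
    conditions: AssayConditions,
    post_perm_window: Optional[Sequence[float]] = None,
) -> KineticEstimates:
    """Recover F0/Fn/FN and the nuclear concentrations from a trace.

    ``F0`` is the (background-subtracted) intensity at drug addition, ``Fn``
    the mean over the steady-state window and ``FN`` the mean over a
    post-permeabilization window (by default the last quarter of the record
    after the Triton event).  ``C_n = C_T (F0 - Fn)/F0`` and
    ``C_N = C_T (F0 - FN)/F0``; both are clamped to [0, C_T] with a warning.
    """
    events = trace.events
    if "drug_added" not in events:
        raise KineticsError("missing event marker: drug_added")
    if "steady_state_window" not in events:
        raise KineticsError("missing event marker: steady_state_window")
    t0 = float(events["drug_added"])
    if not (trace.times[0] <= t0 <= trace.times[-1]):
        raise KineticsError("drug_added lies outside the trace")
    bg = conditions.background_intensity
    f0 = float(np.interp(t0, trace.times, trace.intensities)) - bg
    if f0 <= 0:
        raise KineticsError("F0 must be positive after background subtraction")
    fn = _window_mean(trace, events["steady_state_window"]) - bg

    ct = conditions.total_drug
    est = KineticEstimates(F0=f0, Fn=fn)
    est.C_n = _clamped(ct * (f0 - fn) / f0, ct, "C_n")

    t_perm = events.get("permeabilization")
    if t_perm is not None:
        if post_perm_window is None:
            t_end = trace.times[-1]
            post_perm_window = (t_perm + 0.75 * (t_end - t_perm), t_end)
        fN = _window_mean(trace, post_perm_window) - bg
        est.FN = fN
        est.C_N = _clamped(ct * (f0 - fN) / f0, ct, "C_N")
    return est


def _clamped(value: float, ct: float, name: str) -> float:
    if value < 0 or value > ct:
        warnings.warn(
            f"{name} = {value:.4g} nM outside [0, C_T]; clamped", stacklevel=3
        )
        return float(np.clip(value, 0.0, ct))
    return float(value)


def estimate_initial_influx(
    trace: FluorescenceTrace,
    conditions: AssayConditions,
    window: float = 300.0,
    subwindow: float = 20.0,
    method: str = "exponential",
) -> tuple[float, float]:
    """Initial passive uptake rate ``V_+`` (nM/s) and coefficient ``k_+``.

    ``V_+ = (C_T/F0) * max(-dF/dt)`` and ``k_+ = V_+ / (C_T * rho)``.  Two
    derivative estimators are available:

    * ``"exponential"`` (default) — least-squares fit of
      ``F(t) = B + A exp(-lambda t)`` to the first ``window`` seconds after
      drug addition; the steepest decline is the analytic derivative
      ``A * lambda`` at t = 0.  The global fit removes both the curvature
      bias of short regression windows and the selection bias of taking a
      maximum over noisy slopes.
    * ``"window"`` — steepest linear-regression slope over sliding
      ``subwindow``-second segments within the window (box-car smoothed
      over 9 samples first).
    """
    if window < subwindow:
        raise KineticsError("window must be at least one subwindow long")
    t0 = float(trace.events.get("drug_added", trace.times[0]))
    mask = (trace.times >= t0) & (trace.times <= t0 + window)
    t = trace.times[mask] - t0
    f = trace.intensities[mask]
    if t.size < 5:
        raise KineticsError("need at least 5 samples in the influx window")
    f0 = float(np.interp(t0, trace.times, trace.intensities)) - conditions.background_intensity
    if f0 <= 0:
        raise KineticsError("F0 must be positive after background subtraction")

    if method == "exponential":
        steepest = _steepest_slope_exponential(t, f)
    elif method == "window":
        steepest = _steepest_slope_window(t, f, subwindow)
    else:
        raise KineticsError("method must be 'exponential' or 'window'")

    v_plus = conditions.total_drug / f0 * max(-steepest, 0.0)
    if v_plus == 0.0:
        warnings.warn("trace is flat over the influx window; V_+ = 0", stacklevel=2)
    k_plus = v_plus / (conditions.total_drug * conditions.cell_density)
    return float(v_plus), float(k_plus)


def _steepest_slope_exponential(t: np.ndarray, f: np.ndarray) -> float:
    """Derivative at t = 0 of a fitted single exponential decline."""
    from scipy.optimize import curve_fit

    span = f[0] - f[-1]
    if abs(span) < 1e-12 * max(abs(f[0]), 1.0):
        return 0.0

    def model(tt, a, lam, b):
        return b + a * np.exp(-lam * tt)

    lam0 = 1.0 / max(t[-1] / 2.0, 1e-6)
    try:
        popt, _ = curve_fit(
            model,
            t,
            f,
            p0=(span, lam0, f[-1]),
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError:
        # fall back to the windowed estimator on pathological traces
        return _steepest_slope_window(t, f, min(20.0, t[-1] - t[0]))
    a, lam, _b = popt
    return float(min(-a * lam, 0.0))


def _steepest_slope_window(t: np.ndarray, f: np.ndarray, subwindow: float) -> float:
    """Steepest linear-regression slope over sliding sub-windows."""
    smooth = 9
    if f.size > smooth:
        kernel = np.ones(smooth) / smooth
        f = np.convolve(f, kernel, mode="valid")
        half = (smooth - 1) // 2
        t = t[half : half + f.size]
    steepest = 0.0
    found = False
    for i in range(t.size):
        j = int(np.searchsorted(t, t[i] + subwindow, side="right"))
        if j - i < 3 or t[j - 1] - t[i] < 0.5 * subwindow:
            continue
        tt, ff = t[i:j], f[i:j]
        steepest = min(steepest, float(np.polyfit(tt - tt[0], ff, 1)[0]))
        found = True
    if not found:
        raise KineticsError("influx window shorter than the regression subwindow")
    return steepest


def estimate_active_efflux(
    est: KineticEstimates,
    conditions: AssayConditions,
    k_plus: float,
) -> KineticEstimates:
    """Close the steady-state balance and estimate the pump parameters.

    Uses the three measured fluorescence levels only:

    * ``C_e_ss = C_T - C_n`` — free drug outside the nucleus at steady state
      (the cytosolic pool holds a negligible share of the volume);
    * ``C_i = C_n (C_T - C_N)/C_N`` — intracellular free concentration from
      a linear intercalation isotherm (bound/free ratio at steady state
      equals the ratio after permeabilization);
    * ``V_a = k_+ rho (C_e_ss - C_i)`` — at steady state net passive influx
      balances active efflux; ``k_a = V_a / (C_i rho)``.
    """
    if est.C_n is None or est.C_N is None:
        raise KineticsError(
            "active-efflux estimation needs C_n and C_N "
            "(no permeabilization step in this trace?)"
        )
    if est.C_N <= 0:
        raise KineticsError("C_N must be positive to close the isotherm")
    ct = conditions.total_drug
    rho = conditions.cell_density
    c_n, c_N = est.C_n, est.C_N
    if c_n > c_N:
        warnings.warn(
            f"C_n = {c_n:.4g} exceeds C_N = {c_N:.4g}; clamping C_n to C_N",
            stacklevel=2,
        )
        c_n = c_N
    out = replace_fields(est)
    out.C_e_ss = ct - c_n
    out.C_i = c_n * (ct - c_N) / c_N
    v_a = k_plus * rho * (out.C_e_ss - out.C_i)
    if v_a < 0:
        warnings.warn("estimated V_a < 0; clamped to 0", stacklevel=2)
        v_a = 0.0
    out.V_a = float(v_a)
    if out.C_i == 0:
        if v_a > 0:
            raise KineticsError("degenerate trace: C_i = 0 with V_a > 0")
        out.k_a = 0.0
    else:
        out.k_a = float(v_a / (out.C_i * rho))
    out.k_plus = float(k_plus)
    return out


def replace_fields(est: KineticEstimates) -> KineticEstimates:
    """Shallow copy of a KineticEstimates record."""
    return KineticEstimates(**vars(est))


def inhibition_ratio(k_a_inhibited: float, k_a_control: float) -> InhibitionResult:
    """Ratio r = k_a(inhibitor)/k_a(control); 1 = no inhibition, 0 = full block."""
    if not (k_a_control > 0):
        raise KineticsError("control efflux coefficient must be > 0")
    if k_a_inhibited < 0:
        raise KineticsError("efflux coefficients must be >= 0")
    return InhibitionResult(k_a_control=k_a_control, k_a_inhibited=k_a_inhibited)


def analyze_trace(
    trace: FluorescenceTrace,
    conditions: AssayConditions,
    window: float = 120.0,
    subwindow: float = 20.0,
) -> KineticEstimates:
    """Full inverse pipeline on one trace: levels -> influx -> efflux."""
    est = concentrations_from_trace(trace, conditions)
    v_plus, k_plus = estimate_initial_influx(
        trace, conditions, window=window, subwindow=subwindow
    )
    est.V_plus, est.k_plus = v_plus, k_plus
    if est.C_N is not None and est.C_N > 0:
        full = estimate_active_efflux(est, conditions, k_plus)
        full.V_plus = v_plus
        return full
    return est


def estimate_inhibition(
    trace_inhibited: FluorescenceTrace,
    trace_control: FluorescenceTrace,
    conditions_inhibited: AssayConditions,
    conditions_control: AssayConditions,
    **kwargs,
) -> tuple[InhibitionResult, KineticEstimates, KineticEstimates]:
    """Estimate r from an inhibited and a control trace."""
    est_i = analyze_trace(trace_inhibited, conditions_inhibited, **kwargs)
    est_0 = analyze_trace(trace_control, conditions_control, **kwargs)
    if est_i.k_a is None or est_0.k_a is None:
        raise KineticsError("both traces must include a permeabilization step")
    return inhibition_ratio(est_i.k_a, est_0.k_a), est_i, est_0
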