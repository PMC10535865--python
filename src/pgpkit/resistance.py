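"""Dose-response fitting and multidrug-resistance reversal statistics.

Viability-versus-dose tables (CCK-8 style, percent of untreated control)
are fitted with a four-parameter logistic (Hill) curve

    v(c) = bottom + (top - bottom) / (1 + (c / ic50)^h)

from which IC50 and arbitrary IC levels are extracted.  The resistance
index divides the IC50 of the resistant line (with or without modulator)
by the IC50 of the sensitive line without modulator; the reversal index
divides the no-modulator resistance index by the with-modulator one.
Printed tables in this field round each intermediate to one decimal
(half-up), so the indices are computed on rounded intermediates by
default, with ``decimals=None`` for exact arithmetic.

Also includes the 2^-ddCt relative-expression statistic for qPCR and the
fold-accumulation ratio for intracellular drug-uptake readings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lmfit import Model


class DoseResponseError(ValueError):
    """Invalid input to a dose-response or index operation."""


@dataclass
class DoseResponseData:
    """Replicate-resolved viability table: parallel dose/viability arrays."""

    doses: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.doses.shape != self.viability.shape or self.doses.ndim != 1:
            raise DoseResponseError("doses and viability must be parallel 1-D arrays")
        if np.any(self.doses < 0):
            raise DoseResponseError("doses must be >= 0")
        if not np.all(np.isfinite(self.viability)):
            raise DoseResponseError("viability must be finite")
        if np.unique(self.doses).size < 4:
            raise DoseResponseError("need at least 4 distinct doses")
        if 0.0 not in self.doses:
            raise DoseResponseError("dose 0 (normalization anchor) must be present")


@dataclass
class HillFit:
    """Fitted 4-parameter logistic with an honest convergence flag."""

    ic50: float
    hill_slope: float
    top: float
    bottom: float
    rss: float
    converged: bool


def _hill(c, ic50, h, top, bottom):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ic50) ** h, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_dose_response(
    data: DoseResponseData,
    fix_top: Optional[float] = None,
    fix_bottom: Optional[float] = None,
) -> HillFit:
    """Least-squares 4PL fit; top/bottom may be fixed (e.g. 100/0).

    When no dose pushes mean viability below the curve midpoint the IC50 is
    not bracketed by the data: the fit reports the largest tested dose as a
    lower bound and sets ``converged = False``.
    """
    doses, viab = data.doses, data.viability
    if np.allclose(viab, viab[0]):
        raise DoseResponseError("all viabilities equal: IC50 not identifiable")

    per_dose = pd.DataFrame({"dose": doses, "v": viab}).groupby("dose")["v"].mean()
    top0 = fix_top if fix_top is not None else float(per_dose.iloc[0])
    bottom0 = fix_bottom if fix_bottom is not None else float(per_dose.min())

    positive = np.sort(np.unique(doses[doses > 0]))
    # IC50 is bracketed only if some dose halves viability relative to control
    below = per_dose[per_dose.index > 0] < 50.0
    ic50_0 = float(positive[np.argmin(np.abs(per_dose[per_dose.index > 0] - 50.0))])

    model = Model(_hill)
    params = model.make_params(ic50=ic50_0, h=1.0, top=top0, bottom=bottom0)
    params["ic50"].set(min=1e-12 * positive.max(), max=1e6 * positive.max())
    params["h"].set(min=1e-3, max=50.0)
    if fix_top is not None:
        params["top"].set(value=fix_top, vary=False)
    if fix_bottom is not None:
        params["bottom"].set(value=fix_bottom, vary=False)
    else:
        params["bottom"].set(min=min(0.0, bottom0))
    result = model.fit(viab, params, c=doses)

    bracketed = bool(below.any())
    converged = bool(result.success) and bracketed and result.params["ic50"].value <= positive.max() * 10
    ic50 = float(result.params["ic50"].value) if bracketed else float(positive.max())
    return HillFit(
        ic50=ic50,
        hill_slope=float(result.params["h"].value),
        top=float(result.params["top"].value),
        bottom=float(result.params["bottom"].value),
        rss=float(np.sum(result.residual**2)),
        converged=converged,
    )


def ic_level(fit: HillFit, level: float) -> float:
    """Dose inhibiting growth by ``level`` percent of the untreated control.

    Closed-form inversion of the fitted curve at the target viability
    ``100 - level`` (so IC_50 is the dose giving 50% viability; for a
    100/0-anchored curve, ``c = ic50 * (level / (100 - level))^(1/h)``).
    """
    if not fit.converged:
        raise DoseResponseError("fit did not converge; IC levels are undefined")
    if not (0.0 < level < 100.0):
        raise DoseResponseError("level must lie in (0, 100)")
    target = 100.0 - level
    if not (fit.bottom < target < fit.top):
        raise DoseResponseError("requested level lies outside the fitted range")
    return float(fit.ic50 * ((fit.top - target) / (target - fit.bottom)) ** (1.0 / fit.hill_slope))


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero at ``decimals`` (matches printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def resistance_index(
    ic50_resistant: float,
    ic50_sensitive_no_mod: float,
    decimals: Optional[int] = 1,
) -> float:
    """IC50(resistant line, +/- modulator) / IC50(sensitive line, no modulator)."""
    if not (ic50_resistant > 0 and ic50_sensitive_no_mod > 0):
        raise DoseResponseError("IC50 inputs must be positive")
    q = ic50_resistant / ic50_sensitive_no_mod
    return q if decimals is None else round_half_up(q, decimals)


def reversal_index(
    ri_without_mod: float,
    ri_with_mod: float,
    decimals: Optional[int] = 1,
) -> float:
    """Fold reduction of the resistance index by the modulator."""
    if not (ri_without_mod > 0 and ri_with_mod > 0):
        raise DoseResponseError("resistance indices must be positive")
    q = ri_without_mod / ri_with_mod
    return q if decimals is None else round_half_up(q, decimals)


def resistance_reversal_table(
    ic50_sensitive_no_mod: float,
    treatments: Sequence[tuple[str, float, float]],
    decimals: Optional[int] = 1,
) -> pd.DataFrame:
    """Assemble the resistance/reversal table from fitted IC50s.

    ``treatments`` lists (modulator_label, modulator_conc, ic50_resistant);
    the first row must be the no-modulator condition (its reversal index
    is 1 by definition).
    """
    if not treatments:
        raise DoseResponseError("at least the no-modulator row is required")
    rows = []
    ri0 = None
    for i, (label, conc, ic50_r) in enumerate(treatments):
        ri = resistance_index(ic50_r, ic50_sensitive_no_mod, decimals=decimals)
        if i == 0:
            ri0 = ri
            rev: float = 1.0
        else:
            rev = reversal_index(ri0, ri, decimals=decimals)
        rows.append(
            {
                "modulator_label": label,
                "modulator_conc": conc,
                "ic50_sensitive_no_mod": ic50_sensitive_no_mod,
                "ic50_resistant": ic50_r,
                "resistance_index": ri,
                "reversal_index": rev,
            }
        )
    return pd.DataFrame(rows)


def ddct_expression(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression 2^-ddCt normalized to a reference gene and control."""
    cts = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(math.isfinite(c) for c in cts):
        raise DoseResponseError("all Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


def ddct_table(
    qpcr: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_sample: str,
) -> pd.DataFrame:
    """Per-sample 2^-ddCt from a long qPCR table (columns sample, gene, ct)."""
    need = {"sample", "gene", "ct"}
    if not need.issubset(qpcr.columns):
        raise DoseResponseError(f"qPCR table must have columns {sorted(need)}")
    mean_ct = qpcr.groupby(["sample", "gene"])["ct"].mean()
    try:
        ct_t_ctrl = mean_ct[(control_sample, target_gene)]
        ct_r_ctrl = mean_ct[(control_sample, reference_gene)]
    except KeyError as exc:
        raise DoseResponseError(f"control sample/gene missing from table: {exc}") from exc
    rows = []
    for sample in qpcr["sample"].unique():
        try:
            fold = ddct_expression(
                mean_ct[(sample, target_gene)],
                mean_ct[(sample, reference_gene)],
                ct_t_ctrl,
                ct_r_ctrl,
            )
        except KeyError as exc:
            raise DoseResponseError(f"sample {sample!r} missing gene: {exc}") from exc
        rows.append({"sample": sample, "relative_expression": fold})
    return pd.DataFrame(rows)


def accumulation_fold(
    intensity_treated: float,
    intensity_control: float,
    background: float = 0.0,
) -> float:
    """Background-subtracted fold accumulation of intracellular drug."""
    ctrl = intensity_control - background
    if not (ctrl > 0):
        raise DoseResponseError("control intensity must exceed the background")
    return float(max(intensity_treated - background, 0.0) / ctrl)
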