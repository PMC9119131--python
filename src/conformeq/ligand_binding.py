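"""Titration analysis under the conformational-selection assumption.

A ligand binds the WT conformer, depleting its unbound pool and pulling the
SLIP⇌WT equilibrium towards WT.  Bound-WT peaks broaden, so the bound
concentration cannot be read off directly; instead, volumes of peaks that
show no chemical-shift change (which report each conformer's *total*
concentration) are scaled against the zero-ligand spectrum:

    C_WT,T  = C_WT,0  * (V_WT / V_WT,0)
    C_SLIP  = C_SLIP,0 * (V_SLIP / V_SLIP,0)

and, assuming unbound WT stays in the apo equilibrium with SLIP,

    C_WT,B  = C_WT,T − keq_apo · C_SLIP

(for a 50:50 apo sample keq_apo = 1 and this is simply C_WT,T − C_SLIP).
The bound-WT series is then fit to a single-site isotherm

    C_WT,B = Bmax · C_L / (Kd + C_L)

for the dissociation constant Kd and maximal binding Bmax.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .population_quant import PeakVolumeTable, scale_concentrations

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "bound_wt_series",
    "fit_isotherm",
    "lower_bound_kd",
    "methyl_titration_fit",
    "titration_fit",
]

logger = logging.getLogger(__name__)


@dataclass
class TitrationSeries:
    """A ligand-titration series of conformer-labelled peak volumes.

    The peak table's ``covariate`` column holds the total ligand
    concentration (µM); the first point must be the zero-ligand reference,
    which defines the reference volumes and the conformer pools
    ``c_wt_0`` / ``c_slip_0``.  ``keq_apo`` defaults to their ratio.
    """

    table: PeakVolumeTable
    c_wt_0: float
    c_slip_0: float
    keq_apo: float | None = None
    #: populated by bound_wt_series: per-point (CL, C_WT,T, C_SLIP, C_WT,B)
    derived: list[tuple[float, float, float, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.c_wt_0 <= 0 or self.c_slip_0 <= 0:
            raise ValueError("zero-ligand conformer concentrations must be > 0")
        if self.keq_apo is None:
            self.keq_apo = self.c_wt_0 / self.c_slip_0
        cls = self.ligand_concentrations
        if not cls or cls[0] != 0.0:
            raise ValueError(
                "titration requires a zero-ligand reference as its first point; "
                f"got ligand grid {cls}"
            )

    @property
    def p_total(self) -> float:
        return self.c_wt_0 + self.c_slip_0

    @property
    def ligand_concentrations(self) -> list[float]:
        return [self.table.covariate_of(c) for c in self.table.condition_ids]


@dataclass(frozen=True)
class BindingFit:
    """Single-site isotherm fit: Kd and Bmax in µM with standard errors."""

    kd: float
    bmax: float
    se_kd: float
    se_bmax: float
    residuals: tuple[float, ...]

    def __post_init__(self):
        if self.kd <= 0 or self.bmax <= 0:
            raise ValueError("kd and bmax must be positive")

    def predict(self, cl) -> np.ndarray:
        cl = np.asarray(cl, dtype=float)
        return self.bmax * cl / (self.kd + cl)


def bound_wt_series(series: TitrationSeries) -> list[float]:
    """Bound-WT concentration (µM) at every titration point.

    Applies the reference-volume scaling and the unchanged-apo-equilibrium
    inversion described in the module docstring.  Negative values (noise can
    push the inversion slightly below zero) are clipped to 0 with a warning
    so the ligand grid stays intact for fitting.

    Side effect: fills ``series.derived`` with per-point
    ``(CL, C_WT,T, C_SLIP, C_WT,B)`` tuples for reporting.
    """
    conds = series.table.condition_ids
    ref = series.table.condition(conds[0])
    series.derived = []
    out = []
    for cid in conds:
        cl = series.table.covariate_of(cid)
        cond = series.table.condition(cid)
        c_wt_t, c_slip = scale_concentrations(cond, ref, series.c_wt_0, series.c_slip_0)
        c_wt_b = c_wt_t - series.keq_apo * c_slip
        if c_wt_b < 0:
            warnings.warn(
                f"clipped negative bound-WT concentration ({c_wt_b:.3g} µM) to 0 "
                f"at CL={cl} µM",
                stacklevel=2,
            )
            c_wt_b = 0.0
        series.derived.append((cl, c_wt_t, c_slip, c_wt_b))
        out.append(c_wt_b)
    return out


def fit_isotherm(cl, cwt_b) -> BindingFit:
    """Nonlinear least-squares fit of the 1:1 isotherm Bmax·CL/(Kd+CL).

    Starting values are Kd₀ = median nonzero CL and Bmax₀ = 1.2 × max
    observed bound concentration, with positivity bounds (Kd ≤ 10⁶ µM).

    Raises
    ------
    ValueError
        Fewer than 3 points, missing CL = 0 anchor, negative bound values,
        or an all-zero series (no binding signal).
    RuntimeError
        Optimiser non-convergence (starting values reported).
    """
    cl = np.asarray(cl, dtype=float)
    cwt_b = np.asarray(cwt_b, dtype=float)
    if cl.shape != cwt_b.shape:
        raise ValueError("cl and cwt_b must have the same length")
    if len(cl) < 3:
        raise ValueError(f"isotherm fit needs >= 3 points, got {len(cl)}")
    if 0.0 not in cl:
        raise ValueError("isotherm fit requires a CL = 0 reference point")
    if (cwt_b < 0).any():
        raise ValueError("bound-WT concentrations must be >= 0")
    if not (cwt_b > 0).any():
        raise ValueError("no binding: bound-WT concentration is zero at every point")

    kd0 = float(np.median(cl[cl > 0]))
    bmax0 = 1.2 * float(cwt_b.max())

    def isotherm(x, kd, bmax):
        return bmax * x / (kd + x)

    try:
        popt, pcov = curve_fit(
            isotherm,
            cl,
            cwt_b,
            p0=[kd0, bmax0],
            bounds=([1e-12, 1e-12], [1e6, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"isotherm fit did not converge (start Kd={kd0}, Bmax={bmax0}): {err}"
        ) from err
    se = np.sqrt(np.diag(pcov))
    resid = cwt_b - isotherm(cl, *popt)
    return BindingFit(
        kd=float(popt[0]),
        bmax=float(popt[1]),
        se_kd=float(se[0]),
        se_bmax=float(se[1]),
        residuals=tuple(float(r) for r in resid),
    )


def lower_bound_kd(cl_max: float, max_bound_fraction: float) -> float:
    """Lower bound (µM) on the Kd of an invisible bound state.

    If a bound state is undetectable, its occupancy at the highest ligand
    concentration ``cl_max`` is at most some fraction ``f``.  Inverting the
    1:1 isotherm at that occupancy gives the smallest Kd compatible with
    invisibility:

        Kd ≥ cl_max · (1 − f) / f

    so f = 0.10 at cl_max = 1000 µM bounds Kd ≥ 9000 µM (9 mM).
    """
    if not (0.0 < max_bound_fraction < 1.0):
        raise ValueError(
            f"max_bound_fraction must lie in (0, 1), got {max_bound_fraction}"
        )
    if cl_max <= 0:
        raise ValueError(f"cl_max must be > 0, got {cl_max}")
    return cl_max * (1.0 - max_bound_fraction) / max_bound_fraction


def titration_fit(series: TitrationSeries) -> BindingFit:
    """Full pipeline on one titration: volume inversion then isotherm fit."""
    cwt_b = bound_wt_series(series)
    return fit_isotherm(series.ligand_concentrations, cwt_b)


def methyl_titration_fit(series: TitrationSeries) -> BindingFit:
    """Titration fit on a methyl-peak series.

    Identical machinery to the amide pipeline — slow-exchange methyl peak
    volumes report the same conformer totals — kept as a named entry point
    so amide and methyl analyses are reported separately.
    """
    logger.info("methyl titration: keq_apo=%g held fixed across all points", series.keq_apo)
    return titration_fit(series)
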