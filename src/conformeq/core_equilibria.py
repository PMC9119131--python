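"""Four-state conformational-selection model and coupled-equilibrium solver.

A protein interconverts between two stably folded conformers, here called
``WT`` and ``SLIP``, in slow exchange.  A ligand binds the WT conformer with
1:1 stoichiometry and may bind the SLIP conformer with a (much weaker)
affinity of its own.  The four protein states and free ligand are linked by
a thermodynamic cycle:

    SLIP_u  <-- keq_apo -->  WT_u
      |                        |
   kd_slip                   kd_wt
      |                        |
    SLIP_b  <-- keq_bound --> WT_b

with ``keq_apo = [WT_u]/[SLIP_u]`` and dissociation constants in µM.  Cycle
closure fixes ``keq_bound = keq_apo * kd_slip / kd_wt``.

All concentrations in this package are micromolar (µM).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy.optimize import brentq

__all__ = [
    "NON_BINDING",
    "FourStateModel",
    "ConformerState",
    "SolverError",
    "solve_four_state",
    "keq_bound",
    "predict_shift_curve",
]


class _NonBinding:
    """Sentinel for a conformer that does not bind ligand (Kd -> infinity).

    Used instead of ``math.inf`` so that intent is explicit in configs and
    reprs, and so arithmetic never silently overflows.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NON_BINDING"


#: Module-level sentinel: pass as ``kd_slip`` (or ``kd_wt``) to mark that
#: conformer as binding-incompetent.
NON_BINDING = _NonBinding()


class SolverError(RuntimeError):
    """Raised when the coupled-equilibrium solver fails to converge."""


def _is_non_binding(kd) -> bool:
    return kd is NON_BINDING or kd is None or (isinstance(kd, float) and math.isinf(kd))


@dataclass(frozen=True)
class FourStateModel:
    """Thermodynamic parameters of the four-state cycle.

    Parameters
    ----------
    keq_apo
        Apo conformational equilibrium constant, ``[WT_u]/[SLIP_u]``
        (dimensionless, > 0).  A 50:50 mixture has ``keq_apo = 1``.
    kd_wt
        Ligand dissociation constant of the WT conformer, µM.
    kd_slip
        Ligand dissociation constant of the SLIP conformer, µM, or the
        :data:`NON_BINDING` sentinel when the bound SLIP state is
        experimentally invisible.
    """

    keq_apo: float
    kd_wt: float
    kd_slip: object = NON_BINDING

    def __post_init__(self):
        if not (self.keq_apo > 0):
            raise ValueError(f"keq_apo must be > 0, got {self.keq_apo}")
        if _is_non_binding(self.kd_wt):
            if _is_non_binding(self.kd_slip):
                raise ValueError("at least one conformer must bind ligand")
        elif not (self.kd_wt > 0):
            raise ValueError(f"kd_wt must be > 0, got {self.kd_wt}")
        if not _is_non_binding(self.kd_slip) and not (self.kd_slip > 0):
            raise ValueError(f"kd_slip must be > 0 or NON_BINDING, got {self.kd_slip}")

    @property
    def slip_binds(self) -> bool:
        return not _is_non_binding(self.kd_slip)

    @property
    def wt_binds(self) -> bool:
        return not _is_non_binding(self.kd_wt)


@dataclass(frozen=True)
class ConformerState:
    """Solved concentrations (µM) of the four protein states and free ligand."""

    c_wt_unbound: float
    c_wt_bound: float
    c_slip_unbound: float
    c_slip_bound: float
    c_ligand_free: float
    p_total: float
    l_total: float

    @property
    def c_wt_total(self) -> float:
        """Total WT-conformer concentration, bound + unbound (µM)."""
        return self.c_wt_unbound + self.c_wt_bound

    @property
    def c_slip_total(self) -> float:
        """Total SLIP-conformer concentration, bound + unbound (µM)."""
        return self.c_slip_unbound + self.c_slip_bound

    @property
    def percent_wt(self) -> float:
        return 100.0 * self.c_wt_total / self.p_total if self.p_total > 0 else float("nan")

    def protein_residual(self) -> float:
        return abs(self.c_wt_total + self.c_slip_total - self.p_total)

    def ligand_residual(self) -> float:
        return abs(self.c_ligand_free + self.c_wt_bound + self.c_slip_bound - self.l_total)


def _bound_ligand(model: FourStateModel, p_total: float, l_free: float) -> tuple[float, float, float, float]:
    """Protein-state concentrations at a given free-ligand concentration.

    With ``x = [WT_u]``, every other protein state is proportional to ``x``:
    ``[SLIP_u] = x/keq_apo``, ``[WT_b] = x*L/kd_wt``,
    ``[SLIP_b] = x*L/(keq_apo*kd_slip)``.  The protein mass balance then
    fixes ``x`` in closed form.
    """
    k = model.keq_apo
    a_wt = l_free / model.kd_wt if model.wt_binds else 0.0
    a_slip = l_free / model.kd_slip if model.slip_binds else 0.0
    denom = 1.0 + 1.0 / k + a_wt + a_slip / k
    x = p_total / denom
    return x, x * a_wt, x / k, (x / k) * a_slip


def solve_four_state(
    model: FourStateModel,
    p_total: float,
    l_total: float,
    rel_tol: float = 1e-10,
) -> ConformerState:
    """Solve the coupled conformational and binding equilibria by mass balance.

    The problem reduces to a single root-find on the free-ligand
    concentration ``L`` in the bracket ``[0, l_total]``: the ligand balance
    ``g(L) = L + bound(L) - l_total`` is continuous and strictly increasing
    with ``g(0) <= 0 <= g(l_total)``, so Brent's method converges
    unconditionally.  Protein states are back-substituted in closed form.

    Parameters
    ----------
    model
        Four-state model parameters.
    p_total, l_total
        Total protein and ligand concentrations, µM.
    rel_tol
        Acceptable mass-balance residual relative to the totals.

    Returns
    -------
    ConformerState
        The unique physical solution.

    Raises
    ------
    ValueError
        On negative totals.
    SolverError
        If the residuals exceed ``rel_tol`` after root refinement.
    """
    if p_total < 0 or l_total < 0:
        raise ValueError(
            f"totals must be non-negative (p_total={p_total}, l_total={l_total})"
        )
    if p_total == 0:
        return ConformerState(0.0, 0.0, 0.0, 0.0, l_total, p_total, l_total)
    if l_total == 0 or not (model.wt_binds or model.slip_binds):
        wt_u, _, slip_u, _ = _bound_ligand(model, p_total, 0.0)
        return ConformerState(wt_u, 0.0, slip_u, 0.0, l_total, p_total, l_total)

    def g(l_free: float) -> float:
        _, wt_b, _, slip_b = _bound_ligand(model, p_total, l_free)
        return l_free + wt_b + slip_b - l_total

    l_free = brentq(g, 0.0, l_total, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    wt_u, wt_b, slip_u, slip_b = _bound_ligand(model, p_total, l_free)
    state = ConformerState(wt_u, wt_b, slip_u, slip_b, l_free, p_total, l_total)

    if state.protein_residual() > rel_tol * max(p_total, 1.0) or (
        state.ligand_residual() > rel_tol * max(l_total, 1.0)
    ):
        raise SolverError(
            "mass-balance residuals exceed tolerance for "
            f"model={model}, p_total={p_total}, l_total={l_total}"
        )
    return state


def keq_bound(model: FourStateModel):
    """Equilibrium constant between the two ligand-bound states.

    Thermodynamic cycle closure gives
    ``keq_bound = keq_apo * kd_slip / kd_wt``.  When the SLIP conformer is
    non-binding the bound-state equilibrium constant is unbounded: the
    :data:`NON_BINDING` kd maps to an "infinite" ratio, returned as the
    sentinel with a warning rather than as a float.
    """
    if not model.slip_binds:
        warnings.warn(
            "kd_slip is non-binding: keq_bound is unbounded (WT-bound only)",
            stacklevel=2,
        )
        return NON_BINDING
    if not model.wt_binds:
        return 0.0
    return model.keq_apo * model.kd_slip / model.kd_wt


def predict_shift_curve(
    model: FourStateModel,
    p_total: float,
    ligand_grid: Sequence[float],
    rel_tol: float = 1e-10,
) -> list[tuple[float, float, float]]:
    """Forward-model the ligand-driven conformational shift.

    For each total ligand concentration in ``ligand_grid``, solves the
    four-state equilibria and reports the percentage of protein in each
    conformer (bound + unbound).  When the ligand prefers WT
    (``kd_wt < kd_slip``) the WT percentage rises monotonically with ligand.

    Returns
    -------
    list of (l_total, percent_wt, percent_slip)
    """
    out = []
    for l_total in ligand_grid:
        if l_total < 0:
            raise ValueError(f"ligand concentrations must be >= 0, got {l_total}")
        st = solve_four_state(model, p_total, float(l_total), rel_tol=rel_tol)
        pct_wt = st.percent_wt
        out.append((float(l_total), pct_wt, 100.0 - pct_wt))
    return out
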