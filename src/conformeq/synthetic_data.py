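"""Synthetic peak-volume generators for parameter-recovery testing.

Emulates the observables of a two-state slow-exchange fold-switching
protein: per-conformer peak volumes proportional to conformer populations
(times a per-peak response factor), for either a temperature series governed
by linear van't Hoff behaviour or a ligand titration governed by the
four-state conformational-selection model.  Noise is multiplicative
lognormal by default — NMR volume errors scale roughly with peak size and
volumes are strictly positive — with an additive-Gaussian mode available.

Defaults reproduce the studied system: ΔH = 6.8 kcal mol⁻¹,
ΔS = 23.9 cal mol⁻¹ K⁻¹ for the temperature dependence; keq_apo = 1,
Kd(WT) = 684 µM with a non-binding SLIP conformer, 200 µM protein, and the
amide titration grid 0–1000 µM for ligand binding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_equilibria import NON_BINDING, FourStateModel, solve_four_state
from .ligand_binding import TitrationSeries
from .population_quant import PEAK_TABLE_COLUMNS, PeakVolumeTable
from .vant_hoff import GAS_CONSTANT_KCAL

__all__ = ["SyntheticConfig", "generate_equilibrium_series", "generate_titration"]

_DEFAULT_MODEL = FourStateModel(keq_apo=1.0, kd_wt=684.0, kd_slip=NON_BINDING)
_DEFAULT_T_GRID = tuple(range(278, 304, 5))  # 278–303 K in 5 K steps
_DEFAULT_L_GRID = (0.0, 25.0, 50.0, 100.0, 200.0, 500.0, 1000.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world for the generators.

    Attributes
    ----------
    delta_h, delta_s
        Conversion enthalpy (kcal mol⁻¹) and entropy (cal mol⁻¹ K⁻¹) of
        SLIP→WT, driving the temperature series.
    plateau_above
        If set (K), the equilibrium constant is held at its value at this
        temperature for all higher temperatures, emulating the
        aggregation-driven plateau seen above ~303 K.
    model, p_total
        Four-state binding model and total protein (µM) for titrations.
    temperature_grid, ligand_grid
        Condition grids (K; µM, must include 0 for titrations).
    n_peaks_per_conformer, response_factors
        Number of peaks reported per conformer and their positive response
        multipliers (defaults to 1.0 each).
    noise_cv
        Coefficient of variation of the volume noise; 0 disables noise.
    noise_mode
        "lognormal" (default, mean-one multiplicative) or "additive"
        (Gaussian with sd = cv × expected volume, floored at 0).
    broadened_bound_fraction
        Fraction of the bound-WT contribution *removed* from WT volumes in
        titrations (0 = the unperturbed-peak assumption holds exactly;
        > 0 probes its violation by exchange broadening).
    binding_mode
        "mass_action" (default): titration states solved exactly from the
        coupled four-state equilibria, with ligand depletion.  "isotherm":
        bound-WT follows the single-site isotherm in *total* ligand,
        ``C_WT,B = Bmax·CL/(kd_wt + CL)`` with ``Bmax`` equal to the apo WT
        pool, and unbound WT stays in the apo ratio with SLIP (ligand
        treated as in excess).  The isotherm mode is the stated world of
        the titration fitting model, so its parameters are recoverable
        exactly; the mass-action mode deviates from that hyperbola (an
        apparent-Kd bias the analysis of real data inherits).
    seed
        RNG seed; identical config + seed gives identical tables.
    """

    delta_h: float = 6.8
    delta_s: float = 23.9
    plateau_above: float | None = None
    model: FourStateModel = _DEFAULT_MODEL
    p_total: float = 200.0
    temperature_grid: Sequence[float] = _DEFAULT_T_GRID
    ligand_grid: Sequence[float] = _DEFAULT_L_GRID
    n_peaks_per_conformer: int = 5
    response_factors: Sequence[float] | None = None
    noise_cv: float = 0.0
    noise_mode: str = "lognormal"
    broadened_bound_fraction: float = 0.0
    binding_mode: str = "mass_action"
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.noise_mode not in ("lognormal", "additive"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if self.binding_mode not in ("mass_action", "isotherm"):
            raise ValueError(f"unknown binding_mode {self.binding_mode!r}")
        if self.n_peaks_per_conformer < 1:
            raise ValueError("need at least one peak per conformer")
        if not (0.0 <= self.broadened_bound_fraction <= 1.0):
            raise ValueError("broadened_bound_fraction must be in [0, 1]")
        if self.response_factors is not None:
            rf = tuple(float(r) for r in self.response_factors)
            if len(rf) != self.n_peaks_per_conformer:
                raise ValueError(
                    "response_factors must have n_peaks_per_conformer entries"
                )
            if any(r <= 0 for r in rf):
                raise ValueError("response factors must be > 0")
            object.__setattr__(self, "response_factors", rf)
        else:
            object.__setattr__(
                self, "response_factors", (1.0,) * self.n_peaks_per_conformer
            )

    def keq_at(self, temperature: float) -> float:
        """Van't Hoff Keq(T), held constant above the plateau temperature."""
        t_eff = temperature
        if self.plateau_above is not None and temperature > self.plateau_above:
            t_eff = self.plateau_above
        r = GAS_CONSTANT_KCAL
        return math.exp(self.delta_s / 1000.0 / r - self.delta_h / (r * t_eff))


def _noisy(rng: np.random.Generator, expected: float, cfg: SyntheticConfig) -> float:
    if cfg.noise_cv == 0:
        return expected
    if cfg.noise_mode == "lognormal":
        sigma = math.sqrt(math.log1p(cfg.noise_cv**2))
        # mean-one lognormal so E[volume] = expected
        return expected * rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma)
    return max(0.0, expected + rng.normal(0.0, cfg.noise_cv * expected))


def _emit_rows(
    rows: list,
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    condition_id: str,
    covariate: float,
    wt_signal: float,
    slip_signal: float,
) -> None:
    for conf, signal in (("WT", wt_signal), ("SLIP", slip_signal)):
        for i, rf in enumerate(cfg.response_factors):
            rows.append(
                {
                    "condition_id": condition_id,
                    "covariate": covariate,
                    "peak_id": f"R{i + 1}_{conf}",
                    "conformer": conf,
                    "volume": _noisy(rng, signal * rf, cfg),
                    "volume_sd": np.nan,
                    "unperturbed": True,
                }
            )


def generate_equilibrium_series(config: SyntheticConfig) -> PeakVolumeTable:
    """Peak-volume table of a temperature series with van't Hoff populations.

    At each temperature, ``Keq = exp(ΔS/R − ΔH/(R·T))`` (plateau-clamped if
    configured) sets the WT fraction; per-peak volumes are the conformer
    fraction times the peak's response factor, with multiplicative noise.
    """
    if not len(config.temperature_grid):
        raise ValueError("temperature_grid is empty")
    rng = np.random.default_rng(config.seed)
    rows: list = []
    for t in config.temperature_grid:
        keq = config.keq_at(float(t))
        f_wt = keq / (1.0 + keq)
        _emit_rows(rows, rng, config, f"T{t:g}K", float(t), f_wt, 1.0 - f_wt)
    return PeakVolumeTable(pd.DataFrame(rows, columns=list(PEAK_TABLE_COLUMNS)))


def _titration_state(config: SyntheticConfig, l_total: float):
    """Ground-truth ConformerState at one titration point (see binding_mode)."""
    from .core_equilibria import ConformerState

    if config.binding_mode == "mass_action":
        return solve_four_state(config.model, config.p_total, l_total)
    # isotherm mode: bound-WT is exactly Bmax*CL/(kd_wt+CL) with Bmax = apo
    # WT pool; unbound WT keeps the apo ratio with SLIP; ligand in excess
    keq = config.model.keq_apo
    bmax = config.p_total * keq / (1.0 + keq)
    bound = bmax * l_total / (config.model.kd_wt + l_total)
    slip = (config.p_total - bound) / (1.0 + keq)
    return ConformerState(
        c_wt_unbound=keq * slip,
        c_wt_bound=bound,
        c_slip_unbound=slip,
        c_slip_bound=0.0,
        c_ligand_free=max(l_total - bound, 0.0),
        p_total=config.p_total,
        l_total=l_total,
    )


def generate_titration(config: SyntheticConfig) -> TitrationSeries:
    """Synthetic ligand titration from the four-state model.

    Each point's :class:`~conformeq.core_equilibria.ConformerState` is
    solved exactly; unperturbed-peak volumes report conformer *totals*
    (bound + unbound), matching the slow-exchange premise of the inversion,
    so at zero noise the analysis pipeline recovers the generator's bound-WT
    concentrations exactly.  Set ``broadened_bound_fraction > 0`` to
    attenuate the bound-state contribution to WT volumes and probe that
    assumption's failure mode.
    """
    grid = [float(l) for l in config.ligand_grid]
    if not grid or grid[0] != 0.0:
        raise ValueError(
            f"ligand_grid must start with the zero-ligand reference, got {grid}"
        )
    rng = np.random.default_rng(config.seed)
    rows: list = []
    truth = []
    for j, l_total in enumerate(grid):
        st = _titration_state(config, l_total)
        wt_signal = st.c_wt_unbound + st.c_wt_bound * (1.0 - config.broadened_bound_fraction)
        _emit_rows(
            rows, rng, config, f"L{j:02d}", l_total, wt_signal, st.c_slip_total
        )
        truth.append(st)
    table = PeakVolumeTable(pd.DataFrame(rows, columns=list(PEAK_TABLE_COLUMNS)))
    apo = truth[0]
    series = TitrationSeries(
        table=table,
        c_wt_0=apo.c_wt_total,
        c_slip_0=apo.c_slip_total,
        keq_apo=config.model.keq_apo,
    )
    series.truth = truth  # ConformerState per point, for recovery tests
    return series
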