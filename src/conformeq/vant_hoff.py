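"""Van't Hoff analysis of the SLIP→WT conformational equilibrium.

Over a temperature range in which the enthalpy and entropy of conversion are
constant, ``ln Keq = -ΔH/(R·T) + ΔS/R`` is linear in ``1/T``.  An ordinary
least-squares fit of ``ln Keq`` on ``1/T`` therefore yields ΔH from the
slope and ΔS from the intercept.  The equilibrium direction is fixed
throughout as SLIP→WT, i.e. ``Keq = [WT]/[SLIP]``: a positive ΔG means SLIP
is favoured at that temperature.

Units: ΔH and ΔG in kcal mol⁻¹, ΔS in cal mol⁻¹ K⁻¹ (the conventional mixed
units; the kcal/cal bridge is explicit wherever the two meet).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .population_quant import EquilibriumMeasurement

__all__ = ["GAS_CONSTANT_KCAL", "ThermoFit", "vant_hoff_fit", "select_linear_region", "delta_g"]

#: Gas constant in kcal mol⁻¹ K⁻¹.
GAS_CONSTANT_KCAL = 1.98720425e-3


@dataclass(frozen=True)
class ThermoFit:
    """Result of a linear van't Hoff fit.

    ``delta_h`` in kcal mol⁻¹, ``delta_s`` in cal mol⁻¹ K⁻¹, standard
    errors likewise; ``region`` lists the temperatures (K) that entered the
    fit.
    """

    delta_h: float
    delta_s: float
    se_delta_h: float
    se_delta_s: float
    r_squared: float
    region: tuple[float, ...]

    def delta_g(self, temperature: float = 298.0) -> float:
        """ΔG at ``temperature`` (K), kcal mol⁻¹; negative favours WT."""
        return delta_g_from_params(self.delta_h, self.delta_s, temperature)


def delta_g_from_params(delta_h: float, delta_s: float, temperature: float) -> float:
    """ΔG = ΔH − T·ΔS with ΔH in kcal mol⁻¹ and ΔS in cal mol⁻¹ K⁻¹."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return delta_h - temperature * delta_s / 1000.0


def delta_g(fit_or_dh, delta_s: float | None = None, temperature: float = 298.0) -> float:
    """Gibbs free energy of the SLIP→WT conversion, kcal mol⁻¹.

    Accepts either a :class:`ThermoFit` (``delta_g(fit, temperature=...)``)
    or explicit ``(delta_h, delta_s, temperature)`` values.  Uses T = 298 K
    by default (pass ``temperature=298.15`` for the thermochemical standard).
    """
    if isinstance(fit_or_dh, ThermoFit):
        return fit_or_dh.delta_g(temperature)
    if delta_s is None:
        raise TypeError("delta_s required when passing delta_h as a number")
    return delta_g_from_params(float(fit_or_dh), delta_s, temperature)


def _extract(measurements: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """(temperatures, keqs) arrays from EquilibriumMeasurements or (T, Keq) pairs."""
    temps, keqs = [], []
    for m in measurements:
        if isinstance(m, EquilibriumMeasurement):
            temps.append(m.covariate)
            keqs.append(m.keq)
        else:
            t, k = m
            temps.append(float(t))
            keqs.append(float(k))
    return np.asarray(temps, dtype=float), np.asarray(keqs, dtype=float)


def vant_hoff_fit(
    measurements: Sequence,
    region: Sequence[float] | None = None,
) -> ThermoFit:
    """Fit ΔH and ΔS from temperature-dependent equilibrium constants.

    Parameters
    ----------
    measurements
        :class:`EquilibriumMeasurement` objects (covariate = temperature, K)
        or plain ``(temperature, keq)`` pairs.
    region
        Optional subset of temperatures to fit (e.g. from
        :func:`select_linear_region`); default uses all points.

    Returns
    -------
    ThermoFit
        Slope maps to ``ΔH = -slope·R`` (kcal mol⁻¹); intercept to
        ``ΔS = intercept·R·1000`` (cal mol⁻¹ K⁻¹).  Standard errors come
        from the OLS fit; with exactly 3 points they are poorly determined
        and with collinear data they are 0.
    """
    temps, keqs = _extract(measurements)
    if region is not None:
        region_set = {float(t) for t in region}
        mask = np.array([t in region_set for t in temps])
        temps, keqs = temps[mask], keqs[mask]
    if len(np.unique(temps)) < 3:
        raise ValueError(
            f"van't Hoff fit needs >= 3 distinct temperatures, got {sorted(set(temps))}"
        )
    bad = temps[~(keqs > 0) | ~np.isfinite(keqs)]
    if bad.size:
        raise ValueError(
            f"non-positive or non-finite Keq at temperatures {bad.tolist()} K"
        )

    x = 1.0 / temps
    y = np.log(keqs)
    res = stats.linregress(x, y)
    dh = -res.slope * GAS_CONSTANT_KCAL
    ds = res.intercept * GAS_CONSTANT_KCAL * 1000.0
    # degenerate (perfectly collinear) fits report nan stderr; normalise to 0
    se_h = 0.0 if not np.isfinite(res.stderr) else res.stderr * GAS_CONSTANT_KCAL
    se_s = 0.0 if not np.isfinite(res.intercept_stderr) else res.intercept_stderr * GAS_CONSTANT_KCAL * 1000.0
    r2 = res.rvalue**2
    if not np.isfinite(r2):  # zero-variance y (constant Keq)
        r2 = 1.0
    return ThermoFit(
        delta_h=dh,
        delta_s=ds,
        se_delta_h=se_h,
        se_delta_s=se_s,
        r_squared=float(r2),
        region=tuple(sorted(np.unique(temps))),
    )


def select_linear_region(
    measurements: Sequence,
    min_points: int = 3,
    max_temperature: float | str | None = 303.0,
) -> tuple[float, ...]:
    """Choose the temperatures over which the van't Hoff plot is linear.

    Two modes:

    * explicit cutoff (default 303 K, where aggregation flattens the
      equilibrium in this system): returns all temperatures at or below
      ``max_temperature``;
    * ``max_temperature="auto"``: scans contiguous low-temperature windows
      of at least ``min_points`` points and returns the one maximising the
      r² of the van't Hoff line, preferring the widest window on ties — so
      a high-temperature plateau is excluded while perfectly linear data
      keep their full range.
    """
    if min_points < 3:
        raise ValueError(f"min_points must be >= 3, got {min_points}")
    temps, keqs = _extract(measurements)
    order = np.argsort(temps)
    temps, keqs = temps[order], keqs[order]

    if max_temperature != "auto":
        if max_temperature is None:
            max_temperature = math.inf
        sel = temps[temps <= float(max_temperature)]
        if len(np.unique(sel)) < min_points:
            raise ValueError(
                f"fewer than {min_points} temperatures at or below {max_temperature} K"
            )
        return tuple(np.unique(sel))

    x, y = 1.0 / temps, np.log(keqs)
    best: tuple[float, int] | None = None  # (r2, end index)
    for end in range(min_points, len(temps) + 1):
        if len(np.unique(temps[:end])) < min_points:
            continue
        r = stats.linregress(x[:end], y[:end]).rvalue ** 2
        if not np.isfinite(r):
            r = 1.0
        # prefer wider windows on (near-)ties
        if best is None or r > best[0] + 1e-12:
            best = (r, end)
        elif abs(r - best[0]) <= 1e-12 and end > best[1]:
            best = (best[0], end)
    if best is None:
        raise ValueError("no contiguous window satisfies min_points")
    return tuple(np.unique(temps[: best[1]]))
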