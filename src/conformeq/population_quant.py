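"""Conformer populations from slow-exchange NMR peak volumes.

In slow exchange each conformer gives its own resolvable peaks whose volumes
are proportional to its population (times a per-peak response factor).  This
module turns a conformer-labelled peak-volume table into percent
populations, equilibrium constants and — via reference scaling against a
zero-ligand spectrum — absolute conformer concentrations.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PEAK_TABLE_COLUMNS",
    "PeakVolumeTable",
    "EquilibriumMeasurement",
    "DegenerateInputError",
    "percent_populations",
    "keq_from_percent",
    "percent_from_keq",
    "scale_concentrations",
]

logger = logging.getLogger(__name__)

#: Required column order of the delimited peak-table dialect.
PEAK_TABLE_COLUMNS = (
    "condition_id",
    "covariate",
    "peak_id",
    "conformer",
    "volume",
    "volume_sd",
    "unperturbed",
)

_CONFORMERS = ("WT", "SLIP")

# strips a trailing/leading conformer decoration from a peak id so that
# "L391_WT" and "L391_SLIP" pair up under the residue tag "L391"
_TAG_RE = re.compile(r"[._-]?(wt|slip)[._-]?", re.IGNORECASE)


class DegenerateInputError(ValueError):
    """Raised when a condition carries no usable population signal."""


@dataclass(frozen=True)
class EquilibriumMeasurement:
    """Conformer populations at one experimental condition.

    ``keq`` follows the SLIP→WT convention, ``[WT]/[SLIP]``; percentages sum
    to 100.  ``sd_percent`` is the spread of percent_wt across peak pairs
    (or the jackknife estimate when peaks are unpaired).
    """

    condition_id: str
    covariate: float
    percent_wt: float
    percent_slip: float
    keq: float
    sd_percent: float
    n_peaks: int = 0

    def __post_init__(self):
        if not math.isclose(self.percent_wt + self.percent_slip, 100.0, rel_tol=1e-9):
            raise ValueError("percent_wt + percent_slip must equal 100")


class PeakVolumeTable:
    """Conformer-labelled peak volumes across experimental conditions.

    Thin validated wrapper around a :class:`pandas.DataFrame` with the
    columns of :data:`PEAK_TABLE_COLUMNS`.  ``covariate`` is the condition's
    temperature (K) or total ligand concentration (µM) depending on the
    experiment; ``unperturbed`` flags peaks with no chemical-shift change on
    ligand addition, the only peaks admitted to reference scaling.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(
                f"peak table missing columns {missing}; expected {list(PEAK_TABLE_COLUMNS)}"
            )
        df = df.loc[:, list(PEAK_TABLE_COLUMNS)].copy()
        df["condition_id"] = df["condition_id"].astype(str)
        df["peak_id"] = df["peak_id"].astype(str)
        df["conformer"] = df["conformer"].astype(str).str.upper()
        df["covariate"] = pd.to_numeric(df["covariate"])
        df["volume"] = pd.to_numeric(df["volume"])
        df["volume_sd"] = pd.to_numeric(df["volume_sd"], errors="coerce")
        if df["unperturbed"].dtype != bool:
            df["unperturbed"] = (
                df["unperturbed"]
                .astype(str)
                .str.strip()
                .str.lower()
                .map({"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False, "": False, "nan": False})
                .fillna(False)
                .astype(bool)
            )
        bad = sorted(set(df["conformer"]) - set(_CONFORMERS))
        if bad:
            raise ValueError(f"unknown conformer labels {bad}; expected {_CONFORMERS}")
        if (df["volume"] < 0).any():
            rows = df.index[df["volume"] < 0].tolist()
            raise ValueError(f"negative volumes at rows {rows}")
        dup = df.duplicated(subset=["condition_id", "peak_id", "conformer"])
        if dup.any():
            raise ValueError(
                "duplicate (condition_id, peak_id, conformer) rows: "
                f"{df.loc[dup, ['condition_id', 'peak_id']].to_dict('records')}"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakVolumeTable) and self.df.reset_index(drop=True).equals(
            other.df.reset_index(drop=True)
        )

    @property
    def condition_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["condition_id"]))

    def condition(self, condition_id: str) -> pd.DataFrame:
        sub = self.df[self.df["condition_id"] == str(condition_id)]
        if sub.empty:
            raise KeyError(f"no rows for condition {condition_id!r}")
        return sub

    def covariate_of(self, condition_id: str) -> float:
        return float(self.condition(condition_id)["covariate"].iloc[0])


def _residue_tag(peak_id: str) -> str:
    return _TAG_RE.sub("", peak_id)


def percent_populations(table: PeakVolumeTable, condition_id: str) -> EquilibriumMeasurement:
    """Percent WT / percent SLIP at one condition from relative peak volumes.

    Peaks whose ids share a residue tag across the two conformers (e.g.
    ``L391_WT`` / ``L391_SLIP``) are paired, each pair yielding an
    independent percent estimate; the reported value is the mean over pairs
    and ``sd_percent`` their standard deviation.  Without any pairing,
    volumes are summed per conformer and the spread is estimated by
    jackknife over peaks.

    Raises
    ------
    DegenerateInputError
        If all volumes are zero.
    ValueError
        If either conformer has no peaks at the condition.
    """
    sub = table.condition(condition_id)
    wt = sub[sub["conformer"] == "WT"]
    slip = sub[sub["conformer"] == "SLIP"]
    for name, part in (("WT", wt), ("SLIP", slip)):
        if part.empty:
            raise ValueError(
                f"condition {condition_id!r} has no {name}-labelled peaks"
            )
    if sub["volume"].sum() == 0:
        raise DegenerateInputError(
            f"all peak volumes are zero at condition {condition_id!r}"
        )

    wt_tags = {_residue_tag(p): v for p, v in zip(wt["peak_id"], wt["volume"])}
    slip_tags = {_residue_tag(p): v for p, v in zip(slip["peak_id"], slip["volume"])}
    shared = sorted(set(wt_tags) & set(slip_tags))

    if shared:
        per_pair = []
        for tag in shared:
            tot = wt_tags[tag] + slip_tags[tag]
            if tot > 0:
                per_pair.append(100.0 * wt_tags[tag] / tot)
        pct = float(np.mean(per_pair))
        sd = float(np.std(per_pair, ddof=1)) if len(per_pair) > 1 else 0.0
        n = len(per_pair)
    else:
        vw, vs = wt["volume"].sum(), slip["volume"].sum()
        pct = 100.0 * vw / (vw + vs)
        # jackknife over peaks: leave-one-out percent estimates
        vols = list(zip(sub["conformer"], sub["volume"]))
        loo = []
        for i in range(len(vols)):
            w = sum(v for c, v in (vols[:i] + vols[i + 1:]) if c == "WT")
            s = sum(v for c, v in (vols[:i] + vols[i + 1:]) if c == "SLIP")
            if w + s > 0 and s >= 0:
                loo.append(100.0 * w / (w + s))
        m = len(loo)
        if m > 1:
            sd = float(math.sqrt((m - 1) / m * np.sum((np.array(loo) - np.mean(loo)) ** 2)))
        else:
            sd = 0.0
        n = len(vols)

    keq = pct / (100.0 - pct) if pct < 100.0 else math.inf
    return EquilibriumMeasurement(
        condition_id=str(condition_id),
        covariate=table.covariate_of(condition_id),
        percent_wt=pct,
        percent_slip=100.0 - pct,
        keq=keq,
        sd_percent=sd,
        n_peaks=n,
    )


def keq_from_percent(percent_wt: float) -> float:
    """Equilibrium constant ``[WT]/[SLIP]`` from a WT percentage.

    Defined only on the open interval (0, 100): fully locked conformations
    (reported as "<1" or ">99" in population tables) have a Keq of 0 or
    infinity and must be handled by the caller as censored values.
    """
    if not (0.0 < percent_wt < 100.0):
        raise ValueError(
            f"percent_wt must lie strictly between 0 and 100, got {percent_wt} "
            "(locked conformations have no finite Keq)"
        )
    return percent_wt / (100.0 - percent_wt)


def percent_from_keq(keq: float) -> float:
    """Inverse of :func:`keq_from_percent`: WT percentage from ``[WT]/[SLIP]``."""
    if not (keq > 0):
        raise ValueError(f"keq must be > 0, got {keq}")
    return 100.0 * keq / (1.0 + keq)


def scale_concentrations(
    condition: pd.DataFrame,
    reference: pd.DataFrame,
    c_wt_0: float,
    c_slip_0: float,
) -> tuple[float, float]:
    """Absolute conformer concentrations by volume scaling against a reference.

    Slow-exchange volumes of peaks unaffected by ligand binding report each
    conformer's *total* concentration (bound + unbound).  Scaling the
    per-conformer volumes against the zero-ligand reference therefore gives

        C_WT,T = C_WT,0 * (V_WT / V_WT,0)
        C_SLIP = C_SLIP,0 * (V_SLIP / V_SLIP,0)

    Only peaks flagged ``unperturbed`` enter; when several qualify, the
    scale factor is the mean of their per-peak volume ratios (ratios are
    formed per peak so that response factors cancel exactly).

    Parameters
    ----------
    condition, reference
        Row slices of a peak table (e.g. from ``PeakVolumeTable.condition``)
        for the measurement and the zero-ligand reference.
    c_wt_0, c_slip_0
        Known conformer concentrations at the reference condition, µM.

    Returns
    -------
    (c_wt_total, c_slip_total) in µM.
    """
    out = []
    for conf, c0 in (("WT", c_wt_0), ("SLIP", c_slip_0)):
        cond = condition[(condition["conformer"] == conf) & condition["unperturbed"]]
        ref = reference[(reference["conformer"] == conf) & reference["unperturbed"]]
        if cond.empty or ref.empty:
            raise ValueError(f"no unperturbed {conf} peaks available for scaling")
        ref_vols = dict(zip(ref["peak_id"], ref["volume"]))
        ratios = []
        for pid, v in zip(cond["peak_id"], cond["volume"]):
            if pid in ref_vols:
                v0 = ref_vols[pid]
                if v0 <= 0:
                    raise ValueError(
                        f"reference volume for peak {pid!r} ({conf}) is zero"
                    )
                ratios.append(v / v0)
        if not ratios:
            raise ValueError(
                f"no {conf} peak shared between condition and reference"
            )
        out.append(c0 * float(np.mean(ratios)))
    return out[0], out[1]
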