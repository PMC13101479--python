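"""Blank correction and normalization of plate-reader OD600/fluorescence kinetics.

The relative fluorescence of well *i* at time *t* is

    F'_i(t) = F_i(t)/F_i(0) - Fbar_blank(t)/Fbar_blank(0)
    OD'_i(t) = OD_i(t) - ODbar_blank(t)
    r_i(t) = F'_i(t) / OD'_i(t)

where the blank means are arithmetic averages over medium-only wells at each
time step.  For single-time-point (endpoint) assays the fluorescence
numerator is instead F_i(t)/Fbar_blank(t) - 1.  Time points where the
blank-subtracted OD falls at or below a small guard epsilon are masked — an
early-time 0/0 is expected in real plates and must never become a silent
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlateSeries",
    "RelativeFluorescenceSeries",
    "blank_average",
    "relative_fluorescence",
    "endpoint_relative_fluorescence",
    "growth_rate",
]

OD_EPSILON = 1e-3  # OD units; guard for the OD' denominator
ROLES = ("sample", "blank")


@dataclass
class PlateSeries:
    """OD600 and single-channel fluorescence readings on a shared time grid.

    ``od`` and ``fluor`` are DataFrames indexed by time (hours) with one
    column per well; ``roles`` maps each well to "sample" or "blank".
    """

    od: pd.DataFrame
    fluor: pd.DataFrame
    roles: dict[str, str]
    treatment: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.od.columns) != list(self.fluor.columns):
            raise ValueError("od and fluor must cover the same wells")
        if not np.array_equal(self.od.index.to_numpy(), self.fluor.index.to_numpy()):
            raise ValueError("od and fluor must share the time grid")
        unknown = set(self.roles.values()) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown well roles: {unknown}")
        missing = set(self.od.columns) - set(self.roles)
        if missing:
            raise ValueError(f"wells without a role: {missing}")
        if not self.blank_wells:
            raise ValueError("at least one blank well is required")
        for df in (self.od, self.fluor):
            if not np.all(np.isfinite(df.to_numpy())):
                raise ValueError("readings must be finite")

    @classmethod
    def from_arrays(cls, times, od: dict, fluor: dict, roles: dict,
                    treatment: dict | None = None) -> "PlateSeries":
        idx = pd.Index(np.asarray(times, dtype=float), name="time_h")
        return cls(od=pd.DataFrame(od, index=idx),
                   fluor=pd.DataFrame(fluor, index=idx),
                   roles=dict(roles), treatment=treatment or {})

    @property
    def times(self) -> np.ndarray:
        return self.od.index.to_numpy()

    @property
    def wells(self) -> list[str]:
        return list(self.od.columns)

    @property
    def blank_wells(self) -> list[str]:
        return [w for w, r in self.roles.items() if r == "blank" and w in self.od.columns]

    @property
    def sample_wells(self) -> list[str]:
        return [w for w, r in self.roles.items() if r == "sample" and w in self.od.columns]

    # -- long-format dialect: well, role, time_h, channel, value ------------
    def to_long_csv(self, path: str | Path) -> None:
        rows = []
        for channel, df in (("OD600", self.od), ("fluorescence", self.fluor)):
            long = df.reset_index().melt(id_vars="time_h", var_name="well",
                                         value_name="value")
            long["channel"] = channel
            rows.append(long)
        out = pd.concat(rows, ignore_index=True)
        out["role"] = out["well"].map(self.roles)
        out[["well", "role", "time_h", "channel", "value"]].to_csv(path, index=False)

    @classmethod
    def from_long_csv(cls, path: str | Path) -> "PlateSeries":
        df = pd.read_csv(path)
        required = {"well", "role", "time_h", "channel", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"long plate export needs columns {sorted(required)}")
        roles = df.drop_duplicates("well").set_index("well")["role"].to_dict()
        od = df[df.channel == "OD600"].pivot(index="time_h", columns="well",
                                             values="value")
        fl = df[df.channel == "fluorescence"].pivot(index="time_h", columns="well",
                                                    values="value")
        fl = fl[od.columns]
        return cls(od=od, fluor=fl, roles=roles)

    # -- wide-format dialect: time_h column + "<well>:<channel>" columns ----
    def to_wide_csv(self, path: str | Path) -> None:
        wide = pd.DataFrame(index=self.od.index)
        for w in self.wells:
            wide[f"{w}:OD600"] = self.od[w]
            wide[f"{w}:fluorescence"] = self.fluor[w]
        wide.reset_index().to_csv(path, index=False)

    @classmethod
    def from_wide_csv(cls, path: str | Path, roles: dict[str, str]) -> "PlateSeries":
        df = pd.read_csv(path).set_index("time_h")
        od_cols = {c.split(":")[0]: df[c] for c in df.columns if c.endswith(":OD600")}
        fl_cols = {c.split(":")[0]: df[c] for c in df.columns
                   if c.endswith(":fluorescence")}
        return cls(od=pd.DataFrame(od_cols), fluor=pd.DataFrame(fl_cols)[list(od_cols)],
                   roles=roles)


@dataclass
class RelativeFluorescenceSeries:
    """r_i(t) for one well, with masked (undefined) time points flagged."""

    well: str
    times: np.ndarray
    values: np.ndarray          # NaN where masked
    masked: np.ndarray          # True where OD' <= epsilon

    def at(self, t: float) -> float:
        i = int(np.flatnonzero(np.isclose(self.times, t))[0]) \
            if np.any(np.isclose(self.times, t)) else None
        if i is None:
            raise KeyError(f"time {t} not on the plate grid")
        if self.masked[i]:
            raise ValueError(
                f"r_{self.well}({t}) is undefined: blank-subtracted OD is at or "
                f"below the {OD_EPSILON} guard (no growth above blank)")
        return float(self.values[i])


def blank_average(series: PlateSeries) -> tuple[pd.Series, pd.Series]:
    """Arithmetic mean over blank wells at each time point, both channels."""
    blanks = series.blank_wells
    if not blanks:
        raise ValueError("no blank wells in the plate series")
    return series.fluor[blanks].mean(axis=1), series.od[blanks].mean(axis=1)


def relative_fluorescence(series: PlateSeries, well: str,
                          eps: float = OD_EPSILON) -> RelativeFluorescenceSeries:
    """Growth-normalized relative fluorescence r_i(t) for one well.

    Undefined time points (OD' <= eps) are masked with NaN and flagged, never
    returned as silent zeros; ``.at(t)`` raises on them.
    """
    f_blank, od_blank = blank_average(series)
    f = series.fluor[well]
    od = series.od[well]
    if f.iloc[0] <= 0 or f_blank.iloc[0] <= 0:
        raise ValueError("F_i(0) and blank-mean fluorescence at t=0 must be > 0")

    f_rel = f / f.iloc[0] - f_blank / f_blank.iloc[0]
    od_rel = od - od_blank
    masked = (od_rel <= eps).to_numpy()
    values = np.where(masked, np.nan, f_rel.to_numpy() /
                      np.where(masked, np.nan, od_rel.to_numpy()))
    return RelativeFluorescenceSeries(well=well, times=series.times,
                                      values=values, masked=masked)


def endpoint_relative_fluorescence(series: PlateSeries, well: str, t: float,
                                   eps: float = OD_EPSILON) -> float:
    """Single-time-point variant: (F_i(t)/Fbar_blank(t) - 1) / OD'_i(t)."""
    f_blank, od_blank = blank_average(series)
    if not np.any(np.isclose(series.times, t)):
        raise KeyError(f"time {t} not on the plate grid")
    i = int(np.flatnonzero(np.isclose(series.times, t))[0])
    fb = f_blank.iloc[i]
    if fb <= 0:
        raise ValueError("blank-mean fluorescence must be > 0")
    od_rel = series.od[well].iloc[i] - od_blank.iloc[i]
    if od_rel <= eps:
        raise ValueError(
            f"endpoint r for well {well} at t={t} is undefined: blank-subtracted "
            f"OD {od_rel:.4g} is at or below the {eps} guard")
    return float((series.fluor[well].iloc[i] / fb - 1.0) / od_rel)


def growth_rate(series: PlateSeries, well: str, window: int = 5,
                eps: float = OD_EPSILON) -> tuple[float, float]:
    """Maximum sliding-window slope of ln(OD') — a generic growth-rate estimate.

    Returns (rate per hour, window-start time).  A convenience estimator, not
    a formula prescribed by the assay definition.
    """
    _, od_blank = blank_average(series)
    od_rel = (series.od[well] - od_blank).to_numpy()
    t = series.times
    good = od_rel > eps
    if good.sum() < window:
        raise ValueError(
            f"need at least {window} time points with blank-subtracted OD > {eps}")
    tg, yg = t[good], np.log(od_rel[good])
    best_rate, best_t = -np.inf, tg[0]
    for s in range(tg.size - window + 1):
        slope = np.polyfit(tg[s:s + window], yg[s:s + window], 1)[0]
        if slope > best_rate:
            best_rate, best_t = slope, tg[s]
    return float(best_rate), float(best_t)
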