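"""Synthetic populations, trajectories, cytometry events and plate-reader curves.

A low-rate Cre-lox reporter population contains two genotypes: *unrecombined*
cells carrying two lox sites (dark) and *recombined* cells carrying one lox
site (fluorescent).  Under constant inducer exposure the mean fraction of
recombined cells follows the logistic curve

    f(t) = f_max / (1 + (f_max/f0 - 1) * exp(-k t))

with ``f0`` the measured fraction at time 0, ``f_max`` the plateau fraction
(a fitting parameter in inference) and ``k`` the per-hour recombination rate.
When ``f << f_max`` the leading term of the expansion in ``f/f_max`` is pure
exponential growth ``f0 * exp(k t)``.

This module provides the closed forms, an exact stochastic jump-process
generator whose mean-field limit is the logistic curve (so that parameter
recovery tests target exactly the fitted model), and generators for the two
measurement layers used downstream: single-cell cytometry events and bulk
plate-reader growth/fluorescence curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cytometry import EventTable
from .plate_reader import PlateSeries

__all__ = [
    "SimulationConfig",
    "SwitchingTrajectory",
    "CytometryModel",
    "DoseModel",
    "GrowthParams",
    "BrightnessParams",
    "eval_logistic_fraction",
    "eval_exponential_fraction",
    "simulate_stochastic_switching",
    "synthesize_cytometry_events",
    "synthesize_plate_reader",
    "sample_dose_response",
]

MECHANISMS = ("logistic_mean", "constant_hazard")


@dataclass
class SimulationConfig:
    """Parameters of one stochastic switching simulation.

    Attributes
    ----------
    n_cells:
        Fixed population size N (equal genotype growth rates decouple the
        recombined fraction from population growth, so N stays constant).
    f0_true:
        Initial recombined fraction, in [0, 1).
    k_true:
        Per-hour recombination rate, >= 0.
    fmax_true:
        Plateau fraction in (0, 1]; only used by the logistic_mean mechanism.
    mechanism:
        "logistic_mean" — conversion fires at total rate
        k * R * (1 - R / (f_max * N)), whose mean-field limit is the logistic
        curve; "constant_hazard" — each unrecombined cell switches at hazard
        k, total rate k * U, mean f(t) = 1 - (1 - f0) * exp(-k t).
    t_grid:
        Strictly increasing sampling times in hours, starting at 0.
    rng_seed:
        Seed for the generator stream.
    """

    n_cells: int
    f0_true: float
    k_true: float
    fmax_true: float = 1.0
    mechanism: str = "logistic_mean"
    t_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 8.0, 9))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.n_cells < 10:
            raise ValueError("n_cells must be >= 10")
        if not (0.0 <= self.f0_true < 1.0):
            raise ValueError("f0_true must lie in [0, 1)")
        if self.k_true < 0:
            raise ValueError("k_true must be >= 0")
        if not (0.0 < self.fmax_true <= 1.0):
            raise ValueError("fmax_true must lie in (0, 1]")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if self.mechanism == "logistic_mean" and self.f0_true >= self.fmax_true:
            raise ValueError("f0_true must be < fmax_true for logistic_mean")
        if self.t_grid.ndim != 1 or self.t_grid.size < 1 or self.t_grid[0] != 0.0:
            raise ValueError("t_grid must be 1-D and start at 0")
        if np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing")


@dataclass
class SwitchingTrajectory:
    """Time series of recombined-cell fractions for one replicate.

    ``counts`` holds per-time (recombined, total) integer pairs when the
    fractions derive from counted events (simulation or gated cytometry);
    fraction-only trajectories leave it None.
    """

    times: np.ndarray
    fractions: np.ndarray
    counts: tuple[np.ndarray, np.ndarray] | None = None
    replicate_id: str = ""
    treatment: float = 0.0  # inducer concentration, molar

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.times.shape != self.fractions.shape:
            raise ValueError("times and fractions must have the same shape")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if self.counts is not None:
            x = np.asarray(self.counts[0], dtype=np.int64)
            n = np.asarray(self.counts[1], dtype=np.int64)
            if x.shape != self.times.shape or n.shape != self.times.shape:
                raise ValueError("counts must align with times")
            if np.any(x < 0) or np.any(x > n):
                raise ValueError("counts must satisfy 0 <= x <= n")
            if not np.allclose(self.fractions, x / n):
                raise ValueError("fractions must equal recombined/total")
            self.counts = (x, n)

    @property
    def n_times(self) -> int:
        return self.times.size


@dataclass
class CytometryModel:
    """Per-genotype single-cell fluorescence model (log-normal channels).

    FL1-A is log-normal per genotype with the recombined ("bright") log-mean
    strictly above the unrecombined ("dim") one; FSC-A/SSC-A are shared
    between genotypes.  ``immature_fraction`` is the proportion of recombined
    cells whose fluorophore has not yet matured and which therefore read out
    in the dim distribution — the maturation effect seen when cells recombine
    shortly before measurement.
    """

    fl1_log_mean_dim: float = np.log(300.0)
    fl1_log_sd_dim: float = 0.5
    fl1_log_mean_bright: float = np.log(30000.0)
    fl1_log_sd_bright: float = 0.6
    fsc_log_mean: float = np.log(50000.0)
    fsc_log_sd: float = 0.4
    ssc_log_mean: float = np.log(20000.0)
    ssc_log_sd: float = 0.5
    immature_fraction: float = 0.0

    def __post_init__(self) -> None:
        for sd in (self.fl1_log_sd_dim, self.fl1_log_sd_bright,
                   self.fsc_log_sd, self.ssc_log_sd):
            if sd <= 0:
                raise ValueError("log-sds must be > 0")
        if not (0.0 <= self.immature_fraction <= 1.0):
            raise ValueError("immature_fraction must lie in [0, 1]")
        if self.fl1_log_mean_bright <= self.fl1_log_mean_dim:
            raise ValueError("bright FL1-A log-mean must exceed dim log-mean")


@dataclass
class DoseModel:
    """Hill-shaped ground-truth map from inducer concentration to rate.

    k(c) = k_leak + k_max * c^n / (c^n + K_half^n).  This is generator-side
    plumbing only: inference estimates k separately per concentration and
    never assumes this (or any) functional form.
    """

    k_max: float = 2.0          # per-hour
    K_half: float = 3e-6        # molar
    hill_n: float = 2.0
    k_leak: float = 0.0         # per-hour

    def __post_init__(self) -> None:
        if self.k_max < 0 or self.k_leak < 0:
            raise ValueError("rates must be >= 0")
        if self.K_half <= 0 or self.hill_n <= 0:
            raise ValueError("K_half and hill_n must be > 0")

    def rate(self, c: float | np.ndarray) -> float | np.ndarray:
        c = np.asarray(c, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            cn = np.power(c, self.hill_n)
            out = self.k_leak + self.k_max * cn / (cn + self.K_half ** self.hill_n)
        out = np.where(c == 0, self.k_leak, out)
        return float(out) if out.ndim == 0 else out


@dataclass
class GrowthParams:
    """Logistic bulk-growth parameters for plate-reader synthesis."""

    od0: float = 0.01           # net OD600 above blank at t=0
    rate: float = 0.9           # per-hour
    capacity: float = 0.8       # net OD600 plateau
    blank_od: float = 0.09      # OD600 of medium-only wells
    od_noise_sd: float = 0.002


@dataclass
class BrightnessParams:
    """Fluorescence model for plate-reader synthesis."""

    background: float = 100.0       # blank-well fluorescence, a.u.
    per_od_brightness: float = 5e4  # fluorescence per unit OD of recombined cells
    fluor_noise_sd: float = 2.0


def eval_logistic_fraction(t, f0: float, fmax: float, k: float):
    """Mean recombined fraction under the logistic model.

    f(t) = fmax / (1 + (fmax/f0 - 1) * exp(-k t)); non-decreasing in t and
    bounded by fmax.  Requires 0 < f0 <= fmax <= 1 (the curve divides by f0).
    """
    if f0 <= 0:
        raise ValueError("f0 must be > 0 (the logistic curve divides by f0)")
    if f0 > fmax:
        raise ValueError("f0 must be <= fmax")
    if fmax > 1:
        raise ValueError("fmax must be <= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    t = np.asarray(t, dtype=float)
    out = fmax / (1.0 + (fmax / f0 - 1.0) * np.exp(-k * t))
    return float(out) if out.ndim == 0 else out


def eval_exponential_fraction(t, f0: float, k: float, *, warn_above_one: bool = True):
    """Early-growth exponential approximation f(t) = f0 * exp(k t).

    Values above 1 are possible (the approximation knows no saturation); they
    are returned as-is but flagged with a warning, since a fraction cannot
    exceed 1.
    """
    if f0 <= 0:
        raise ValueError("f0 must be > 0")
    if k < 0:
        raise ValueError("k must be >= 0")
    t = np.asarray(t, dtype=float)
    out = f0 * np.exp(k * t)
    if warn_above_one and np.any(out > 1.0):
        warnings.warn("exponential fraction exceeds 1; outside model validity",
                      stacklevel=2)
    return float(out) if out.ndim == 0 else out


def _birth_chain_times(rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Cumulative jump times of a pure birth chain with per-state rates."""
    waits = rng.exponential(1.0 / rates)
    return np.cumsum(waits)


def simulate_stochastic_switching(config: SimulationConfig) -> SwitchingTrajectory:
    """Exact event-driven simulation of the two-genotype switching process.

    The population size N is fixed; the state is the recombined count R.
    logistic_mean: R -> R+1 at total rate k * R * (1 - R/(f_max N)) — a pure
    birth chain whose mean-field limit is the logistic curve.
    constant_hazard: R -> R+1 at total rate k * (N - R), mean
    f(t) = 1 - (1 - f0) exp(-k t).

    Because the total rate depends only on R, the full jump chain is sampled
    exactly by drawing one exponential waiting time per state (next-reaction
    stepping, vectorized); counts are then read off the sampling grid.
    """
    N = config.n_cells
    R0 = int(round(config.f0_true * N))
    k = config.k_true
    rng = np.random.default_rng(config.rng_seed)
    t_grid = config.t_grid

    if config.mechanism == "logistic_mean":
        if R0 == 0:
            raise ValueError(
                "round(f0_true * n_cells) is 0: the logistic_mean process is "
                "absorbed at R=0 and the mean curve is undefined at f0=0")
        # States R0 .. R_cap-1 can fire; rate hits 0 at R >= f_max*N.
        R_cap = int(np.ceil(config.fmax_true * N))
        states = np.arange(R0, R_cap)
        rates = k * states * (1.0 - states / (config.fmax_true * N))
        valid = rates > 0
        states, rates = states[valid], rates[valid]
    else:  # constant_hazard
        states = np.arange(R0, N)          # R values from which a jump occurs
        rates = k * (N - states)

    if k == 0 or states.size == 0:
        R_at = np.full(t_grid.shape, R0, dtype=np.int64)
    else:
        jump_times = _birth_chain_times(rates, rng)
        R_at = R0 + np.searchsorted(jump_times, t_grid, side="right")

    x = R_at.astype(np.int64)
    n = np.full_like(x, N)
    return SwitchingTrajectory(
        times=t_grid, fractions=x / n, counts=(x, n),
        replicate_id=f"sim-seed{config.rng_seed}", treatment=0.0)


def synthesize_cytometry_events(fraction: float, n_events: int,
                                model: CytometryModel | None = None,
                                seed: int | np.random.Generator = 0,
                                sample_id: str = "synthetic") -> EventTable:
    """Draw single-cell events for a population with a given recombined fraction.

    Each event is recombined with probability ``fraction``; recombined cells
    read out in the bright FL1-A distribution unless immature (probability
    ``model.immature_fraction``), in which case they read out dim.  True
    genotype labels are retained as hidden ground truth for tests.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    model = model or CytometryModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    recombined = rng.random(n_events) < fraction
    immature = recombined & (rng.random(n_events) < model.immature_fraction)
    bright = recombined & ~immature

    fl1 = np.where(
        bright,
        np.exp(rng.normal(model.fl1_log_mean_bright, model.fl1_log_sd_bright, n_events)),
        np.exp(rng.normal(model.fl1_log_mean_dim, model.fl1_log_sd_dim, n_events)),
    )
    fsc = np.exp(rng.normal(model.fsc_log_mean, model.fsc_log_sd, n_events))
    ssc = np.exp(rng.normal(model.ssc_log_mean, model.ssc_log_sd, n_events))
    return EventTable.from_arrays(fsc=fsc, ssc=ssc, fl1=fl1,
                                  sample_id=sample_id, true_labels=recombined)


def synthesize_plate_reader(trajectory: SwitchingTrajectory,
                            growth: GrowthParams | None = None,
                            brightness: BrightnessParams | None = None,
                            n_sample_wells: int = 3,
                            n_blank_wells: int = 3,
                            seed: int = 0) -> PlateSeries:
    """Bulk OD600 + fluorescence curves for a switching population.

    OD600 follows logistic growth plus the blank offset and additive noise;
    fluorescence is blank background plus per-cell brightness times the
    recombined-cell density (net OD times recombined fraction).  Blank wells
    contain background only.
    """
    if n_blank_wells < 1:
        raise ValueError("at least one blank well is required")
    growth = growth or GrowthParams()
    brightness = brightness or BrightnessParams()
    rng = np.random.default_rng(seed)
    t = trajectory.times
    frac = trajectory.fractions

    od_net = growth.capacity / (
        1.0 + (growth.capacity / growth.od0 - 1.0) * np.exp(-growth.rate * t))
    signal = brightness.per_od_brightness * od_net * frac

    wells, roles, od_cols, fl_cols = [], {}, {}, {}
    for j in range(n_sample_wells):
        w = f"S{j + 1}"
        wells.append(w)
        roles[w] = "sample"
        od_cols[w] = growth.blank_od + od_net + rng.normal(0, growth.od_noise_sd, t.size)
        fl_cols[w] = brightness.background + signal + rng.normal(
            0, brightness.fluor_noise_sd, t.size)
    for j in range(n_blank_wells):
        w = f"B{j + 1}"
        wells.append(w)
        roles[w] = "blank"
        od_cols[w] = growth.blank_od + rng.normal(0, growth.od_noise_sd, t.size)
        fl_cols[w] = brightness.background + rng.normal(
            0, brightness.fluor_noise_sd, t.size)

    return PlateSeries.from_arrays(times=t, od=od_cols, fluor=fl_cols, roles=roles,
                                   treatment={w: trajectory.treatment for w in wells})


def sample_dose_response(model: DoseModel, concentrations) -> np.ndarray:
    """Ground-truth per-hour rates k(c) for a list of molar concentrations."""
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    return np.asarray(model.rate(c), dtype=float)
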