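"""Detection, leakage, generation-accounting and stability statistics.

A whole-cell biosensor's sensitivity is assessed on a ladder of inducer
concentrations: within each biological replicate (experiment) a two-sided
Welch's t-test compares readouts between successive concentrations, and the
per-experiment p-values for the same step are combined across experiments
with Fisher's method (X = -2 sum ln p ~ chi-square with 2m df).  The lowest
concentration whose step up from the previous level is significant at alpha
is the detection limit.  Readouts are gated fluorescent fractions for a
recombinase reporter or median single-cell fluorescence for a transcription
reporter; no transformation is applied.

Serial-passage bookkeeping converts cell-density ratios and dilution factors
into generations per cycle, log2(rho_i * D / rho_{i-1}), and stability
tracking reports the relative change of the fluorescent fraction against the
post-exposure reference over ~50 generations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cytometry import FractionEstimate

__all__ = [
    "ARSENIC_MOLAR_MASS",
    "ppb_to_molar",
    "ppb_to_nanomolar",
    "welch_t_two_sided",
    "fisher_combine",
    "apply_p_floor",
    "DoseComparison",
    "LadderResult",
    "detection_ladder",
    "leakage_summary",
    "generations",
    "generation_table",
    "StabilityTrack",
    "stability_track",
]

ARSENIC_MOLAR_MASS = 74.92  # g/mol, elemental As
P_FLOOR = 1e-300


def ppb_to_molar(ppb: float, molar_mass: float = ARSENIC_MOLAR_MASS) -> float:
    """Convert a ppb (ug/L) mass concentration to molar.

    The 10 ug/L drinking-water limit for arsenic corresponds to ~133 nM.
    """
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    return ppb * 1e-6 / molar_mass


def ppb_to_nanomolar(ppb: float, molar_mass: float = ARSENIC_MOLAR_MASS) -> float:
    return ppb_to_molar(ppb, molar_mass) * 1e9


def welch_t_two_sided(a, b) -> tuple[float, float, float]:
    """Unequal-variance t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("readouts must be finite")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def apply_p_floor(p_values, floor: float = P_FLOOR) -> np.ndarray:
    """Floor p-values at machine-representable precision, with a warning."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p < floor):
        warnings.warn(f"p-values floored at {floor} before log-combination",
                      stacklevel=2)
    return np.maximum(p, floor)


def fisher_combine(p_values) -> tuple[float, int, float]:
    """Fisher's method: (chi-square statistic, df = 2m, combined p).

    A p of exactly 0 is rejected (the log diverges); floor such values
    explicitly with ``apply_p_floor`` first.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("at least one p-value is required")
    if np.any(p == 0):
        raise ValueError("p = 0 cannot be log-combined; floor it explicitly "
                         "at machine precision with apply_p_floor")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclass
class DoseComparison:
    """Welch comparison of one adjacent concentration pair in one experiment."""

    experiment: str
    c_low: float
    c_high: float
    t: float
    df: float
    p: float

    def __post_init__(self) -> None:
        if not self.c_low < self.c_high:
            raise ValueError("require c_low < c_high")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")


@dataclass
class LadderResult:
    """Per-step combined p-values and the detection limit of the ladder."""

    steps: pd.DataFrame                 # c_low, c_high, chi2, df, combined_p
    comparisons: list                   # per-experiment DoseComparisons
    lowest_detected: float | None
    alpha: float
    holm: bool = False


def detection_ladder(readouts: pd.DataFrame, alpha: float = 0.05,
                     experiments: list | None = None,
                     holm: bool = False) -> LadderResult:
    """Welch-per-experiment + Fisher-across-experiments detection ladder.

    ``readouts`` needs columns ``experiment``, ``concentration`` (molar) and
    ``value`` (one row per technical replicate).  For each adjacent pair in
    the sorted concentration ladder, a two-sided Welch test is run per
    experiment and the per-experiment p-values are Fisher-combined.  The
    detection limit is the lowest concentration whose step up from the
    previous level has combined p < alpha.  ``experiments`` restricts the
    combination to a subset (e.g. excluding a longer-duration replicate);
    ``holm`` applies a Holm adjustment across ladder steps (off by default —
    the combination is across experiments per step, not across steps).
    """
    required = {"experiment", "concentration", "value"}
    if not required.issubset(readouts.columns):
        raise ValueError(f"readouts needs columns {sorted(required)}")
    df = readouts.copy()
    if experiments is not None:
        df = df[df["experiment"].isin(experiments)]
        if df.empty:
            raise ValueError("no readouts left after experiment subsetting")

    concs = np.sort(df["concentration"].unique())
    if concs.size < 2:
        raise ValueError("a ladder needs at least 2 concentrations")
    exps = sorted(df["experiment"].unique())
    gaps = [(e, c) for e in exps for c in concs
            if df[(df.experiment == e) & (df.concentration == c)].shape[0] < 2]
    if gaps:
        raise ValueError(
            "each experiment needs >= 2 technical replicates at every "
            f"concentration; missing/short: {gaps}")

    comparisons: list[DoseComparison] = []
    rows = []
    for c_low, c_high in zip(concs[:-1], concs[1:]):
        step_ps = []
        for e in exps:
            a = df[(df.experiment == e) & (df.concentration == c_low)]["value"]
            b = df[(df.experiment == e) & (df.concentration == c_high)]["value"]
            t, dof, p = welch_t_two_sided(a, b)
            comparisons.append(DoseComparison(experiment=str(e), c_low=c_low,
                                              c_high=c_high, t=t, df=dof, p=p))
            step_ps.append(p)
        chi2, dof2, combined = fisher_combine(apply_p_floor(step_ps))
        rows.append({"c_low": c_low, "c_high": c_high, "chi2": chi2,
                     "df": dof2, "combined_p": combined})
    steps = pd.DataFrame(rows)

    pcol = "combined_p"
    if holm:
        order = np.argsort(steps["combined_p"].to_numpy())
        m = len(steps)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * steps["combined_p"].iloc[i])
            adj[i] = min(running, 1.0)
        steps["combined_p_holm"] = adj
        pcol = "combined_p_holm"

    detected = steps[steps[pcol] < alpha]
    lowest = float(detected["c_high"].min()) if not detected.empty else None
    return LadderResult(steps=steps, comparisons=comparisons,
                        lowest_detected=lowest, alpha=alpha, holm=holm)


def _p_hat(est) -> float:
    return est.p_hat if isinstance(est, FractionEstimate) else float(est)


def leakage_summary(zero_inducer, baseline) -> float:
    """Median across experiments of the zero-inducer added recombined fraction.

    Each experiment contributes (endpoint p_hat - baseline p_hat); negative
    values from sampling noise are kept as-is.
    """
    zero_inducer = list(zero_inducer)
    baseline = list(baseline)
    if len(zero_inducer) != len(baseline) or not zero_inducer:
        raise ValueError("paired per-experiment endpoint and baseline "
                         "estimates are required")
    added = [_p_hat(z) - _p_hat(b) for z, b in zip(zero_inducer, baseline)]
    return float(np.median(added))


def generations(rho_prev: float, rho_i: float, dilution_factor: float) -> float:
    """Generations in one growth cycle from density bookkeeping.

    The culture at density rho_{i-1} is diluted D-fold and regrows to rho_i,
    so the population doubles log2(rho_i * D / rho_{i-1}) times.  Regrowth to
    the same density (carrying capacity) gives exactly log2(D).
    """
    if rho_prev <= 0 or rho_i <= 0 or dilution_factor <= 0:
        raise ValueError("densities and dilution_factor must be > 0")
    return float(np.log2(rho_i * dilution_factor / rho_prev))


def generation_table(densities, dilution_factors) -> pd.DataFrame:
    """Per-cycle and cumulative generations over a serial-passage series.

    ``densities`` has one entry per cycle endpoint including the starting
    density (length n_cycles + 1); ``dilution_factors`` one per cycle (or a
    scalar applied to every cycle).
    """
    rho = np.asarray(densities, dtype=float)
    if rho.size < 2:
        raise ValueError("need a starting density plus at least one cycle")
    D = np.broadcast_to(np.asarray(dilution_factors, dtype=float), (rho.size - 1,))
    per_cycle = np.array([generations(rho[i], rho[i + 1], D[i])
                          for i in range(rho.size - 1)])
    return pd.DataFrame({
        "cycle": np.arange(1, rho.size),
        "dilution_factor": D,
        "generations": per_cycle,
        "cumulative_generations": np.cumsum(per_cycle),
    })


@dataclass
class StabilityTrack:
    """Fluorescent-fraction track across passages, relative to post-exposure."""

    labels: list
    fractions: np.ndarray
    relative_change: np.ndarray     # (f - f_ref) / f_ref; decline is negative
    reference_label: str
    table: pd.DataFrame = field(repr=False, default=None)


def stability_track(estimates: dict, reference_label: str = "post_exposure") -> StabilityTrack:
    """Relative change of the fluorescent fraction versus the reference point.

    ``estimates`` maps point labels (pre_induction, post_exposure,
    passage_1, ...) to FractionEstimates or plain fractions.  The reference
    (post-exposure) point must be present and nonzero; monotone decline is
    not assumed.  A decline of 60% appears as relative_change = -0.60.
    """
    if reference_label not in estimates:
        raise ValueError(f"reference point '{reference_label}' missing")
    labels = list(estimates)
    fracs = np.array([_p_hat(estimates[lab]) for lab in labels])
    f_ref = _p_hat(estimates[reference_label])
    if f_ref == 0:
        raise ValueError("reference fraction is 0; relative decline undefined")
    rel = (fracs - f_ref) / f_ref
    table = pd.DataFrame({"label": labels, "fraction": fracs,
                          "relative_change": rel})
    return StabilityTrack(labels=labels, fractions=fracs, relative_change=rel,
                          reference_label=reference_label, table=table)
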