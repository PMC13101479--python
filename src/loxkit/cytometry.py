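"""Event-level cytometry: control-derived gating and fraction/median estimation.

The binary readout of a recombinase reporter is the fraction of cells inside a
fluorescence gate whose lower boundary is drawn to exclude a non-fluorescent
control strain.  Gates here are derived reproducibly from a control sample: a
debris cut at a low FSC-A quantile, then an FL1-A lower boundary placed at a
high tail quantile ``q`` of the FSC-passing control events (optionally per
FSC-A bin, approximating a sloped polygon boundary).  Fractions carry the
binomial standard error sqrt(p(1-p)/n); medians carry a bootstrap standard
error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "GateSpec",
    "FractionEstimate",
    "MedianFluorescence",
    "derive_gate_from_control",
    "estimate_fluorescent_fraction",
    "estimate_median_fluorescence",
]

CHANNELS = ("FSC-A", "SSC-A", "FL1-A")
MIN_CONTROL_EVENTS = 1000
LABEL_COLUMN = "true_recombined"


@dataclass
class EventTable:
    """Per-event scatter and fluorescence measurements for one sample.

    Wraps a DataFrame with columns FSC-A, SSC-A, FL1-A (arbitrary units).
    ``true_labels`` holds hidden ground-truth genotype labels and exists only
    for synthetic data.
    """

    data: pd.DataFrame
    sample_id: str = ""
    true_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing channel columns: {missing}")
        if len(self.data) < 1:
            raise ValueError("an EventTable needs at least one event")
        vals = self.data[list(CHANNELS)].to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("channel values must be finite")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=bool)
            if self.true_labels.shape[0] != len(self.data):
                raise ValueError("true_labels must align with events")

    @classmethod
    def from_arrays(cls, fsc, ssc, fl1, sample_id: str = "",
                    true_labels=None) -> "EventTable":
        df = pd.DataFrame({"FSC-A": np.asarray(fsc, dtype=float),
                           "SSC-A": np.asarray(ssc, dtype=float),
                           "FL1-A": np.asarray(fl1, dtype=float)})
        return cls(df, sample_id=sample_id, true_labels=true_labels)

    @property
    def n_events(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        df = self.data[list(CHANNELS)].copy()
        if self.true_labels is not None:
            df[LABEL_COLUMN] = self.true_labels.astype(int)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sample_id: str | None = None) -> "EventTable":
        df = pd.read_csv(path)
        labels = None
        if LABEL_COLUMN in df.columns:
            labels = df.pop(LABEL_COLUMN).to_numpy().astype(bool)
        sid = sample_id if sample_id is not None else Path(path).stem
        return cls(df, sample_id=sid, true_labels=labels)


@dataclass
class GateSpec:
    """Threshold gate in FL1-A vs FSC-A space derived from a control sample.

    ``fl1_low`` is a scalar lower FL1-A boundary; when ``fl1_bin_edges`` is
    set, the boundary is piecewise-constant per FSC-A bin (``fl1_bin_low``
    holds one threshold per bin) to allow an FSC-dependent boundary.
    """

    fsc_low: float
    fl1_low: float | None = None
    fl1_bin_edges: np.ndarray | None = None
    fl1_bin_low: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.fsc_low):
            raise ValueError("fsc_low must be finite")
        if self.fl1_low is None and self.fl1_bin_low is None:
            raise ValueError("either fl1_low or a per-bin boundary is required")
        if self.fl1_low is not None and not np.isfinite(self.fl1_low):
            raise ValueError("fl1_low must be finite")
        q = self.provenance.get("quantile")
        if q is not None and not (0.5 < q < 1.0):
            raise ValueError("tail quantile must lie in (0.5, 1)")

    def passes_debris_cut(self, table: EventTable) -> np.ndarray:
        return table.data["FSC-A"].to_numpy() >= self.fsc_low

    def is_positive(self, table: EventTable) -> np.ndarray:
        """Boolean mask of FSC-passing events above the FL1-A boundary."""
        fsc = table.data["FSC-A"].to_numpy()
        fl1 = table.data["FL1-A"].to_numpy()
        keep = fsc >= self.fsc_low
        if self.fl1_bin_low is not None:
            idx = np.clip(np.searchsorted(self.fl1_bin_edges, fsc, side="right") - 1,
                          0, len(self.fl1_bin_low) - 1)
            thr = np.asarray(self.fl1_bin_low)[idx]
        else:
            thr = self.fl1_low
        return keep & (fl1 > thr)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "fsc_low": self.fsc_low,
            "fl1_low": self.fl1_low,
            "fl1_bin_edges": None if self.fl1_bin_edges is None
            else np.asarray(self.fl1_bin_edges).tolist(),
            "fl1_bin_low": None if self.fl1_bin_low is None
            else np.asarray(self.fl1_bin_low).tolist(),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GateSpec":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        payload = json.loads(text)
        for key in ("fl1_bin_edges", "fl1_bin_low"):
            if payload.get(key) is not None:
                payload[key] = np.asarray(payload[key], dtype=float)
        return cls(**payload)


@dataclass
class FractionEstimate:
    """Gated-positive fraction with its binomial standard error.

    When the raw count sits on the boundary (x = 0 or x = n) the point
    estimate uses the Jeffreys-style smoothing (x + 0.5) / (n + 1) so that
    downstream logistic fits, which divide by f0, remain evaluable.
    """

    x: int
    n: int
    p_hat: float
    se: float
    smoothed: bool = False
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.x <= self.n):
            raise ValueError("counts must satisfy 0 <= x <= n")


@dataclass
class MedianFluorescence:
    """Median FL1-A with bootstrap standard error."""

    median: float
    se: float
    n_boot: int
    n: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")


def derive_gate_from_control(control: EventTable, q: float = 0.999,
                             fsc_debris_quantile: float = 0.01,
                             n_fsc_bins: int | None = None) -> GateSpec:
    """Place the gate boundary so it excludes the control strain.

    ``fsc_low`` is the control's ``fsc_debris_quantile`` FSC-A quantile (debris
    cut); ``fl1_low`` is the ``q`` tail quantile of FSC-passing control FL1-A,
    so at most (1 - q) of FSC-passing control events lie above it.  With
    ``n_fsc_bins`` the FL1-A boundary is computed per FSC-A quantile bin.
    """
    if control.n_events < MIN_CONTROL_EVENTS:
        raise ValueError(
            f"control has {control.n_events} events; at least "
            f"{MIN_CONTROL_EVENTS} are required to place a tail boundary")
    if not (0.5 < q < 1.0):
        raise ValueError("q must lie in (0.5, 1)")

    fsc = control.data["FSC-A"].to_numpy()
    fl1 = control.data["FL1-A"].to_numpy()
    fsc_low = float(np.quantile(fsc, fsc_debris_quantile))
    keep = fsc >= fsc_low
    provenance = {"control_sample_id": control.sample_id, "quantile": q,
                  "fsc_debris_quantile": fsc_debris_quantile}

    if n_fsc_bins is None:
        return GateSpec(fsc_low=fsc_low,
                        fl1_low=float(np.quantile(fl1[keep], q)),
                        provenance=provenance)

    edges = np.quantile(fsc[keep], np.linspace(0, 1, n_fsc_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    thresholds = np.empty(n_fsc_bins)
    for b in range(n_fsc_bins):
        in_bin = keep & (fsc >= edges[b]) & (fsc < edges[b + 1])
        if in_bin.sum() < 50:
            raise ValueError("too few control events per FSC bin; reduce n_fsc_bins")
        thresholds[b] = np.quantile(fl1[in_bin], q)
    return GateSpec(fsc_low=fsc_low, fl1_bin_edges=edges, fl1_bin_low=thresholds,
                    provenance=provenance)


def estimate_fluorescent_fraction(sample: EventTable, gate: GateSpec) -> FractionEstimate:
    """Count FSC-passing events above the FL1-A boundary and attach binomial error."""
    keep = gate.passes_debris_cut(sample)
    n = int(keep.sum())
    if n == 0:
        raise ValueError("no events pass the debris cut")
    x = int(gate.is_positive(sample).sum())
    smoothed = x == 0 or x == n
    p_hat = (x + 0.5) / (n + 1) if smoothed else x / n
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n))
    return FractionEstimate(x=x, n=n, p_hat=p_hat, se=se, smoothed=smoothed,
                            sample_id=sample.sample_id)


def estimate_median_fluorescence(sample: EventTable, gate: GateSpec | None = None,
                                 n_boot: int = 1000,
                                 seed: int | np.random.Generator = 0) -> MedianFluorescence:
    """Median FL1-A over FSC-passing events with a bootstrap standard error.

    The continuous readout of a transcription reporter.  ``gate`` supplies the
    debris cut only; its FL1-A boundary is ignored.
    """
    fl1 = sample.data["FL1-A"].to_numpy()
    if gate is not None:
        fl1 = fl1[gate.passes_debris_cut(sample)]
    n = fl1.size
    if n < 100:
        raise ValueError("at least 100 events are required for a median estimate")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_medians = np.median(fl1[idx], axis=1)
    return MedianFluorescence(median=float(np.median(fl1)),
                              se=float(np.std(boot_medians, ddof=1)),
                              n_boot=n_boot, n=n, sample_id=sample.sample_id)
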