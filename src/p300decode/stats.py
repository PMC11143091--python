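"""Conventional ERP measures at a chosen electrode and shared statistics.

``paired_ttest`` and ``pearson`` are deliberately written out in closed form
(mean/SD arithmetic plus the exact t-distribution tail) so they can be cross-
checked against scipy as an independent reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist

from .epochs import EpochSet

#: Default component measurement windows (ms post-stimulus).
COMPONENT_WINDOWS = {"P200": (150.0, 250.0), "P300": (300.0, 500.0)}


@dataclass
class ErpWaveform:
    """Trial-averaged voltage at one electrode."""

    values: np.ndarray  # µV, one per sample
    times: np.ndarray  # ms
    n_trials: int
    condition: str = ""

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if len(self.values) != len(self.times):
            raise ValueError("values/times length mismatch")


@dataclass
class ComponentMeasure:
    component: str
    window_ms: tuple[float, float]
    kind: str  # "peak" | "mean"
    value: float  # µV
    peak_latency_ms: float


def grand_average(
    epochs: EpochSet, electrode: str, condition: str | None = None
) -> ErpWaveform:
    """Mean across trials at one electrode, optionally filtered by a query.

    *condition* is a pandas query over the metadata plus the ``label`` column
    (e.g. ``"label == 1 and scenario == 'social'"``).
    """
    meta = epochs.meta.copy()
    meta["label"] = epochs.labels
    idx = meta.query(condition).index.to_numpy() if condition else meta.index.to_numpy()
    if len(idx) == 0:
        raise ValueError(f"empty selection for condition {condition!r}")
    ch = epochs.layout.index(electrode)
    return ErpWaveform(
        values=epochs.data[idx, ch, :].mean(axis=0),
        times=epochs.times,
        n_trials=len(idx),
        condition=condition or "all",
    )


def component_amplitude(
    wave: ErpWaveform,
    component: str,
    window_ms: tuple[float, float] | None = None,
    kind: str = "peak",
) -> ComponentMeasure:
    """Peak (or mean) amplitude of a component inside its window.

    Peak latency uses the earliest maximum on ties.
    """
    window_ms = window_ms or COMPONENT_WINDOWS[component]
    lo, hi = window_ms
    mask = (wave.times >= lo) & (wave.times <= hi)
    if not mask.any():
        raise ValueError(f"window {window_ms} outside waveform time range")
    seg = wave.values[mask]
    seg_t = wave.times[mask]
    peak_i = int(np.argmax(seg))  # argmax returns the first (earliest) maximum
    value = float(seg[peak_i]) if kind == "peak" else float(seg.mean())
    return ComponentMeasure(
        component=component,
        window_ms=window_ms,
        kind=kind,
        value=value,
        peak_latency_ms=float(seg_t[peak_i]),
    )


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Paired two-sided t test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, n - 1, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = 2.0 * float(t_dist.sf(abs(t), df=n - 1))
    return t, n - 1, p


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * float(t_dist.sf(abs(t), df=n - 2))
    return r, p
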