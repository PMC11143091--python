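"""Gradient saliency maps and the spatio-temporal quantifications built on them.

The saliency map of an epoch is the gradient of the pre-softmax class score
with respect to the 8 x 201 input, which for a linear classifier reduces
exactly to its weight vector — the module's ground-truth anchor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epochs import EpochSet, epoch_times
from .layout import ChannelLayout
from .stats import pearson


@dataclass
class SaliencyMap:
    """Signed gradients M(i, j) over channels x samples for one class."""

    values: np.ndarray  # (8, 201)
    class_index: int
    times: np.ndarray  # ms
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("saliency values must be 2D (channels, samples)")
        if self.values.shape[0] != self.layout.n_channels:
            raise ValueError("saliency channel axis does not match layout")


@dataclass
class LinearOracleModel:
    """h_c(X) = w_c . X + b_c on the flattened input; the analytic oracle."""

    weights: np.ndarray  # (n_classes, channels, samples) or (channels, samples)
    biases: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim == 2:
            w = w[None]
        self.weights = w

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]

    def class_score(self, x: np.ndarray, class_index: int) -> float:
        b = np.atleast_1d(self.biases)
        bias = b[class_index] if len(b) > 1 else float(b[0])
        return float(np.tensordot(self.weights[class_index], x, axes=2) + bias)

    def input_gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        if not 0 <= class_index < self.n_classes:
            raise IndexError(f"class index {class_index} out of range")
        return self.weights[class_index].copy()


def compute_saliency(
    model, epoch: np.ndarray, class_index: int = 1, provenance: dict | None = None
) -> SaliencyMap:
    """Gradient of the class score at one epoch, reshaped to channels x samples.

    *model* needs an ``input_gradient(epoch, class_index)`` method (the CNN or
    the linear oracle).
    """
    epoch = np.asarray(epoch, dtype=float)
    grad = model.input_gradient(epoch, class_index)
    default_times = epoch_times()
    if epoch.shape[1] == len(default_times):
        times = default_times
    else:
        times = np.arange(epoch.shape[1], dtype=float)
    return SaliencyMap(
        values=np.asarray(grad).reshape(epoch.shape),
        class_index=class_index,
        times=times,
        provenance=provenance or {},
    )


def saliency_for_epochs(
    model, epochs: EpochSet, class_index: int = 1, condition: str | None = "label == 1"
) -> SaliencyMap:
    """Average normalized per-trial saliency over a selection of epochs.

    Default selection is target trials with gradients for the target class,
    following the normalize-then-superimpose protocol.
    """
    meta = epochs.meta.copy()
    meta["label"] = epochs.labels
    idx = meta.query(condition).index.to_numpy() if condition else meta.index.to_numpy()
    if len(idx) == 0:
        raise ValueError("empty epoch selection for saliency")
    grads = model.input_gradient(epochs.data[idx], class_index)
    maps = [
        normalize_map(
            SaliencyMap(values=g, class_index=class_index, times=epochs.times, layout=epochs.layout)
        )
        for g in grads
    ]
    return average_maps(maps)


def normalize_map(smap: SaliencyMap) -> SaliencyMap:
    """Scale so max |value| = 1, preserving sign; all-zero maps pass through."""
    peak = np.abs(smap.values).max()
    if peak == 0:
        return replace(smap, normalized=True, provenance={**smap.provenance, "all_zero": True})
    return replace(smap, values=smap.values / peak, normalized=True)


def average_maps(maps: list[SaliencyMap]) -> SaliencyMap:
    """Element-wise mean of maps (superimpose-and-average)."""
    if not maps:
        raise ValueError("cannot average an empty list of maps")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape:
            raise ValueError("saliency map shape mismatch")
        if m.class_index != first.class_index:
            raise ValueError("saliency maps belong to different classes")
    stacked = np.stack([m.values for m in maps])
    prov = dict(first.provenance)
    prov["n_averaged"] = len(maps)
    return replace(first, values=stacked.mean(axis=0), provenance=prov)


# ------------------------------------------------------------------ profiles --
def spatial_profile(smap: SaliencyMap) -> pd.Series:
    """Per-electrode mean of |gradient| across all samples."""
    return pd.Series(np.abs(smap.values).mean(axis=1), index=list(smap.layout.names))


def temporal_profile(smap: SaliencyMap) -> pd.Series:
    """Per-sample mean of |gradient| across electrodes, indexed by time (ms)."""
    return pd.Series(np.abs(smap.values).mean(axis=0), index=smap.times)


def peak_gradient(
    profile: pd.Series, window_ms: tuple[float, float] = (300.0, 400.0)
) -> tuple[float, float]:
    """(peak value, peak latency ms) inside a window; earliest sample on ties."""
    times = profile.index.to_numpy(dtype=float)
    mask = (times >= window_ms[0]) & (times <= window_ms[1])
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    seg = profile.to_numpy()[mask]
    seg_t = times[mask]
    i = int(np.argmax(seg))
    return float(seg[i]), float(seg_t[i])


# ------------------------------------------------------------ sliding window --
@dataclass(frozen=True)
class IntervalResult:
    start_ms: float
    end_ms: float
    statistic: float

    @property
    def center_ms(self) -> float:
        return (self.start_ms + self.end_ms) / 2.0


def most_varied_interval(
    smap: SaliencyMap,
    electrode: str = "Pz",
    width_ms: float = 100.0,
    step_ms: float = 5.0,
    statistic: str = "mean",
    search_band_ms: tuple[float, float] | None = None,
) -> IntervalResult:
    """Grid-aligned window maximizing |gradient| on one electrode's row.

    Candidate windows start at the epoch start and advance in ``step_ms``
    steps while fully inside the epoch; a sample belongs to a window when
    start <= t <= start + width (inclusive). Statistic is the window mean of
    |gradient| by default ('sum' and 'max' selectable). Earliest window on ties.

    ``search_band_ms`` optionally restricts candidate windows to lie fully
    inside a band (used by the latency-trend analysis, which searches the
    P300 region only).
    """
    row = np.abs(smap.values[smap.layout.index(electrode)])
    times = smap.times
    if width_ms > times[-1] - times[0]:
        raise ValueError("window wider than the epoch")
    reducer = {"mean": np.mean, "sum": np.sum, "max": np.max}[statistic]
    lo, hi = search_band_ms if search_band_ms is not None else (times[0], times[-1])
    best: IntervalResult | None = None
    start = lo
    while start + width_ms <= hi + 1e-9:
        mask = (times >= start - 1e-9) & (times <= start + width_ms + 1e-9)
        value = float(reducer(row[mask]))
        if best is None or value > best.statistic + 1e-15:
            best = IntervalResult(start_ms=float(start), end_ms=float(start + width_ms), statistic=value)
        start += step_ms
    return best


def most_varied_intervals_by_session(
    maps_by_session: dict[int, SaliencyMap], electrode: str = "Pz", **kwargs
) -> pd.DataFrame:
    rows = []
    for session, smap in sorted(maps_by_session.items()):
        res = most_varied_interval(smap, electrode=electrode, **kwargs)
        rows.append(
            {
                "session": session,
                "start_ms": res.start_ms,
                "end_ms": res.end_ms,
                "center_ms": res.center_ms,
                "statistic": res.statistic,
            }
        )
    return pd.DataFrame(rows)


#: Window-search band for the latency-trend analysis: the P300 region (all
#: most-varied intervals are reported to fall within 300-500 ms).
P300_SEARCH_BAND_MS = (250.0, 550.0)


def per_session_latency_centers(
    dataset: EpochSet,
    scenario: str = "social",
    model_seeds: int = 3,
    model_config=None,
    train_config=None,
    electrode: str = "Pz",
    search_band_ms: tuple[float, float] = P300_SEARCH_BAND_MS,
    seed_offset: int = 0,
) -> pd.DataFrame:
    """Most-varied-window center per session from per-session trained models.

    For every session: train ``model_seeds`` independently initialized
    classifiers on that session's epochs (one scenario), average their
    normalized target-trial saliency maps (averaging across differently
    initialized models cancels initialization noise, as cross-subject map
    averaging does), and locate the 100 ms window with the largest mean
    |gradient| at *electrode* inside the P300 search band.
    """
    from .nn.model import EEGNetConfig
    from .nn.train import TrainConfig, train_on

    model_config = model_config or EEGNetConfig()
    if train_config is None:
        train_config = TrainConfig(
            learning_rate=1e-3, max_epochs=12, patience=12, val_fraction=0.0, dtype="float32"
        )
    rows = []
    for session in sorted(dataset.meta["session"].unique()):
        sub = dataset.query(f"session == {session} and scenario == {scenario!r}")
        maps = []
        for s in range(model_seeds):
            tcfg = dataclasses.replace(
                train_config, seed=seed_offset + 1000 * int(session) + s
            )
            model, _ = train_on(sub, model_config, tcfg)
            maps.append(saliency_for_epochs(model, sub))
        interval = most_varied_interval(
            average_maps(maps), electrode=electrode, search_band_ms=search_band_ms
        )
        rows.append(
            {
                "session": int(session),
                "start_ms": interval.start_ms,
                "end_ms": interval.end_ms,
                "center_ms": interval.center_ms,
                "statistic": interval.statistic,
            }
        )
    return pd.DataFrame(rows)


def latency_trend(centers_ms: np.ndarray, sessions: np.ndarray | None = None) -> tuple[float, float]:
    """Pearson correlation between session number and window-center latency."""
    centers_ms = np.asarray(centers_ms, dtype=float)
    if sessions is None:
        sessions = np.arange(1, len(centers_ms) + 1, dtype=float)
    return pearson(np.asarray(sessions, dtype=float), centers_ms)
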