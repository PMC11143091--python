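"""Continuous-recording preprocessing: notch, band-pass, epoching, censoring.

All filters are zero-phase (applied forward-backward with ``filtfilt``) so
component latencies survive intact — the latency-trend analysis depends on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .continuous import ContinuousRecording
from .epochs import EPOCH_TMAX_MS, EPOCH_TMIN_MS, EpochSet

logger = logging.getLogger(__name__)

SEGMENT_TMIN_MS = -200.0
SEGMENT_TMAX_MS = 1200.0


def notch_50hz(rec: ContinuousRecording, freq: float = 50.0, q: float = 30.0) -> ContinuousRecording:
    """Zero-phase 50 Hz band-stop (IIR notch, quality factor 30)."""
    if rec.sfreq <= 2 * freq:
        raise ValueError(f"sampling rate {rec.sfreq} Hz too low for a {freq} Hz notch")
    b, a = sps.iirnotch(freq, q, fs=rec.sfreq)
    return rec.copy_with(sps.filtfilt(b, a, rec.signal, axis=1))


def bandpass_2_30(
    rec: ContinuousRecording, low: float = 2.0, high: float = 30.0, order: int = 4
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass (4th order, applied forward-backward)."""
    nyq = rec.sfreq / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) Hz for sfreq {rec.sfreq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.sfreq, output="sos")
    return rec.copy_with(sps.sosfiltfilt(sos, rec.signal, axis=1))


@dataclass
class RawEpochs:
    """Wide-window epochs straight out of segmentation (pre-detrend/crop)."""

    data: np.ndarray  # n x channels x samples
    labels: np.ndarray
    meta: pd.DataFrame
    sfreq: float
    tmin_ms: float


def segment(
    rec: ContinuousRecording,
    tmin_ms: float = SEGMENT_TMIN_MS,
    tmax_ms: float = SEGMENT_TMAX_MS,
) -> RawEpochs:
    """Cut one wide epoch per event; events too close to an edge are dropped.

    Per-epoch sample count is (tmax - tmin) * sfreq + 1 (inclusive endpoints).
    """
    pre = int(round(-tmin_ms / 1000.0 * rec.sfreq))
    post = int(round(tmax_ms / 1000.0 * rec.sfreq))
    n_samp = pre + post + 1
    keep_rows, chunks = [], []
    for i, ev in enumerate(rec.events.itertuples(index=False)):
        start = ev.sample - pre
        stop = ev.sample + post + 1
        if start < 0 or stop > rec.n_samples:
            logger.warning(
                "dropping event at sample %d: window [%d, %d) outside recording", ev.sample, start, stop
            )
            continue
        keep_rows.append(i)
        chunks.append(rec.signal[:, start:stop])
    meta = rec.events.iloc[keep_rows].reset_index(drop=True)
    data = np.stack(chunks) if chunks else np.empty((0, rec.layout.n_channels, n_samp))
    labels = meta["code"].to_numpy(dtype=int) if len(meta) else np.empty(0, dtype=int)
    meta = meta.drop(columns=["sample", "code"], errors="ignore")
    return RawEpochs(data=data, labels=labels, meta=meta, sfreq=rec.sfreq, tmin_ms=tmin_ms)


def censor_adjacent_mask(labels: np.ndarray, run_ids: np.ndarray) -> np.ndarray:
    """Keep-mask implementing target-neighbour censoring.

    For every target trial, the immediately preceding and following trials *in
    presentation order within the same run* are removed (unless they are
    themselves targets). Targets are always retained.
    """
    labels = np.asarray(labels)
    n = len(labels)
    keep = np.ones(n, dtype=bool)
    for i in np.flatnonzero(labels == 1):
        for j in (i - 1, i + 1):
            if 0 <= j < n and run_ids[j] == run_ids[i] and labels[j] == 0:
                keep[j] = False
    return keep


def censor_adjacent(epochs: RawEpochs | EpochSet) -> RawEpochs | EpochSet:
    """Apply target-neighbour censoring using run/block ordering metadata."""
    meta = epochs.meta
    required = {"block", "run"}
    if not required.issubset(meta.columns):
        raise ValueError("censoring requires 'block' and 'run' ordering metadata")
    # unique run id per (subject?, session?, scenario?, block, run)
    key_cols = [c for c in ("subject", "session", "scenario", "block", "run") if c in meta.columns]
    run_ids = pd.factorize(pd.MultiIndex.from_frame(meta[key_cols]))[0]
    keep = censor_adjacent_mask(epochs.labels, run_ids)
    if isinstance(epochs, EpochSet):
        return epochs.select(keep)
    return RawEpochs(
        data=epochs.data[keep],
        labels=epochs.labels[keep],
        meta=meta.iloc[keep].reset_index(drop=True),
        sfreq=epochs.sfreq,
        tmin_ms=epochs.tmin_ms,
    )


def detrend_and_crop(
    raw: RawEpochs,
    tmin_ms: float = EPOCH_TMIN_MS,
    tmax_ms: float = EPOCH_TMAX_MS,
    layout=None,
) -> EpochSet:
    """Crop to the analysis window and remove a per-channel linear trend.

    The best-fit line is estimated on the cropped window, matching the final
    8 x 201 product of the pipeline.
    """
    if tmin_ms < raw.tmin_ms:
        raise ValueError("requested window starts before the raw epoch window")
    start = int(round((tmin_ms - raw.tmin_ms) / 1000.0 * raw.sfreq))
    n_out = int(round((tmax_ms - tmin_ms) / 1000.0 * raw.sfreq)) + 1
    if start + n_out > raw.data.shape[2]:
        raise ValueError("requested window ends after the raw epoch window")
    cropped = raw.data[:, :, start : start + n_out]
    detrended = sps.detrend(cropped, axis=2, type="linear")
    from .layout import ChannelLayout

    return EpochSet(
        data=detrended,
        labels=raw.labels,
        meta=raw.meta,
        layout=layout or ChannelLayout(),
        sfreq=raw.sfreq,
        tmin_ms=tmin_ms,
    )


def preprocess_recording(
    rec: ContinuousRecording,
    notch: bool = True,
    band: tuple[float, float] | None = (2.0, 30.0),
    censor: bool = True,
    segment_window_ms: tuple[float, float] = (SEGMENT_TMIN_MS, SEGMENT_TMAX_MS),
    crop_window_ms: tuple[float, float] = (EPOCH_TMIN_MS, EPOCH_TMAX_MS),
) -> EpochSet:
    """Full chain: notch -> band-pass -> segment -> censor -> detrend + crop."""
    if notch:
        rec = notch_50hz(rec)
    if band is not None:
        rec = bandpass_2_30(rec, *band)
    raw = segment(rec, *segment_window_ms)
    if censor:
        raw = censor_adjacent(raw)
    return detrend_and_crop(raw, *crop_window_ms, layout=rec.layout)
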