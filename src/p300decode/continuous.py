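"""Continuous multichannel recording with event markers.

Recordings are exchanged as plain text: a TSV signal matrix (one column per
channel, one row per sample) plus a TSV event table (sample index, code,
optional metadata columns).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import ChannelLayout


@dataclass
class ContinuousRecording:
    """channels x samples voltage matrix (µV) with stimulus events.

    ``events`` is a DataFrame with at least columns ``sample`` (int index into
    the signal) and ``code`` (1 = target, 0 = standard); extra columns (subject,
    session, scenario, run, ...) travel through epoching untouched.
    """

    signal: np.ndarray
    sfreq: float
    events: pd.DataFrame
    layout: ChannelLayout = field(default_factory=ChannelLayout)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2D (channels, samples)")
        if self.signal.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows, layout has {self.layout.n_channels}"
            )
        ev = self.events.reset_index(drop=True)
        if len(ev) and not ev["sample"].is_monotonic_increasing:
            ev = ev.sort_values("sample", ignore_index=True)
        if len(ev) and (ev["sample"].iloc[-1] >= self.signal.shape[1] or ev["sample"].iloc[0] < 0):
            raise ValueError("event sample indices must lie within the signal")
        self.events = ev

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def copy_with(self, signal: np.ndarray) -> "ContinuousRecording":
        return ContinuousRecording(
            signal=signal, sfreq=self.sfreq, events=self.events.copy(), layout=self.layout
        )

    # ---------------------------------------------------------------- IO ----
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        sig = pd.DataFrame(self.signal.T, columns=list(self.layout.names))
        sig.to_csv(directory / "signal.tsv", sep="\t", index=False, float_format="%.6f")
        self.events.to_csv(directory / "events.tsv", sep="\t", index=False)
        header = {
            "sfreq": self.sfreq,
            "channels": list(self.layout.names),
            "positions": self.layout.positions.tolist(),
        }
        (directory / "recording.json").write_text(json.dumps(header, indent=2))

    @staticmethod
    def load(directory: str | Path) -> "ContinuousRecording":
        directory = Path(directory)
        header = json.loads((directory / "recording.json").read_text())
        sig = pd.read_csv(directory / "signal.tsv", sep="\t")
        events = pd.read_csv(directory / "events.tsv", sep="\t")
        layout = ChannelLayout(
            names=tuple(header["channels"]), positions=np.array(header["positions"])
        )
        return ContinuousRecording(
            signal=sig.to_numpy().T, sfreq=header["sfreq"], events=events, layout=layout
        )
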