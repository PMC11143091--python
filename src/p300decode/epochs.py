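"""Labeled single-trial epoch container shared by all pipeline stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import ChannelLayout

#: Epoch window endpoints (ms relative to stimulus onset) and sampling rate.
EPOCH_TMIN_MS = -100.0
EPOCH_TMAX_MS = 700.0
SFREQ = 250.0
#: Samples per epoch: 0.8 s * 250 Hz + 1 (both endpoints included).
N_SAMPLES = int(round((EPOCH_TMAX_MS - EPOCH_TMIN_MS) / 1000.0 * SFREQ)) + 1

#: Metadata columns carried with every epoch.
META_COLUMNS = ("subject", "session", "scenario", "block", "run", "trial_in_run", "true_p300_latency")


def epoch_times(
    tmin_ms: float = EPOCH_TMIN_MS, tmax_ms: float = EPOCH_TMAX_MS, sfreq: float = SFREQ
) -> np.ndarray:
    """Time axis in ms, inclusive of both endpoints."""
    n = int(round((tmax_ms - tmin_ms) / 1000.0 * sfreq)) + 1
    return tmin_ms + np.arange(n) * 1000.0 / sfreq


@dataclass
class EpochSet:
    """n_epochs x 8 x 201 voltage array (µV) with labels and trial metadata.

    ``labels`` are 1 for target stimuli, 0 for standards. ``meta`` carries one
    row per epoch (subject/session/scenario/block/run/trial order and, for
    simulated data, the ground-truth P300 latency).
    """

    data: np.ndarray
    labels: np.ndarray
    meta: pd.DataFrame
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    sfreq: float = SFREQ
    tmin_ms: float = EPOCH_TMIN_MS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D (n, channels, samples), got {self.data.shape}")
        if self.data.shape[1] != self.layout.n_channels:
            raise ValueError(
                f"channel axis {self.data.shape[1]} != layout size {self.layout.n_channels}"
            )
        if len(self.labels) != len(self.data):
            raise ValueError("labels/data length mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if len(self.meta) != len(self.data):
            raise ValueError("meta/data length mismatch")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.n_samples) * 1000.0 / self.sfreq

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            labels=self.labels[mask],
            meta=self.meta.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask],
            layout=self.layout,
            sfreq=self.sfreq,
            tmin_ms=self.tmin_ms,
        )

    def query(self, expr: str) -> "EpochSet":
        """Subset by a pandas query on the metadata table."""
        idx = self.meta.query(expr).index.to_numpy()
        return self.select(idx)

    @staticmethod
    def concatenate(parts: list["EpochSet"]) -> "EpochSet":
        if not parts:
            raise ValueError("cannot concatenate an empty list")
        first = parts[0]
        return EpochSet(
            data=np.concatenate([p.data for p in parts], axis=0),
            labels=np.concatenate([p.labels for p in parts]),
            meta=pd.concat([p.meta for p in parts], ignore_index=True),
            layout=first.layout,
            sfreq=first.sfreq,
            tmin_ms=first.tmin_ms,
        )

    # ---------------------------------------------------------------- IO ----
    def save(self, directory: str | Path) -> None:
        """Write epochs.npz + metadata.tsv + epochs.json into *directory*."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(directory / "epochs.npz", data=self.data, labels=self.labels)
        meta = self.meta.copy()
        meta["label"] = self.labels
        meta.to_csv(directory / "metadata.tsv", sep="\t", index=False)
        header = {
            "sfreq": self.sfreq,
            "tmin_ms": self.tmin_ms,
            "channels": list(self.layout.names),
            "positions": self.layout.positions.tolist(),
        }
        (directory / "epochs.json").write_text(json.dumps(header, indent=2))

    @staticmethod
    def load(directory: str | Path) -> "EpochSet":
        directory = Path(directory)
        with np.load(directory / "epochs.npz") as z:
            data, labels = z["data"], z["labels"]
        meta = pd.read_csv(directory / "metadata.tsv", sep="\t")
        meta = meta.drop(columns=["label"], errors="ignore")
        header = json.loads((directory / "epochs.json").read_text())
        layout = ChannelLayout(
            names=tuple(header["channels"]), positions=np.array(header["positions"])
        )
        return EpochSet(
            data=data,
            labels=labels,
            meta=meta,
            layout=layout,
            sfreq=header["sfreq"],
            tmin_ms=header["tmin_ms"],
        )
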