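"""Electrode montage for the 8-channel centro-parietal cap."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default electrode order used throughout the package.
DEFAULT_CHANNELS = ("C3", "Cz", "C4", "CPz", "P3", "Pz", "P4", "POz")

# Approximate 2D scalp coordinates (x: left-to-right, y: posterior-to-anterior),
# arbitrary units on a unit head radius. Only relative distances matter: they
# seed smooth topography weights for simulated components.
_DEFAULT_POSITIONS = {
    "C3": (-0.40, 0.00),
    "Cz": (0.00, 0.00),
    "C4": (0.40, 0.00),
    "CPz": (0.00, -0.20),
    "P3": (-0.35, -0.40),
    "Pz": (0.00, -0.40),
    "P4": (0.35, -0.40),
    "POz": (0.00, -0.60),
}


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered electrode names plus 2D scalp positions.

    Parameters
    ----------
    names
        Ordered electrode labels; must contain exactly 8 unique entries.
    positions
        ``(8, 2)`` array of scalp coordinates, row-aligned with *names*.
    """

    names: tuple[str, ...] = DEFAULT_CHANNELS
    positions: np.ndarray = field(
        default_factory=lambda: np.array(
            [_DEFAULT_POSITIONS[ch] for ch in DEFAULT_CHANNELS], dtype=float
        )
    )

    def __post_init__(self) -> None:
        if len(self.names) != 8:
            raise ValueError(f"layout must have exactly 8 channels, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (8, 2):
            raise ValueError(f"positions must be (8, 2), got {pos.shape}")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        """Row index of electrode *name* (raises ValueError if absent)."""
        try:
            return self.names.index(name)
        except ValueError:
            raise ValueError(f"unknown electrode {name!r}; have {self.names}") from None

    def gaussian_topography(self, center: str, spread: float = 0.45) -> np.ndarray:
        """Smooth per-channel weights in [0, 1] peaking (=1) at *center*.

        Weights fall off as a Gaussian of the scalp distance to the focal
        electrode; *spread* is the Gaussian sigma in position units.
        """
        if spread <= 0:
            raise ValueError("spread must be positive")
        c = self.positions[self.index(center)]
        d2 = np.sum((self.positions - c) ** 2, axis=1)
        w = np.exp(-0.5 * d2 / spread**2)
        return w / w.max()
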