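"""Frequency-band scheme for the motor-network analysis.

The analysis divides the 4--48 Hz range into four canonical bands:
theta (4--8), alpha (8--15), beta (15--30) and gamma (30--48 Hz).
Bands are half-open ``[low, high)`` except the last, which also owns its
upper edge so the full grid is covered by exactly one band per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BandScheme", "DEFAULT_BANDS", "default_frequency_grid"]


@dataclass(frozen=True)
class BandScheme:
    """Contiguous partition of a frequency range into named bands.

    Parameters
    ----------
    edges : dict
        Mapping band name -> (low, high) in Hz.  Bands must be contiguous
        and ordered; each frequency bin belongs to the band whose
        half-open interval ``[low, high)`` contains it (the top band is
        closed at its upper edge).
    """

    edges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "theta": (4.0, 8.0),
            "alpha": (8.0, 15.0),
            "beta": (15.0, 30.0),
            "gamma": (30.0, 48.0),
        }
    )

    def __post_init__(self) -> None:
        lows = [lo for lo, _ in self.edges.values()]
        highs = [hi for _, hi in self.edges.values()]
        if any(hi <= lo for lo, hi in self.edges.values()):
            raise ValueError("each band must have low < high")
        if any(h != l for h, l in zip(highs[:-1], lows[1:])):
            raise ValueError("bands must be contiguous and ordered")

    @property
    def names(self) -> list[str]:
        return list(self.edges)

    @property
    def fmin(self) -> float:
        return next(iter(self.edges.values()))[0]

    @property
    def fmax(self) -> float:
        return list(self.edges.values())[-1][1]

    def band_of(self, freq: float) -> str:
        """Name of the band owning ``freq``; raises if out of range."""
        names = self.names
        for i, (name, (lo, hi)) in enumerate(self.edges.items()):
            last = i == len(names) - 1
            if lo <= freq < hi or (last and freq == hi):
                return name
        raise ValueError(f"frequency {freq} Hz outside {self.fmin}-{self.fmax} Hz")

    def membership(self, freqs: np.ndarray) -> dict[str, np.ndarray]:
        """Boolean mask per band over a frequency grid (a partition)."""
        freqs = np.asarray(freqs, dtype=float)
        return {
            name: np.array([self.band_of(f) == name for f in freqs])
            for name in self.names
        }


DEFAULT_BANDS = BandScheme()


def default_frequency_grid(step: float = 1.0) -> np.ndarray:
    """1 Hz grid over 4--48 Hz (45 bins) used for spectrograms."""
    return np.arange(4.0, 48.0 + 0.5 * step, step)
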