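"""The five core motor cortical sources and the scalp montage.

The network model is defined over the supplementary motor area (SMA),
bilateral primary motor cortex (M1) and bilateral premotor cortex (PM).
After mid-sagittal flipping the ipsilesional (i-) hemisphere is mapped to
the left, so iM1/iPM carry left-hemisphere coordinates and cM1/cPM
(contralesional) right-hemisphere ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SourceSet", "DEFAULT_SOURCES", "MONTAGE_32", "mirror_channel"]

#: MNI coordinates (mm) of the five sources, ipsilesional on the left.
_DEFAULT_COORDS: dict[str, tuple[float, float, float]] = {
    "SMA": (-2.0, -2.0, 62.0),
    "iM1": (-41.0, -26.0, 56.0),
    "cM1": (49.0, -27.0, 56.0),
    "iPM": (-40.0, -12.0, 52.0),
    "cPM": (40.0, -2.0, 62.0),
}


@dataclass(frozen=True)
class SourceSet:
    """Labels and MNI coordinates of the motor network nodes."""

    coords: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COORDS)
    )

    def __post_init__(self) -> None:
        if len(self.coords) != 5:
            raise ValueError("the motor source set has exactly 5 sources")

    @property
    def labels(self) -> list[str]:
        return list(self.coords)

    def coordinate_array(self) -> np.ndarray:
        return np.array([self.coords[k] for k in self.labels], dtype=float)


DEFAULT_SOURCES = SourceSet()

#: 32-channel 10-20 system montage used by the synthetic recordings.
MONTAGE_32: list[str] = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT9", "FC5", "FC1", "FC2", "FC6", "FT10",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
]


def mirror_channel(name: str) -> str:
    """Mid-sagittal mirror of a 10-20 channel label.

    Odd electrode numbers lie over the left hemisphere, even over the
    right; 'z' labels are midline and map to themselves.
    """
    head = name.rstrip("0123456789")
    digits = name[len(head):]
    if not digits:
        if name.endswith("z"):
            return name
        raise ValueError(f"channel {name!r} has no left/right pairing")
    n = int(digits)
    mirrored = n + 1 if n % 2 == 1 else n - 1
    return f"{head}{mirrored}"
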