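"""Band- and sign-resolved feature vectors from fitted models.

Each directed connection's frequency-coupling matrix is summarized per
band by two "mechanisms": the excitatory feature is the mean of its
positive entries whose *target* frequency falls in the band, the
inhibitory feature the mean of the negative entries.  With 4 bands this
gives 8 attributes per connection (144 for the 18-edge model).  Source
spectrograms are summarized the same way per source (positive and
negative power bins), giving 40 attributes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, BandScheme
from .dcm import CouplingParams, DCMFit
from .preprocess import SourceSpectrogram

__all__ = ["FeatureVector", "extract_connection_features", "extract_source_features",
           "feature_table"]

_SIGNS = ("excitatory", "inhibitory")


@dataclass
class FeatureVector:
    """Named attribute vector with (unit, band, sign) structure.

    ``kind`` is 'connection' (8 x n_edges attributes) or 'source'
    (8 x n_sources).  Names follow ``unit.band.sign`` where unit is
    ``src->dst`` for connections or the source label.
    """

    values: np.ndarray
    names: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.names):
            raise ValueError("values and names must align")

    def band_of(self, i: int) -> str:
        return self.names[i].split(".")[1]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def _signed_means(entries: np.ndarray) -> tuple[float, float]:
    """(mean of positives, mean of negatives); 0 when a class is empty."""
    pos = entries[entries > 0]
    neg = entries[entries < 0]
    exc = float(pos.mean()) if pos.size else 0.0
    inh = float(neg.mean()) if neg.size else 0.0
    return exc, inh


def extract_connection_features(
    fit: DCMFit | CouplingParams,
    bands: BandScheme = DEFAULT_BANDS,
    band_axis: str = "target",
) -> FeatureVector:
    """8 attributes (4 bands x 2 signs) per directed connection.

    ``band_axis`` chooses whether a cross-frequency entry is assigned
    to the band of its target frequency (rows, default) or its source
    frequency (columns).
    """
    params = fit.params if isinstance(fit, DCMFit) else fit
    if not params.A:
        raise ValueError("fit has no connection coupling matrices")
    masks = bands.membership(params.frequencies)
    values: list[float] = []
    names: list[str] = []
    for (src, dst), mat in params.A.items():
        for b in bands.names:
            sel = mat[masks[b], :] if band_axis == "target" else mat[:, masks[b]]
            exc, inh = _signed_means(sel.ravel())
            for sign, v in zip(_SIGNS, (exc, inh)):
                values.append(v)
                names.append(f"{src}->{dst}.{b}.{sign}")
    return FeatureVector(np.array(values), names, kind="connection")


def extract_source_features(
    spec: SourceSpectrogram, bands: BandScheme = DEFAULT_BANDS
) -> FeatureVector:
    """8 attributes (4 bands x 2 signs) per source from its spectrum.

    Positive and negative baseline-corrected power bins are averaged
    separately per band over the whole analysis window.
    """
    masks = bands.membership(spec.frequencies)
    values: list[float] = []
    names: list[str] = []
    for si, label in enumerate(spec.source_labels):
        for b in bands.names:
            sel = spec.power[si][masks[b], :]
            exc, inh = _signed_means(sel.ravel())
            for sign, v in zip(_SIGNS, (exc, inh)):
                values.append(v)
                names.append(f"{label}.{b}.{sign}")
    return FeatureVector(np.array(values), names, kind="source")


def feature_table(vectors: list[FeatureVector], subject_ids=None) -> pd.DataFrame:
    """Stack per-subject feature vectors into a subjects x attributes frame."""
    if not vectors:
        raise ValueError("no feature vectors given")
    names = vectors[0].names
    for v in vectors[1:]:
        if v.names != names:
            raise ValueError("feature vectors have inconsistent attribute names")
    idx = subject_ids if subject_ids is not None else range(len(vectors))
    return pd.DataFrame([v.values for v in vectors], index=idx, columns=names)
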