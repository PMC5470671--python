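"""From raw trial EEG to source-level baseline-corrected induced power.

The pipeline mirrors a standard induced-response analysis of a cued
movement task: band-pass 4--48 Hz, amplitude-based artifact rejection,
mid-sagittal flipping so the ipsilesional hemisphere is always on the
left, projection to the five motor sources through the pseudoinverse of
a lead field, Morlet time-frequency transform (7 cycles), trial
averaging and baseline correction, cropped to -500..800 ms around the
cue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import signal

from .sources import mirror_channel

__all__ = [
    "TrialEpochs",
    "SourceSpectrogram",
    "bandpass_epochs",
    "reject_artifacts",
    "flip_hemispheres",
    "project_to_sources",
    "morlet_power",
    "average_and_baseline",
]


class EmptyDataError(ValueError):
    """All trials were rejected; downstream stages need at least one."""


@dataclass
class TrialEpochs:
    """Cue-locked EEG epochs: channels x time x trials, in microvolts.

    ``epoch_window`` is (start, stop) in ms relative to the auditory cue
    at time zero.  ``trial_mask`` marks trials where the movement
    succeeded (failed movements are flagged by the therapist, not
    detected algorithmically).
    """

    data: np.ndarray
    sample_rate: float
    channel_names: list[str]
    epoch_window: tuple[float, float]
    trial_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x time x trials")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")
        n_expected = int(round(
            (self.epoch_window[1] - self.epoch_window[0]) / 1000.0 * self.sample_rate
        )) + 1
        if abs(self.data.shape[1] - n_expected) > 1:
            raise ValueError(
                f"time axis ({self.data.shape[1]}) inconsistent with "
                f"epoch_window {self.epoch_window} at {self.sample_rate} Hz"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.epoch_window[0] + np.arange(self.data.shape[1]) / self.sample_rate * 1000.0

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("sample_rate", data=self.sample_rate)
            f.create_dataset(
                "channel_names",
                data=np.array(self.channel_names, dtype=h5py.string_dtype()),
            )
            f.create_dataset("epoch_window", data=np.array(self.epoch_window))
            if self.trial_mask is not None:
                f.create_dataset("trial_mask", data=self.trial_mask.astype(bool))

    @classmethod
    def from_hdf5(cls, path) -> "TrialEpochs":
        with h5py.File(path, "r") as f:
            mask = f["trial_mask"][()] if "trial_mask" in f else None
            return cls(
                data=f["data"][()],
                sample_rate=float(f["sample_rate"][()]),
                channel_names=[s.decode() if isinstance(s, bytes) else str(s)
                               for s in f["channel_names"][()]],
                epoch_window=tuple(f["epoch_window"][()]),
                trial_mask=mask,
            )


@dataclass
class SourceSpectrogram:
    """Baseline-corrected induced power: sources x frequencies x time.

    ``power`` is percent change from baseline by default (see
    :func:`average_and_baseline`); ``times_ms`` spans the analysis
    window around the cue.
    """

    power: np.ndarray
    frequencies: np.ndarray
    times_ms: np.ndarray
    source_labels: list[str]
    n_trials_used: int = 0

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.power.shape != (
            len(self.source_labels),
            self.frequencies.size,
            self.times_ms.size,
        ):
            raise ValueError("power axes must be (sources, frequencies, times)")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("power must be finite")


def bandpass_epochs(raw: TrialEpochs, low: float = 4.0, high: float = 48.0) -> TrialEpochs:
    """Zero-phase 4th-order Butterworth band-pass per channel and trial."""
    nyq = raw.sample_rate / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=raw.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, raw.data, axis=1)
    return replace(raw, data=filtered)


def reject_artifacts(
    epochs: TrialEpochs, threshold_uV: float = 500.0
) -> tuple[TrialEpochs, np.ndarray]:
    """Drop trials whose absolute amplitude exceeds the threshold.

    The criterion is strict ``>`` on any channel at any sample.  Returns
    the surviving epochs (order preserved) and the rejected indices.
    """
    if threshold_uV <= 0:
        raise ValueError("threshold must be positive")
    peak = np.max(np.abs(epochs.data), axis=(0, 1))
    bad = np.flatnonzero(peak > threshold_uV)
    keep = np.flatnonzero(peak <= threshold_uV)
    if keep.size == 0:
        raise EmptyDataError("all trials exceeded the artifact threshold")
    mask = epochs.trial_mask[keep] if epochs.trial_mask is not None else None
    return replace(epochs, data=epochs.data[:, :, keep], trial_mask=mask), bad


def flip_hemispheres(epochs: TrialEpochs, lesion_side: str) -> TrialEpochs:
    """Mirror channels along the mid-sagittal line for right-lesion subjects.

    Mapping every subject's lesion to the left hemisphere lets a single
    (ipsilesional = left) network model serve the whole group.  Left
    lesions pass through unchanged.
    """
    if lesion_side not in ("left", "right"):
        raise ValueError("lesion_side must be 'left' or 'right'")
    if lesion_side == "left":
        return replace(epochs, data=epochs.data.copy())
    index = {name: i for i, name in enumerate(epochs.channel_names)}
    order = np.empty(len(index), dtype=int)
    for i, name in enumerate(epochs.channel_names):
        mirrored = mirror_channel(name)
        if mirrored not in index:
            raise ValueError(f"montage lacks the mirror of channel {name!r}")
        order[i] = index[mirrored]
    return replace(epochs, data=epochs.data[order])


def project_to_sources(epochs: TrialEpochs, lead_field: np.ndarray) -> np.ndarray:
    """Project channel data to sources via the lead-field pseudoinverse.

    Returns a sources x time x trials array (minimum-norm solution; a
    rank-deficient lead field triggers a warning, not an error).
    """
    L = np.asarray(lead_field, dtype=float)
    if L.shape[0] != epochs.data.shape[0]:
        raise ValueError("lead field rows must match channel count")
    if np.linalg.matrix_rank(L) < L.shape[1]:
        warnings.warn("lead field is rank deficient; minimum-norm solution used")
    pinv = np.linalg.pinv(L)
    return np.einsum("sc,ctr->str", pinv, epochs.data)


def morlet_kernel(freq: float, sample_rate: float, n_cycles: float = 7.0) -> np.ndarray:
    """Complex Morlet kernel at ``freq`` Hz, scaled so that convolution
    with a unit-amplitude sinusoid at ``freq`` has magnitude ~1."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    t = np.arange(-3.5 * sigma_t, 3.5 * sigma_t + 0.5 / sample_rate, 1.0 / sample_rate)
    envelope = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = envelope * np.exp(2j * np.pi * freq * t)
    return kernel / (0.5 * envelope.sum())


def morlet_power(
    source_series: np.ndarray,
    sample_rate: float,
    frequencies: np.ndarray,
    wavelet_number: float = 7.0,
) -> np.ndarray:
    """Magnitude of the complex Morlet transform per trial.

    Parameters
    ----------
    source_series : sources x time x trials array.
    frequencies : Hz grid; each must lie below Nyquist.

    Returns
    -------
    power : sources x frequencies x time x trials array of magnitudes
        (the absolute value of the complex transform, i.e. amplitude
        envelope per frequency).
    """
    if wavelet_number < 1:
        raise ValueError("wavelet_number must be >= 1")
    frequencies = np.asarray(frequencies, dtype=float)
    if np.any(frequencies >= sample_rate / 2.0):
        raise ValueError("frequencies must be below Nyquist")
    x = np.asarray(source_series, dtype=float)
    n_src, n_time, n_trials = x.shape
    out = np.empty((n_src, frequencies.size, n_time, n_trials))
    for fi, f in enumerate(frequencies):
        k = morlet_kernel(f, sample_rate, wavelet_number)
        conv = signal.fftconvolve(x, k[None, :, None], mode="same", axes=1)
        out[:, fi] = np.abs(conv)
    return out


def average_and_baseline(
    per_trial_power: np.ndarray,
    times_ms: np.ndarray,
    frequencies: np.ndarray,
    source_labels: list[str],
    baseline_window: tuple[float, float] = (-850.0, -800.0),
    crop_window: tuple[float, float] = (-500.0, 800.0),
    mode: str = "percent",
) -> SourceSpectrogram:
    """Average power over trials, baseline-correct, crop to the analysis window.

    ``mode='percent'`` (default) expresses power as percent change from
    the per-(source, frequency) baseline mean, making downstream
    coupling estimates amplitude-scale-free; ``mode='subtract'`` gives
    plain differences.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    if baseline_window[0] < times_ms[0] or baseline_window[1] >= crop_window[0]:
        raise ValueError("baseline window must lie inside the epoch, before the crop")
    mean_power = np.asarray(per_trial_power, dtype=float).mean(axis=3)
    n_trials = per_trial_power.shape[3]
    bmask = (times_ms >= baseline_window[0]) & (times_ms <= baseline_window[1])
    if not bmask.any():
        raise ValueError("baseline window contains no samples")
    baseline = mean_power[:, :, bmask].mean(axis=2, keepdims=True)
    if mode == "percent":
        if np.any(np.abs(baseline) < 1e-12):
            raise ZeroDivisionError("zero baseline power; percent change undefined")
        corrected = 100.0 * (mean_power - baseline) / baseline
    elif mode == "subtract":
        corrected = mean_power - baseline
    else:
        raise ValueError("mode must be 'percent' or 'subtract'")
    cmask = (times_ms >= crop_window[0]) & (times_ms <= crop_window[1])
    return SourceSpectrogram(
        power=corrected[:, :, cmask],
        frequencies=frequencies,
        times_ms=times_ms[cmask],
        source_labels=list(source_labels),
        n_trials_used=n_trials,
    )
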