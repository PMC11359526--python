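"""Signal-processing chain: raw 4 Hz recordings -> standardized 16 s windows.

Chain order: low-pass denoise -> first-order 0.05 Hz high-pass (phasic
extraction) -> 4 Hz to 1 Hz downsampling -> per-channel (x - mu) / sigma
standardization -> sliding-window segmentation with binary stress labels.
All filters are applied zero-phase (forward-backward) so that response
latencies are not shifted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .simulate import Recording, StimulusProtocol

__all__ = [
    "FilteredRecording",
    "WindowedDataset",
    "lowpass_denoise",
    "highpass_phasic",
    "filter_st",
    "downsample",
    "standardize",
    "make_windows",
    "label_window",
    "preprocess_recording",
    "windows_from_cohort",
]

#: default labeling rule bounds, relative to a stressor time t (seconds):
#: a window is positive iff its start lies in [t - PRE_S, t + POST_S].
PRE_S = 2.0
POST_S = 6.0


def lowpass_denoise(
    signal: np.ndarray, sampling_rate: float, cutoff: float = 1.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass denoising. Output length == input length."""
    signal = np.asarray(signal, dtype=float)
    nyq = sampling_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must be in (0, {nyq}) Hz, got {cutoff}")
    sos = sps.butter(order, cutoff, btype="lowpass", fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, signal)


def highpass_phasic(
    signal: np.ndarray, sampling_rate: float, cutoff: float = 0.05
) -> np.ndarray:
    """First-order 0.05 Hz high-pass extracting the phasic EDA component.

    Applied forward-backward; requires the signal to be longer than the
    filtfilt warm-up (3 x max(len(a), len(b)) samples for a first-order
    section, i.e. 7 samples).
    """
    signal = np.asarray(signal, dtype=float)
    b, a = sps.butter(1, cutoff, btype="highpass", fs=sampling_rate)
    padlen = 3 * max(len(a), len(b))
    if len(signal) <= padlen:
        raise ValueError(
            f"signal length {len(signal)} <= filter warm-up {padlen} samples"
        )
    return sps.filtfilt(b, a, signal)


def filter_st(
    signal: np.ndarray, sampling_rate: float, cutoff: float = 0.05
) -> np.ndarray:
    """Band-limit skin temperature, keeping low-frequency slope changes.

    Default is the same first-order high-pass used for the phasic EDA
    component; the cutoff is configurable.
    """
    return highpass_phasic(signal, sampling_rate, cutoff=cutoff)


def downsample(signal: np.ndarray, from_rate: float, to_rate: float) -> np.ndarray:
    """Anti-aliased decimation. ``from_rate`` must be an integer multiple."""
    signal = np.asarray(signal, dtype=float)
    ratio = from_rate / to_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"from_rate {from_rate} must be an integer multiple of to_rate {to_rate}"
        )
    q = int(round(ratio))
    if q == 1:
        return signal.copy()
    # anti-aliasing at 80% of the target Nyquist, zero-phase so edges stay flat
    sos = sps.butter(8, 0.8 * (to_rate / 2.0), btype="lowpass",
                     fs=from_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, signal)
    n_out = int(len(signal) * to_rate // from_rate)
    return filtered[::q][:n_out]


def standardize(signal: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """(x - mu) / sigma with the population (divide-by-N) standard deviation.

    Constant input yields all-zeros with a warning rather than NaNs.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 2:
        raise ValueError("standardize requires at least 2 samples")
    mu = signal.mean()
    sigma = signal.std()  # population convention (ddof=0)
    if sigma < eps:
        warnings.warn("constant signal: standardization returns zeros", stacklevel=2)
        return np.zeros_like(signal)
    return (signal - mu) / sigma


@dataclass(frozen=True)
class FilteredRecording:
    """Standardized 1 Hz channels of one subject plus the stimulus protocol."""

    subject_id: str
    sampling_rate: float  # Hz, 1 after downsampling
    phasic_eda: np.ndarray
    st_filtered: np.ndarray
    protocol: StimulusProtocol

    @property
    def channels(self) -> np.ndarray:
        """(n_samples, 2) array, column order [eda, st]."""
        return np.column_stack([self.phasic_eda, self.st_filtered])


@dataclass
class WindowedDataset:
    """Fixed-length standardized sequences with binary stress labels."""

    windows: np.ndarray  # (n_windows, window_len, n_channels)
    labels: np.ndarray  # (n_windows,) in {0, 1}
    window_start_s: np.ndarray  # (n_windows,)
    subject_ids: np.ndarray  # (n_windows,) str
    synthetic: np.ndarray = field(default=None)  # (n_windows,) bool provenance

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.window_start_s = np.asarray(self.window_start_s, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.labels), dtype=bool)
        self.synthetic = np.asarray(self.synthetic, dtype=bool)
        if self.windows.ndim != 3:
            raise ValueError("windows must be 3-D (n, length, channels)")
        n = len(self.windows)
        for name in ("labels", "window_start_s", "subject_ids", "synthetic"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must equal number of windows")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]

    def subset(self, mask: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            self.windows[mask],
            self.labels[mask],
            self.window_start_s[mask],
            self.subject_ids[mask],
            self.synthetic[mask],
        )

    def select_channels(self, idx) -> "WindowedDataset":
        return WindowedDataset(
            self.windows[:, :, idx],
            self.labels,
            self.window_start_s,
            self.subject_ids,
            self.synthetic,
        )

    @staticmethod
    def concatenate(parts: list["WindowedDataset"]) -> "WindowedDataset":
        return WindowedDataset(
            np.concatenate([p.windows for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.window_start_s for p in parts]),
            np.concatenate([p.subject_ids for p in parts]),
            np.concatenate([p.synthetic for p in parts]),
        )


def label_window(
    window_start_s: float,
    protocol: StimulusProtocol,
    pre_s: float = PRE_S,
    post_s: float = POST_S,
) -> int:
    """1 iff the window start falls in [t - pre_s, t + post_s] of a stressor t.

    Mirrors the asymmetric event-evaluation window so that a correctly
    labeled positive window, reported at its start time, scores as a true
    positive.
    """
    for t in protocol.stressor_times:
        if t - pre_s <= window_start_s <= t + post_s:
            return 1
    return 0


def make_windows(
    recording: FilteredRecording,
    window_s: float = 16.0,
    stride_s: float = 1.0,
    pre_s: float = PRE_S,
    post_s: float = POST_S,
) -> WindowedDataset:
    """Slide a ``window_s`` window over the 1 Hz channels with ``stride_s``."""
    if stride_s < 1.0 / recording.sampling_rate:
        raise ValueError("stride must be at least one sample")
    data = recording.channels
    w = int(round(window_s * recording.sampling_rate))
    s = int(round(stride_s * recording.sampling_rate))
    n = len(data)
    if n < w:
        raise ValueError(f"recording ({n} samples) shorter than one window ({w})")
    starts = np.arange(0, n - w + 1, s)
    windows = np.stack([data[i : i + w] for i in starts])
    start_times = starts / recording.sampling_rate
    labels = np.array(
        [label_window(t, recording.protocol, pre_s, post_s) for t in start_times]
    )
    return WindowedDataset(
        windows=windows,
        labels=labels,
        window_start_s=start_times,
        subject_ids=np.array([recording.subject_id] * len(starts), dtype=object),
    )


def preprocess_recording(
    recording: Recording,
    lowpass_cutoff: float = 1.0,
    lowpass_order: int = 4,
    highpass_cutoff: float = 0.05,
    st_cutoff: float = 0.05,
    target_rate: float = 1.0,
) -> FilteredRecording:
    """Full per-recording chain up to (but excluding) windowing."""
    fs = recording.sampling_rate
    eda = lowpass_denoise(recording.eda, fs, lowpass_cutoff, lowpass_order)
    eda = highpass_phasic(eda, fs, highpass_cutoff)
    eda = downsample(eda, fs, target_rate)
    eda = standardize(eda)

    st = lowpass_denoise(recording.st, fs, lowpass_cutoff, lowpass_order)
    st = filter_st(st, fs, st_cutoff)
    st = downsample(st, fs, target_rate)
    st = standardize(st)

    return FilteredRecording(
        subject_id=recording.subject_id,
        sampling_rate=target_rate,
        phasic_eda=eda,
        st_filtered=st,
        protocol=recording.protocol,
    )


def windows_from_cohort(
    recordings, window_s: float = 16.0, stride_s: float = 1.0, **chain_kwargs
) -> WindowedDataset:
    """Preprocess and window every recording, concatenating the results."""
    parts = [
        make_windows(preprocess_recording(rec, **chain_kwargs), window_s, stride_s)
        for rec in recordings
    ]
    return WindowedDataset.concatenate(parts)
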