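"""Offline filtering and window segmentation.

The offline chain is a 0.5–70 Hz band-pass plus a 60 Hz notch, applied
zero-phase (forward–backward) so that downstream phase estimates are not
distorted by the filter's phase response.  Filter family and order are
declared defaults (4th-order Butterworth band-pass; IIR notch of quality
factor 30), configurable per call.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .datatypes import Recording

__all__ = ["bandpass_notch", "segment_windows"]


def bandpass_notch(rec: Recording, low_hz: float = 0.5, high_hz: float = 70.0,
                   notch_hz: float = 60.0, order: int = 4,
                   notch_q: float = 30.0) -> Recording:
    """Zero-phase band-pass and notch filter, per channel.

    Parameters
    ----------
    rec : Recording
        Input voltage block.
    low_hz, high_hz : float
        Band-pass corner frequencies (Hz); must satisfy
        ``0 < low_hz < high_hz < fs/2``.
    notch_hz : float or None
        Line-noise notch centre (Hz); ``None`` disables the notch.
    order : int
        Butterworth order (applied forward–backward, so the effective
        magnitude response is squared).
    notch_q : float
        Notch quality factor (centre frequency / -3 dB bandwidth).

    Returns
    -------
    Recording
        New recording with filtered data; labels and metadata preserved.
    """
    nyq = rec.fs / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz >= Nyquist {nyq} Hz")
    if notch_hz is not None and notch_hz >= nyq:
        raise ValueError(f"notch {notch_hz} Hz >= Nyquist {nyq} Hz")

    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs,
                        output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    if notch_hz is not None:
        b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)
    return Recording(subject=rec.subject, condition=rec.condition, fs=rec.fs,
                     channels=list(rec.channels), data=out)


def segment_windows(series: np.ndarray, fs: float, window_s: float = 5.0) -> list:
    """Cut a series into contiguous non-overlapping windows.

    The series is segmented along its last axis into ``floor(T / (window_s *
    fs))`` windows of exactly ``window_s * fs`` samples; any trailing
    remainder is discarded.

    Raises
    ------
    ValueError
        If the series is shorter than one window, or a window would hold
        fewer than 2 samples.
    """
    series = np.asarray(series)
    w = int(round(window_s * fs))
    if w < 2:
        raise ValueError("window must contain at least 2 samples")
    n = series.shape[-1]
    if n < w:
        raise ValueError(f"series of {n} samples shorter than one {w}-sample window")
    k = n // w
    return [series[..., i * w:(i + 1) * w] for i in range(k)]
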