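"""Complex Morlet wavelet time–frequency decomposition.

Each channel's voltage trace is convolved with complex Morlet wavelets — a
complex exponential at the centre frequency tapered by a Gaussian whose
width is set by a constant number of cycles (7 by default, favouring
frequency precision over time precision, appropriate for minutes-long
resting-state epochs).  The kernel spans -1 to +1 s, centred at t = 0, so
its length is always odd.  The resulting complex coefficients yield
instantaneous power (|z|^2) and phase (arg z) per channel, frequency and
time point; samples within half a kernel length of either edge are masked
as convolution transients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .datatypes import Recording

__all__ = ["WaveletSpec", "AnalyticDecomposition", "make_morlet", "decompose",
           "band_average", "default_frequencies", "DEFAULT_ALPHA_BAND"]

#: Default analysis band: alpha, 8–12 Hz inclusive.
DEFAULT_ALPHA_BAND = (8.0, 12.0)


def default_frequencies(lo: float = 2.0, hi: float = 45.0, step: float = 1.0) -> np.ndarray:
    """Default frequency axis, 2–45 Hz in 1 Hz steps."""
    return np.arange(lo, hi + step / 2, step)


@dataclass
class WaveletSpec:
    """Morlet kernel parameters.

    sigma_t = n_cycles / (2 * pi * f) sets the Gaussian taper width; the
    support is fixed at [-support_s, +support_s] seconds.
    """

    f: float
    fs: float
    n_cycles: float = 7.0
    support_s: float = 1.0

    def __post_init__(self):
        if self.f >= self.fs / 2.0:
            raise ValueError(f"centre frequency {self.f} Hz >= Nyquist {self.fs / 2} Hz")
        if self.f <= 0:
            raise ValueError("centre frequency must be positive")
        if self.n_cycles < 3:
            raise ValueError("n_cycles must be >= 3")

    @property
    def sigma_t(self) -> float:
        return self.n_cycles / (2.0 * np.pi * self.f)


def make_morlet(spec: WaveletSpec) -> np.ndarray:
    """Complex Morlet kernel: exp(2*pi*i*f*t) * Gaussian(sigma_t), unit energy.

    The time axis runs from -support_s to +support_s inclusive at the
    sampling rate, giving an odd number of points centred at t = 0.
    """
    n_half = int(round(spec.support_s * spec.fs))
    t = np.arange(-n_half, n_half + 1) / spec.fs
    kernel = np.exp(2j * np.pi * spec.f * t) * np.exp(-(t**2) / (2.0 * spec.sigma_t**2))
    kernel /= np.sqrt(np.sum(np.abs(kernel) ** 2))
    return kernel


@dataclass
class AnalyticDecomposition:
    """Complex wavelet coefficients: channels x frequencies x time.

    ``valid`` masks out at least half a kernel length at each edge; all
    phase/power statistics downstream use only valid samples.
    """

    z: np.ndarray
    freqs: np.ndarray
    valid: np.ndarray  # boolean, time axis
    fs: float
    channels: list

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.z) ** 2

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.z)

    def band_indices(self, band) -> np.ndarray:
        lo, hi = band
        idx = np.flatnonzero((self.freqs >= lo) & (self.freqs <= hi))
        if idx.size == 0:
            raise ValueError(f"band {band} does not intersect the frequency axis "
                             f"[{self.freqs.min()}, {self.freqs.max()}] Hz")
        return idx


def decompose(rec: Recording, frequencies, n_cycles: float = 7.0,
              support_s: float = 1.0) -> AnalyticDecomposition:
    """Convolve every channel with a Morlet kernel at each frequency.

    Linear convolution, same-length output; edges masked by half a kernel
    length per side rather than padded, keeping phase estimates unbiased.
    """
    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if freqs.size == 0:
        raise ValueError("frequency list is empty")
    n_ch, n_t = rec.data.shape
    z = np.empty((n_ch, freqs.size, n_t), dtype=complex)
    half = 0
    for j, f in enumerate(freqs):
        kernel = make_morlet(WaveletSpec(f=f, fs=rec.fs, n_cycles=n_cycles,
                                         support_s=support_s))
        half = max(half, len(kernel) // 2)
        z[:, j, :] = fftconvolve(rec.data, kernel[np.newaxis, :], mode="same", axes=1)
    valid = np.zeros(n_t, dtype=bool)
    if n_t > 2 * half:
        valid[half:n_t - half] = True
    return AnalyticDecomposition(z=z, freqs=freqs, valid=valid, fs=rec.fs,
                                 channels=list(rec.channels))


def band_average(dec: AnalyticDecomposition, band=DEFAULT_ALPHA_BAND):
    """Per-channel power and phase series at the band's frequencies.

    Returns ``(power, phase)`` arrays of shape (channels, band_freqs,
    valid_time).  Connectivity downstream is computed per frequency and then
    averaged across the band's frequencies; averaging the complex signals
    first would change the phase statistics and is deliberately not done.
    """
    idx = dec.band_indices(band)
    zb = dec.z[:, idx, :][:, :, dec.valid]
    return np.abs(zb) ** 2, np.angle(zb)
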