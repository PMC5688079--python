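"""Pairwise functional-connectivity estimators.

Three estimators are provided, all computed from the same Morlet
decomposition and assembled into symmetric channel x channel matrices:

* **Windowed Spearman power correlation** — the power time series of two
  channels are cut into non-overlapping 5 s windows; within each window
  both series are rank-transformed and Pearson-correlated, and the
  per-window coefficients are averaged.  Ranks make the estimate robust to
  the heavy-tailed power distribution; windowing raises the signal-to-noise
  ratio of the average.

* **Intersite phase clustering (ISPC)** — the modulus of the mean unit
  vector of phase-angle differences, |n^-1 sum_t exp(i(phi_x(t) -
  phi_y(t)))|, also called R or the phase-locking value.  Sensitive to any
  phase clustering, including zero-lag (volume-conducted) coupling.

* **Phase-lag index (PLI)** — |n^-1 sum_t sgn(imag(S_xy(t)))| with S_xy =
  z_x * conj(z_y) the instantaneous cross-spectrum.  Only the sign of the
  imaginary cross-spectrum is averaged, so zero-lag coupling (imag = 0)
  contributes nothing: PLI is by construction insensitive to
  volume-conducted, zero-phase-lag correlation.

Connectivity is computed per frequency and averaged across the band's
frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .preprocessing import segment_windows
from .spectral import DEFAULT_ALPHA_BAND, AnalyticDecomposition

__all__ = [
    "MEASURES",
    "ConnectivityMatrix",
    "spearman_power",
    "fisher_z",
    "fisher_z_inverse",
    "ispc",
    "pli",
    "connectivity_matrix",
    "windowed_connectivity_matrices",
]

logger = logging.getLogger(__name__)

MEASURES = ("spearman_power", "ispc", "pli")


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel functional-connectivity matrix.

    The diagonal is fixed at 0 and excluded from every downstream
    statistic.  ``fisher_z`` records whether values are atanh-transformed
    (meaningful for the Spearman measure only).
    """

    values: np.ndarray
    measure: str
    band: tuple = DEFAULT_ALPHA_BAND
    channels: list = field(default_factory=list)
    n_windows: int = 0
    fisher_z: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        np.fill_diagonal(self.values, 0.0)
        if not self.channels:
            self.channels = [f"CH{i + 1:02d}" for i in range(n)]
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal values (the unique pair values)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def _rank(x: np.ndarray) -> np.ndarray:
    """Average-rank transform along the last axis (ties get mean rank)."""
    return rankdata(x, axis=-1)


def spearman_power(px, py, fs: float, window_s: float = 5.0,
                   min_valid_fraction: float = 0.5) -> float:
    """Windowed Spearman correlation of two power time series.

    Each 5 s window is rank-transformed and Pearson-correlated; the
    per-window coefficients are averaged arithmetically.  A window in which
    either series is constant has no defined correlation: it is skipped and
    logged, and if fewer than ``min_valid_fraction`` of windows survive the
    estimate is refused.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    if px.shape != py.shape:
        raise ValueError("power series must have equal length")
    wx = segment_windows(px, fs, window_s)
    wy = segment_windows(py, fs, window_s)
    vals = []
    skipped = 0
    for a, b in zip(wx, wy):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            skipped += 1
            continue
        ra, rb = _rank(a), _rank(b)
        vals.append(_pearson(ra, rb))
    if skipped:
        logger.warning("spearman_power: skipped %d constant window(s)", skipped)
    if len(vals) < max(1, int(np.ceil(min_valid_fraction * len(wx)))):
        raise ValueError(
            f"only {len(vals)}/{len(wx)} windows valid (< {min_valid_fraction:.0%})"
        )
    return float(np.mean(vals))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    return float(np.sum(a * b) / denom)


def fisher_z(r) -> np.ndarray:
    """Fisher-Z (atanh) transform of a correlation coefficient."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher-Z undefined at |r| = 1")
    return np.arctanh(r)


def fisher_z_inverse(z) -> np.ndarray:
    """Inverse Fisher-Z (tanh)."""
    return np.tanh(np.asarray(z, dtype=float))


def ispc(phix, phiy) -> float:
    """Intersite phase clustering of two phase-angle series, in [0, 1]."""
    phix = np.asarray(phix, dtype=float)
    phiy = np.asarray(phiy, dtype=float)
    if phix.shape != phiy.shape:
        raise ValueError("phase series must have equal length")
    if phix.size == 0:
        raise ValueError("empty phase series")
    return float(np.abs(np.mean(np.exp(1j * (phix - phiy)))))


def pli(zx, zy) -> float:
    """Phase-lag index from two complex analytic series, in [0, 1].

    Uses the instantaneous cross-spectrum S_xy(t) = z_x(t) * conj(z_y(t));
    sgn returns +1 / -1 / 0, so exact zero-lag samples contribute nothing.
    """
    zx = np.asarray(zx, dtype=complex)
    zy = np.asarray(zy, dtype=complex)
    if zx.shape != zy.shape:
        raise ValueError("analytic series must have equal length")
    if zx.size == 0:
        raise ValueError("empty analytic series")
    s = zx * np.conj(zy)
    return float(np.abs(np.mean(_sign_imag(s))))


def _sign_imag(s: np.ndarray) -> np.ndarray:
    """sgn of the imaginary cross-spectrum; rounding noise counts as 0.

    For exactly in-phase signals imag(S) is analytically 0 but floats leave
    ~1e-17 residue with arbitrary sign, so anything below a relative
    tolerance is treated as the zero-lag case."""
    im = np.imag(s)
    out = np.sign(im)
    out[np.abs(im) <= 1e-12 * np.abs(s)] = 0.0
    return out


def _ispc_matrix(phase_cft: np.ndarray) -> np.ndarray:
    """ISPC over all pairs; phase_cft is (channels, freqs, time)."""
    e = np.exp(1j * phase_cft)
    n_t = e.shape[-1]
    out = np.abs(np.einsum("cft,dft->cdf", e, np.conj(e))) / n_t
    return out.mean(axis=-1)


def _pli_matrix(z_cft: np.ndarray) -> np.ndarray:
    """PLI over all pairs; z_cft is (channels, freqs, time)."""
    n_ch, n_f, n_t = z_cft.shape
    out = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            s = _sign_imag(z_cft[i] * np.conj(z_cft[j]))
            v = np.abs(s.mean(axis=-1)).mean()
            out[i, j] = out[j, i] = v
    return out


def _spearman_matrix(power_cft: np.ndarray, fs: float, window_s: float) -> tuple:
    """Windowed Spearman power-correlation matrix, averaged over windows
    and band frequencies.  Returns (matrix, n_windows)."""
    mats = _spearman_window_matrices(power_cft, fs, window_s)
    return mats.mean(axis=0), mats.shape[0]


def _spearman_window_matrices(power_cft: np.ndarray, fs: float,
                              window_s: float) -> np.ndarray:
    n_ch, n_f, n_t = power_cft.shape
    w = int(round(window_s * fs))
    if n_t < w:
        raise ValueError("valid segment shorter than one window")
    k = n_t // w
    out = np.empty((k, n_ch, n_ch))
    for wi in range(k):
        seg = power_cft[:, :, wi * w:(wi + 1) * w]
        acc = np.zeros((n_ch, n_ch))
        for fi in range(n_f):
            ranks = _rank(seg[:, fi, :])
            acc += np.corrcoef(ranks)
        out[wi] = acc / n_f
        np.fill_diagonal(out[wi], 0.0)
    return out


def connectivity_matrix(dec: AnalyticDecomposition, measure: str,
                        band=DEFAULT_ALPHA_BAND, window_s: float = 5.0,
                        window_phase: bool = False,
                        apply_fisher_z: bool = False) -> ConnectivityMatrix:
    """Assemble the full channel x channel connectivity matrix.

    Power correlation is always windowed (5 s default).  The phase measures
    use the whole valid series by default; ``window_phase=True`` averages
    the per-window estimates instead.

    Parameters
    ----------
    dec : AnalyticDecomposition
        Wavelet coefficients (only valid-time samples are used).
    measure : {"spearman_power", "ispc", "pli"}
    band : (lo, hi)
        Frequency band in Hz; per-frequency estimates are averaged.
    apply_fisher_z : bool
        atanh-transform the matrix (Spearman only) — intended for
        averaging/statistics, never for thresholding or wiring cost.
    """
    if len(dec.channels) < 2:
        raise ValueError("connectivity requires at least 2 channels")
    idx = dec.band_indices(band)
    zb = dec.z[:, idx, :][:, :, dec.valid]
    n_windows = 0
    if measure == "spearman_power":
        F, n_windows = _spearman_matrix(np.abs(zb) ** 2, dec.fs, window_s)
        if apply_fisher_z:
            off = ~np.eye(F.shape[0], dtype=bool)
            F = F.copy()
            F[off] = fisher_z(F[off])
    elif measure == "ispc":
        if window_phase:
            mats = windowed_connectivity_matrices(dec, "ispc", band, window_s)
            F, n_windows = mats.mean(axis=0), mats.shape[0]
        else:
            F = _ispc_matrix(np.angle(zb))
    elif measure == "pli":
        if window_phase:
            mats = windowed_connectivity_matrices(dec, "pli", band, window_s)
            F, n_windows = mats.mean(axis=0), mats.shape[0]
        else:
            F = _pli_matrix(zb)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    F = (F + F.T) / 2.0
    np.fill_diagonal(F, 0.0)
    return ConnectivityMatrix(values=F, measure=measure, band=tuple(band),
                              channels=list(dec.channels), n_windows=n_windows,
                              fisher_z=apply_fisher_z and measure == "spearman_power")


def windowed_connectivity_matrices(dec: AnalyticDecomposition, measure: str,
                                   band=DEFAULT_ALPHA_BAND,
                                   window_s: float = 5.0) -> np.ndarray:
    """Per-window connectivity matrices, shape (n_windows, n, n).

    The window-level matrices are the resampling unit for the permutation
    statistics: condition labels are exchanged across windows and matrices
    re-averaged under the null.
    """
    idx = dec.band_indices(band)
    zb = dec.z[:, idx, :][:, :, dec.valid]
    n_ch = zb.shape[0]
    w = int(round(window_s * dec.fs))
    n_t = zb.shape[-1]
    if n_t < w:
        raise ValueError("valid segment shorter than one window")
    k = n_t // w
    if measure == "spearman_power":
        return _spearman_window_matrices(np.abs(zb) ** 2, dec.fs, window_s)
    out = np.empty((k, n_ch, n_ch))
    for wi in range(k):
        seg = zb[:, :, wi * w:(wi + 1) * w]
        if measure == "ispc":
            out[wi] = _ispc_matrix(np.angle(seg))
        elif measure == "pli":
            out[wi] = _pli_matrix(seg)
        else:
            raise ValueError(f"unknown measure {measure!r}")
        np.fill_diagonal(out[wi], 0.0)
    return out
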