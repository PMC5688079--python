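"""Synthetic two-condition iEEG cohort generator.

Real intracranial resting-state recordings of the kind this pipeline
analyses are clinical data and generally not shareable, so the package
ships a generator that emulates the statistical structure the analysis
assumes: alpha-band (~10 Hz) oscillations riding on 1/f^beta background
noise, with inter-channel coupling and alpha power that differ between the
eyes-closed (EC) and eyes-open (EO) conditions — stronger alpha coupling
and power with eyes closed, per the alpha-desynchronization hypothesis.

Generative model (common-driver mixing)
---------------------------------------
A single latent "driver" oscillator carries a slowly drifting phase and a
slowly varying log-normal amplitude envelope.  Each channel mixes the
driver with a private, independent oscillator:

    x_i(t) = A_i [ sqrt(g_i) a_d(t) cos(phi_d(t) + delta_i)
                 + sqrt(1-g_i) a_i(t) cos(phi_i(t)) ]  +  eta_i(t)

where ``g_i`` is the channel's coupling weight (taken from the coupling
matrix), ``delta_i`` a fixed per-channel phase lag (so coupling is not
zero-lag and the phase-lag index can see it), ``a``'s are smooth positive
envelopes, and ``eta_i`` is 1/f^beta noise.  Private phase drifts much
faster than the driver's, so uncoupled channels decohere.  This one
mechanism yields simultaneously tunable intersite phase clustering,
phase-lag index and windowed power correlation, all increasing with the
coupling weight.

The model is a statistical stand-in: it makes no attempt at biophysical
forward modelling or volume conduction (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .datatypes import (
    CONDITIONS,
    LATERALITIES,
    REGION_CODES,
    ElectrodeLayout,
    Recording,
    concat_layouts,
)

__all__ = [
    "SyntheticConfig",
    "LayoutSpec",
    "SubjectData",
    "make_layout",
    "simulate_recording",
    "make_cohort",
    "default_cohort_specs",
    "powerlaw_noise",
]

_SEED_MOD = 2**31


@dataclass
class LayoutSpec:
    """Declarative description of one electrode array.

    ``kind`` is ``grid`` (rows x cols subdural grid), ``strip`` (linear
    subdural strip) or ``depth`` (stereotactic linear array; geometrically a
    strip with its own orientation — only pairwise distances matter
    downstream).  ``n_contacts`` is an int for strip/depth or ``(rows,
    cols)`` for a grid.  Clinical arrays of this type typically use 10 mm
    inter-contact spacing, the default here.
    """

    kind: str = "strip"
    n_contacts: object = 6
    spacing_mm: float = 10.0
    origin: tuple = (0.0, 0.0, 0.0)
    orientation: tuple = (1.0, 0.0, 0.0)  # primary axis (strip/depth/grid rows)
    orientation2: tuple = (0.0, 1.0, 0.0)  # grid column axis
    region: str = "Grid"
    laterality: str = "B"
    label_prefix: str = ""

    def __post_init__(self):
        if self.kind not in ("grid", "strip", "depth"):
            raise ValueError(f"unknown layout kind {self.kind!r}")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if self.kind == "grid":
            rows, cols = self.n_contacts
            if rows < 1 or cols < 1:
                raise ValueError("grid must have positive rows and cols")
        elif int(self.n_contacts) < 1:
            raise ValueError("n_contacts must be positive")
        if self.region not in REGION_CODES:
            raise ValueError(f"unknown region code {self.region!r}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"unknown laterality {self.laterality!r}")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("orientation vector must be non-zero")
    return v / n


def make_layout(spec: LayoutSpec) -> ElectrodeLayout:
    """Generate contact coordinates for one array.

    Adjacent contacts are separated by exactly ``spec.spacing_mm`` along the
    array axes; labels are unique within the array.
    """
    origin = np.asarray(spec.origin, dtype=float)
    u = _unit(spec.orientation)
    prefix = spec.label_prefix or {"grid": "G", "strip": "S", "depth": "D"}[spec.kind]
    if spec.kind == "grid":
        rows, cols = spec.n_contacts
        v = _unit(spec.orientation2)
        if abs(np.dot(u, v)) > 1e-9:
            raise ValueError("grid orientation axes must be orthogonal")
        coords = np.array(
            [
                origin + spec.spacing_mm * (r * u + c * v)
                for r in range(rows)
                for c in range(cols)
            ]
        )
        labels = [f"{prefix}{r + 1:02d}-{c + 1:02d}" for r in range(rows) for c in range(cols)]
    else:
        n = int(spec.n_contacts)
        coords = np.array([origin + spec.spacing_mm * k * u for k in range(n)])
        labels = [f"{prefix}{k + 1:02d}" for k in range(n)]
    return ElectrodeLayout(
        labels=labels,
        coords=coords,
        regions=[spec.region] * len(labels),
        lateralities=[spec.laterality] * len(labels),
    )


def _as_coupling_matrix(value, n: int) -> np.ndarray:
    """Expand a scalar to a uniform off-diagonal matrix; validate a matrix."""
    if np.isscalar(value):
        c = float(value) * (np.ones((n, n)) - np.eye(n))
    else:
        c = np.asarray(value, dtype=float).copy()
    if c.shape != (n, n):
        raise ValueError(f"coupling must be {n}x{n}")
    if not np.allclose(c, c.T):
        raise ValueError("coupling matrix must be symmetric")
    if np.any(np.diag(c) != 0):
        raise ValueError("coupling diagonal must be zero")
    if np.any((c < 0) | (c > 1)):
        raise ValueError("coupling entries must lie in [0, 1]")
    return c


@dataclass
class SyntheticConfig:
    """Parameters of the two-condition generator.

    Defaults emulate the study conditions the pipeline targets: 3-minute
    recordings per condition at 500 Hz, a 10 Hz alpha oscillation over
    1/f noise, strong alpha coupling and full alpha power with eyes closed
    (coupling 0.8, power scale 1.0) versus weak coupling and attenuated
    alpha with eyes open (coupling 0.2, power scale 0.5).

    ``coupling`` maps condition -> scalar or symmetric zero-diagonal
    channel x channel matrix with entries in [0, 1].
    """

    n_channels: int = 8
    fs: float = 500.0
    duration_s: float = 180.0
    band_center: float = 10.0
    coupling: dict = field(default_factory=lambda: {"EC": 0.8, "EO": 0.2})
    alpha_power_scale: dict = field(default_factory=lambda: {"EC": 1.0, "EO": 0.5})
    noise_exponent: float = 1.0
    alpha_amp_uv: float = 20.0
    noise_rms_uv: float = 10.0
    seed: int = 0
    subject: str = "S01"

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")
        n_samp = self.duration_s * self.fs
        if n_samp <= 0 or abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("duration_s * fs must be a positive integer")
        for cond in CONDITIONS:
            if cond not in self.coupling or cond not in self.alpha_power_scale:
                raise ValueError(f"coupling/alpha_power_scale must cover {cond}")
            if self.alpha_power_scale[cond] < 0:
                raise ValueError("alpha_power_scale must be >= 0")

    def coupling_matrix(self, condition: str) -> np.ndarray:
        return _as_coupling_matrix(self.coupling[condition], self.n_channels)


def powerlaw_noise(rng, n_samples: int, fs: float, beta: float, rms: float = 1.0) -> np.ndarray:
    """1/f^beta noise via spectral shaping of white noise, scaled to ``rms``."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-beta / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n_samples)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _smooth_envelope(rng, n_samples: int, fs: float, timescale_s: float = 0.5,
                     log_sd: float = 0.4) -> np.ndarray:
    """Smooth positive amplitude envelope: exp of low-pass Gaussian noise."""
    s = gaussian_filter1d(rng.standard_normal(n_samples), sigma=timescale_s * fs,
                          mode="wrap")
    sd = s.std()
    if sd > 0:
        s = s * (log_sd / sd)
    return np.exp(s - log_sd**2 / 2.0)


def _drifting_phase(rng, n_samples: int, fs: float, f0: float,
                    drift_rad_per_sqrt_s: float) -> np.ndarray:
    """Oscillator phase 2*pi*f0*t plus a Wiener phase drift."""
    t = np.arange(n_samples) / fs
    steps = rng.standard_normal(n_samples) * (drift_rad_per_sqrt_s / np.sqrt(fs))
    return 2.0 * np.pi * f0 * t + np.cumsum(steps)


# Phase-drift rates (rad per sqrt-second).  The driver drifts slowly (alpha
# is not perfectly stationary); private oscillators drift fast enough that
# uncoupled channels decohere within a couple of seconds.
_DRIVER_DRIFT = 0.5
_PRIVATE_DRIFT = 6.0


def simulate_recording(config: SyntheticConfig, condition: str) -> Recording:
    """Simulate one condition's multichannel recording.

    Deterministic given ``config.seed`` (EC and EO draw from distinct child
    streams of the same seed, so the two conditions of one subject are
    reproducible independently).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    cond_idx = CONDITIONS.index(condition)
    n = config.n_channels
    n_samples = int(round(config.duration_s * config.fs))
    fs = config.fs

    coupling = config.coupling_matrix(condition)
    # Per-channel driver weight: how strongly the channel locks to the
    # common driver.  The max over partners makes a fully coupled pair
    # (c_ij = 1) lock completely, and an uncoupled channel (row of zeros)
    # fully private.
    g = coupling.max(axis=1) if n > 1 else np.zeros(1)

    # Channel-structure draws (lags) come from a per-subject stream so both
    # conditions share the same lags; signal noise comes from per-condition
    # streams.
    rng_struct = np.random.default_rng([config.seed, 977])
    rng = np.random.default_rng([config.seed, cond_idx])

    delta = rng_struct.uniform(0.15, 0.6, size=n) * rng_struct.choice([-1.0, 1.0], size=n)

    phi_d = _drifting_phase(rng, n_samples, fs, config.band_center, _DRIVER_DRIFT)
    a_d = _smooth_envelope(rng, n_samples, fs)

    amp = config.alpha_amp_uv * np.sqrt(config.alpha_power_scale[condition])
    data = np.empty((n, n_samples))
    for i in range(n):
        phi_i = _drifting_phase(rng, n_samples, fs, config.band_center, _PRIVATE_DRIFT)
        a_i = _smooth_envelope(rng, n_samples, fs)
        alpha = amp * (
            np.sqrt(g[i]) * a_d * np.cos(phi_d + delta[i])
            + np.sqrt(1.0 - g[i]) * a_i * np.cos(phi_i)
        )
        noise = powerlaw_noise(rng, n_samples, fs, config.noise_exponent,
                               rms=config.noise_rms_uv)
        data[i] = alpha + noise

    labels = [f"CH{i + 1:02d}" for i in range(n)]
    return Recording(subject=config.subject, condition=condition, fs=fs,
                     channels=labels, data=data)


@dataclass
class SubjectData:
    """One cohort member: a layout plus the EC and EO recordings."""

    subject: str
    layout: ElectrodeLayout
    rec_ec: Recording
    rec_eo: Recording

    def recording(self, condition: str) -> Recording:
        if condition == "EC":
            return self.rec_ec
        if condition == "EO":
            return self.rec_eo
        raise ValueError(f"unknown condition {condition!r}")


def default_cohort_specs(n_subjects: int):
    """Heterogeneous per-subject implant specs (grids, strips, depths).

    Cycles through implant archetypes seen in clinical cohorts of this
    type: bitemporal strips with hippocampal depths, frontal/interhemispheral
    strips, and a grid-plus-depth implant.  Every subject gets at least one
    depth array.
    """
    archetypes = [
        [
            LayoutSpec("strip", 6, 10.0, (0, 40, 0), (1, 0, 0), region="T", laterality="L", label_prefix="LT"),
            LayoutSpec("depth", 4, 10.0, (0, 0, -20), (0, 1, 0), region="H", laterality="L", label_prefix="LH"),
        ],
        [
            LayoutSpec("strip", 4, 10.0, (0, 60, 20), (1, 0, 0), region="F", laterality="R", label_prefix="RF"),
            LayoutSpec("strip", 4, 10.0, (0, 0, 50), (0, 1, 0), region="IH", laterality="B", label_prefix="IH"),
            LayoutSpec("depth", 4, 10.0, (10, 0, -20), (0, 1, 0), region="H", laterality="R", label_prefix="RH"),
        ],
        [
            LayoutSpec("grid", (2, 4), 10.0, (20, 20, 30), (1, 0, 0), (0, 1, 0), region="Grid", laterality="L", label_prefix="G"),
            LayoutSpec("depth", 4, 10.0, (-10, 0, -20), (0, 1, 0), region="D", laterality="L", label_prefix="DP"),
        ],
    ]
    return [archetypes[k % len(archetypes)] for k in range(n_subjects)]


def _child_seed(master_seed: int, subject_index: int) -> int:
    # Fixed arithmetic so cohorts are reproducible piecewise.
    return (int(master_seed) * 100003 + 1009 * subject_index + 7) % _SEED_MOD


def make_cohort(n_subjects: int, layout_specs=None, config: SyntheticConfig = None,
                seed: int = 0):
    """Simulate a cohort of subjects with heterogeneous implants.

    Parameters
    ----------
    n_subjects : int
        Number of subjects (the target study recorded 11).
    layout_specs : list of list of LayoutSpec, optional
        Per-subject implant descriptions; defaults to
        :func:`default_cohort_specs`.
    config : SyntheticConfig, optional
        Template; ``n_channels``, ``seed`` and ``subject`` are overridden
        per subject to match each layout.
    seed : int
        Master seed; expands to per-subject child seeds by fixed arithmetic.

    Returns
    -------
    list of SubjectData
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if layout_specs is None:
        layout_specs = default_cohort_specs(n_subjects)
    if len(layout_specs) != n_subjects:
        raise ValueError("need one spec list per subject")
    template = config if config is not None else SyntheticConfig()

    cohort = []
    for k in range(n_subjects):
        layout = concat_layouts([make_layout(s) for s in layout_specs[k]])
        n = len(layout)
        sub_id = f"S{k + 1:02d}"
        cfg = SyntheticConfig(
            n_channels=n,
            fs=template.fs,
            duration_s=template.duration_s,
            band_center=template.band_center,
            coupling={c: template.coupling[c] if np.isscalar(template.coupling[c])
                      else template.coupling[c] for c in CONDITIONS},
            alpha_power_scale=dict(template.alpha_power_scale),
            noise_exponent=template.noise_exponent,
            alpha_amp_uv=template.alpha_amp_uv,
            noise_rms_uv=template.noise_rms_uv,
            seed=_child_seed(seed, k),
            subject=sub_id,
        )
        rec_ec = simulate_recording(cfg, "EC")
        rec_eo = simulate_recording(cfg, "EO")
        # cohort recordings adopt the layout's labels
        rec_ec.channels = list(layout.labels)
        rec_eo.channels = list(layout.labels)
        cohort.append(SubjectData(subject=sub_id, layout=layout,
                                  rec_ec=rec_ec, rec_eo=rec_eo))
    return cohort
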