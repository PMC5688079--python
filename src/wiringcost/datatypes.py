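"""Core containers shared across the pipeline.

A :class:`Recording` holds one condition's multichannel voltage block; an
:class:`ElectrodeLayout` holds the 3-D contact coordinates from which the
inter-electrode distance matrix is derived.  Both are thin, validated
dataclasses — all numerics live in the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Resting-state condition labels: eyes closed / eyes open.
CONDITIONS = ("EC", "EO")

#: Electrode region categories: hippocampus, temporal, frontal,
#: interhemispheral, frontal polar, subdural grid, depth (non-hippocampal).
REGION_CODES = ("H", "T", "F", "IH", "FP", "Grid", "D")

LATERALITIES = ("L", "R", "B")


@dataclass
class Recording:
    """Multichannel iEEG signal block for one subject and one condition.

    Parameters
    ----------
    subject : str
        Subject identifier.
    condition : str
        ``"EC"`` (eyes closed) or ``"EO"`` (eyes open).
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Unique channel labels, one per row of ``data``.
    data : ndarray, shape (n_channels, n_samples)
        Voltage traces in microvolts (nominal).
    """

    subject: str
    condition: str
    fs: float
    channels: list
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or infinite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ElectrodeLayout:
    """Channel labels with 3-D coordinates (mm), region codes and laterality.

    The layout is the sole source of the Euclidean distance matrix used by
    the wiring-cost computation; coordinates are Cartesian millimetres.
    """

    labels: list
    coords: np.ndarray  # (n, 3) in mm
    regions: list = field(default_factory=list)
    lateralities: list = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n = len(self.labels)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be ({n}, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if not self.regions:
            self.regions = ["Grid"] * n
        if not self.lateralities:
            self.lateralities = ["B"] * n
        for r in self.regions:
            if r not in REGION_CODES:
                raise ValueError(f"unknown region code {r!r}")
        for lat in self.lateralities:
            if lat not in LATERALITIES:
                raise ValueError(f"unknown laterality {lat!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, labels) -> "ElectrodeLayout":
        """Layout restricted to ``labels``, in the given order."""
        idx = [self.labels.index(l) for l in labels]
        return ElectrodeLayout(
            labels=[self.labels[i] for i in idx],
            coords=self.coords[idx],
            regions=[self.regions[i] for i in idx],
            lateralities=[self.lateralities[i] for i in idx],
        )


def concat_layouts(layouts) -> ElectrodeLayout:
    """Stack several layouts (e.g. a grid plus depth strips) into one."""
    return ElectrodeLayout(
        labels=[l for lay in layouts for l in lay.labels],
        coords=np.vstack([lay.coords for lay in layouts]),
        regions=[r for lay in layouts for r in lay.regions],
        lateralities=[x for lay in layouts for x in lay.lateralities],
    )
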