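"""Plain-text table formats: electrode layouts, matrices, configs.

Layouts are tab-separated tables (label, x_mm, y_mm, z_mm, region,
laterality).  Square matrices (connectivity, distance, wiring cost) are
tab-separated with channel labels as header row and first column, written
with 12 significant digits so a write/read round-trip is lossless at that
precision; each matrix carries a JSON sidecar describing measure, band and
flags.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .datatypes import ElectrodeLayout
from .wiring import WiringCostMatrix

__all__ = ["write_layout", "read_layout", "write_matrix", "read_matrix",
           "write_connectivity", "read_connectivity", "load_config",
           "save_config"]

_LAYOUT_COLS = ["label", "x_mm", "y_mm", "z_mm", "region", "laterality"]
_FLOAT_FMT = "%.12g"


def write_layout(layout: ElectrodeLayout, path) -> str:
    df = pd.DataFrame({
        "label": layout.labels,
        "x_mm": layout.coords[:, 0],
        "y_mm": layout.coords[:, 1],
        "z_mm": layout.coords[:, 2],
        "region": layout.regions,
        "laterality": layout.lateralities,
    })
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return os.fspath(path)


def read_layout(path) -> ElectrodeLayout:
    """Read a tab-separated coordinate table; parse errors carry the line."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    missing = [c for c in _LAYOUT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    coords = np.empty((len(df), 3))
    for j, col in enumerate(("x_mm", "y_mm", "z_mm")):
        for i, v in enumerate(df[col]):
            try:
                coords[i, j] = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}, line {i + 2}: non-numeric {col} value {v!r}"
                ) from None
    return ElectrodeLayout(
        labels=df["label"].tolist(),
        coords=coords,
        regions=df["region"].tolist(),
        lateralities=df["laterality"].tolist(),
    )


def write_matrix(values: np.ndarray, labels, path, sidecar: dict = None) -> str:
    """Square labelled matrix as TSV (+ optional JSON sidecar)."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=list(labels),
                      columns=list(labels))
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="channel")
    if sidecar is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return os.fspath(path)


def read_matrix(path) -> tuple:
    """Read a labelled square matrix; returns (values, labels, sidecar)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    sidecar = None
    side_path = str(path) + ".json"
    if os.path.exists(side_path):
        with open(side_path) as fh:
            sidecar = json.load(fh)
    return df.to_numpy(dtype=float), list(df.columns), sidecar


def write_connectivity(F, path) -> str:
    sidecar = {"measure": F.measure, "band": list(F.band)}
    if isinstance(F, ConnectivityMatrix):
        sidecar.update({"n_windows": F.n_windows, "fisher_z": F.fisher_z,
                        "kind": "connectivity"})
    elif isinstance(F, WiringCostMatrix):
        sidecar.update({"units": "mm * connectivity", "kind": "wiring_cost"})
    return write_matrix(F.values, F.channels, path, sidecar=sidecar)


def read_connectivity(path):
    """Read a connectivity or wiring-cost matrix written by this package."""
    values, labels, sidecar = read_matrix(path)
    if sidecar is None:
        raise ValueError(f"{path}: missing JSON sidecar")
    band = tuple(sidecar.get("band", (8.0, 12.0)))
    if sidecar.get("kind") == "wiring_cost":
        return WiringCostMatrix(values=values, measure=sidecar["measure"],
                                band=band, channels=labels)
    return ConnectivityMatrix(values=values, measure=sidecar["measure"],
                              band=band, channels=labels,
                              n_windows=sidecar.get("n_windows", 0),
                              fisher_z=sidecar.get("fisher_z", False))


def load_config(path) -> dict:
    """YAML (or JSON, a YAML subset) key-value configuration."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> str:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return os.fspath(path)
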