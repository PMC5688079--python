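"""End-to-end pipeline: simulate/load -> filter -> decompose -> connectivity
-> wiring cost -> fixed-threshold metrics -> filtration -> permutation stats.

Every run is driven by a :class:`PipelineConfig` and writes a result tree::

    out_dir/
      manifest.json
      <subject>/layout.tsv
      <subject>/<condition>.edf                  (when simulating)
      <subject>/<condition>_<measure>.tsv        connectivity matrix
      <subject>/<condition>_<measure>_wiring.tsv wiring-cost matrix
      <subject>/<condition>_<measure>_metrics.json
      <subject>/<measure>_metric_difference.json (EC - EO, fixed threshold)
      <subject>/<measure>_filtration.tsv         long-format curves
      <subject>/<measure>_filtration_difference.tsv
      channel_tests.tsv                          per subject/region/channel
      curve_tests.tsv                            per subject/metric
      cohort_summary.tsv                         k/n significant counts

All randomness descends from ``config.seed``, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import connectivity_matrix, windowed_connectivity_matrices
from .datatypes import CONDITIONS
from .edf import read_edf, write_edf
from .filtration import FILTRATION_METRICS, filtrate, filtration_difference
from .graph_metrics import compute_metrics, condition_difference, threshold_fixed
from .io import read_layout, write_connectivity, write_layout
from .preprocessing import bandpass_notch
from .spectral import decompose
from .stats import (channel_condition_test, channel_summaries, cohort_summary,
                    curve_condition_test, region_table)
from .synthetic import SyntheticConfig, make_cohort
from .wiring import distance_matrix, wiring_cost

__all__ = ["PipelineConfig", "run_pipeline"]

_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``subjects`` (a list of ``{"layout": path, "EC": edf_path,
    "EO": edf_path}`` mappings) points at existing data, or
    ``n_subjects``/``duration_s``/``fs`` drive the synthetic generator.
    """

    out_dir: str = "results"
    subjects: list = None               # real-data ingest; None -> simulate
    n_subjects: int = 3
    fs: float = 250.0
    duration_s: float = 120.0
    seed: int = 0
    write_edf_files: bool = True
    # analysis settings
    band: tuple = (8.0, 12.0)
    band_step: float = 1.0
    n_cycles: float = 7.0
    measures: tuple = ("spearman_power", "ispc", "pli")
    window_s: float = 5.0
    low_hz: float = 0.5
    high_hz: float = 70.0
    notch_hz: float = 60.0
    filtration_rule: str = "sublevel"
    filtrate_on: str = "wiring_cost"    # or "connectivity"
    curve_measure: str = "spearman_power"
    n_perm_channel: int = 2000
    n_perm_curve: int = 199

    def band_frequencies(self) -> np.ndarray:
        lo, hi = self.band
        return np.arange(lo, hi + self.band_step / 2, self.band_step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["measures"] = list(self.measures)
        return d


def _load_subjects(config: PipelineConfig):
    from .synthetic import SubjectData

    subjects = []
    for entry in config.subjects:
        layout_path = entry["layout"]
        if not os.path.exists(layout_path):
            raise FileNotFoundError(f"layout file not found: {layout_path}")
        layout = read_layout(layout_path)
        recs = {}
        for cond in CONDITIONS:
            p = entry[cond]
            if not os.path.exists(p):
                raise FileNotFoundError(f"recording file not found: {p}")
            recs[cond] = read_edf(p, condition=cond,
                                  expected_labels=layout.labels)
        subjects.append(SubjectData(subject=recs["EC"].subject, layout=layout,
                                    rec_ec=recs["EC"], rec_eo=recs["EO"]))
    return subjects


def _simulate_subjects(config: PipelineConfig):
    template = SyntheticConfig(fs=config.fs, duration_s=config.duration_s)
    return make_cohort(config.n_subjects, config=template, seed=config.seed)


def _write_df(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a manifest dict (also written to disk).

    Any stage failure raises with a stage-tagged message; results written
    before the failure are left in place.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    stage = "setup"
    try:
        stage = "ingest"
        subjects = (_load_subjects(config) if config.subjects
                    else _simulate_subjects(config))

        freqs = config.band_frequencies()
        channel_rows, curve_rows = [], []
        for sub in subjects:
            sub_dir = os.path.join(out, sub.subject)
            os.makedirs(sub_dir, exist_ok=True)
            write_layout(sub.layout, os.path.join(sub_dir, "layout.tsv"))
            D = distance_matrix(sub.layout)

            stage = f"{sub.subject}:preprocess"
            decs, window_mats = {}, {}
            for cond in CONDITIONS:
                rec = sub.recording(cond)
                if config.subjects is None and config.write_edf_files:
                    write_edf(rec, os.path.join(sub_dir, f"{cond}.edf"))
                filt = bandpass_notch(rec, config.low_hz, config.high_hz,
                                      config.notch_hz)
                stage = f"{sub.subject}:{cond}:decompose"
                decs[cond] = decompose(filt, freqs, n_cycles=config.n_cycles)

            fixed_metrics = {m: {} for m in config.measures}
            for measure in config.measures:
                filts = {}
                for cond in CONDITIONS:
                    stage = f"{sub.subject}:{cond}:{measure}:connectivity"
                    F = connectivity_matrix(decs[cond], measure,
                                            band=config.band,
                                            window_s=config.window_s)
                    write_connectivity(
                        F, os.path.join(sub_dir, f"{cond}_{measure}.tsv"))
                    stage = f"{sub.subject}:{cond}:{measure}:wiring"
                    W = wiring_cost(D, F, labels=sub.layout.labels)
                    write_connectivity(
                        W, os.path.join(sub_dir, f"{cond}_{measure}_wiring.tsv"))
                    stage = f"{sub.subject}:{cond}:{measure}:network"
                    B = threshold_fixed(F)
                    mv = compute_metrics(B)
                    fixed_metrics[measure][cond] = mv
                    with open(os.path.join(
                            sub_dir, f"{cond}_{measure}_metrics.json"), "w") as fh:
                        json.dump({"subject": sub.subject, "condition": cond,
                                   "measure": measure, "band": list(config.band),
                                   "threshold": B.threshold, "metrics": mv},
                                  fh, indent=2, sort_keys=True)
                        fh.write("\n")
                    stage = f"{sub.subject}:{cond}:{measure}:filtration"
                    src = W if config.filtrate_on == "wiring_cost" else F
                    filts[cond] = filtrate(src, D=D, rule=config.filtration_rule)

                diff = condition_difference(fixed_metrics[measure]["EC"],
                                            fixed_metrics[measure]["EO"])
                with open(os.path.join(
                        sub_dir, f"{measure}_metric_difference.json"), "w") as fh:
                    json.dump({"subject": sub.subject, "measure": measure,
                               "difference_ec_minus_eo": diff},
                              fh, indent=2, sort_keys=True)
                    fh.write("\n")

                stage = f"{sub.subject}:{measure}:filtration_tables"
                long_rows = []
                for cond in CONDITIONS:
                    fr = filts[cond]
                    for name in FILTRATION_METRICS:
                        for tau, v in zip(fr.thresholds, fr.curves[name]):
                            long_rows.append((sub.subject, cond, measure, name,
                                              tau, v))
                _write_df(pd.DataFrame(long_rows, columns=[
                    "subject", "condition", "measure", "metric", "threshold",
                    "value"]), os.path.join(sub_dir, f"{measure}_filtration.tsv"))
                fd = filtration_difference(filts["EC"], filts["EO"])
                diff_rows = [(sub.subject, measure, name, tau, v)
                             for name in FILTRATION_METRICS
                             for tau, v in zip(fd["thresholds"], fd[name])]
                _write_df(pd.DataFrame(diff_rows, columns=[
                    "subject", "measure", "metric", "threshold",
                    "difference_ec_minus_eo"]),
                    os.path.join(sub_dir, f"{measure}_filtration_difference.tsv"))

                stage = f"{sub.subject}:{measure}:channel_test"
                wm = {cond: windowed_connectivity_matrices(
                    decs[cond], measure, band=config.band,
                    window_s=config.window_s) for cond in CONDITIONS}
                window_mats[measure] = wm
                df = channel_condition_test(
                    channel_summaries(wm["EC"]), channel_summaries(wm["EO"]),
                    channels=sub.layout.labels,
                    n_perm=config.n_perm_channel, seed=config.seed)
                rt = region_table(df, sub.layout, subject=sub.subject)
                rt.insert(1, "measure", measure)
                channel_rows.append(rt)

            stage = f"{sub.subject}:curve_test"
            wm = window_mats[config.curve_measure]
            ct = curve_condition_test(wm["EC"], wm["EO"], D,
                                      measure=config.curve_measure,
                                      rule=config.filtration_rule,
                                      n_perm=config.n_perm_curve,
                                      seed=config.seed, subject=sub.subject,
                                      filtrate_on=config.filtrate_on)
            curve_rows.append(ct)

        stage = "cohort_tables"
        channel_df = pd.concat(channel_rows, ignore_index=True)
        curve_df = pd.concat(curve_rows, ignore_index=True)
        _write_df(channel_df, os.path.join(out, "channel_tests.tsv"))
        _write_df(curve_df, os.path.join(out, "curve_tests.tsv"))
        summary = cohort_summary(curve_df, by="metric")
        _write_df(summary, os.path.join(out, "cohort_summary.tsv"))

        manifest = {
            "package": "wiringcost",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "subjects": [s.subject for s in subjects],
            "outputs": sorted(
                os.path.relpath(os.path.join(r, f), out)
                for r, _, files in os.walk(out) for f in files
                if f != "manifest.json"
            ),
        }
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage [{stage}]: {exc}") from exc
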