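"""European Data Format (EDF) export and import of recordings.

Writing uses a small built-in EDF encoder (16-bit samples, one 1-second
data record per second of signal, per-channel physical scaling); reading
goes through :func:`mne.io.read_raw_edf`.  Subject id and condition are
stored in the EDF local-patient-identification field so a written file
round-trips to an equivalent :class:`~wiringcost.datatypes.Recording`.
"""

from __future__ import annotations

import datetime as _dt
import os

import numpy as np

from .datatypes import CONDITIONS, Recording

__all__ = ["write_edf", "read_edf"]

_DIG_MAX = 32767
_DIG_MIN = -32768


def _pad(text: str, width: int) -> bytes:
    b = str(text).encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path) -> str:
    """Write a recording as an EDF file.

    The sampling rate must be a positive integer and the signal length a
    whole number of seconds (1 s data records are used).  Samples are
    scaled per channel to the full 16-bit digital range.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.data.shape
    if n_samp % fs != 0:
        raise ValueError("EDF export requires a whole number of seconds")
    n_records = n_samp // fs

    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    phys_min = -phys_max
    # digital <- physical scaling per channel
    gain = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.clip(
        np.round((rec.data - phys_min[:, None]) * gain[:, None] + _DIG_MIN),
        _DIG_MIN, _DIG_MAX,
    ).astype("<i2")

    t0 = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join([
        _pad("0", 8),
        _pad(f"{rec.subject} sex X birthdate {rec.condition}", 80),
        _pad(f"Startdate 01-JAN-2000 {rec.subject} investigator equipment", 80),
        _pad(t0.strftime("%d.%m.%y"), 8),
        _pad(t0.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(lbl, 16) for lbl in rec.channels],
        [_pad("iEEG", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{phys_min[i]:.5g}", 8) for i in range(n_ch)],
        [_pad(f"{phys_max[i]:.5g}", 8) for i in range(n_ch)],
        [_pad(str(_DIG_MIN), 8)] * n_ch,
        [_pad(str(_DIG_MAX), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(fs), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    sig_header = b"".join(b"".join(col) for col in fields)

    path = os.fspath(path)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())  # channel-by-channel within the record
    return path


def _parse_patient_field(path) -> tuple:
    with open(path, "rb") as fh:
        fh.seek(8)
        patient = fh.read(80).decode("ascii", errors="replace").split()
    subject = patient[0] if patient else "unknown"
    condition = next((tok for tok in patient if tok in CONDITIONS), None)
    return subject, condition


def read_edf(path, subject: str = None, condition: str = None,
             expected_labels=None) -> Recording:
    """Read an EDF file into a :class:`Recording` via mne.

    ``subject``/``condition`` override what is parsed from the EDF patient
    field.  When ``expected_labels`` is given, the file's channel labels
    must match it exactly (case-sensitively); offenders are listed in the
    error.
    """
    import mne

    raw = mne.io.read_raw_edf(os.fspath(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; recordings are in uV
    labels = list(raw.ch_names)
    if expected_labels is not None:
        missing = [l for l in expected_labels if l not in labels]
        extra = [l for l in labels if l not in list(expected_labels)]
        if missing or extra:
            raise ValueError(
                f"channel labels do not match layout: missing {missing}, "
                f"unexpected {extra}"
            )
    sub_parsed, cond_parsed = _parse_patient_field(path)
    return Recording(
        subject=subject or sub_parsed,
        condition=condition or cond_parsed or "EC",
        fs=float(raw.info["sfreq"]),
        channels=labels,
        data=data,
    )
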