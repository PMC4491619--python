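"""Recording I/O: EDF and a plain-matrix CSV format.

Two on-disk formats are supported:

* **EDF** (European Data Format). Reading goes through
  :func:`mne.io.read_raw_edf`; writing uses a minimal EDF writer (16-bit,
  one-second data records) implemented here, sufficient for the fixed-rate
  multichannel recordings this package produces.
* **matrix**: a CSV with one header row of channel labels and one column
  per channel (samples in uV), plus a YAML sidecar ``<stem>.yaml`` carrying
  ``sampling_rate`` and optional metadata. Human-readable and diff-able.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import yaml

from .errors import FormatError
from .montage import normalize_label
from .preprocess import Recording

_EDF_DIG_MAX = 32767
_EDF_DIG_MIN = -32768


def _edf_field(value: str, width: int) -> bytes:
    text = str(value)[:width]
    return text.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | os.PathLike) -> None:
    """Write a recording as EDF (16-bit, 1-s data records).

    The sampling rate must be a whole number of samples per second and the
    signal is truncated to whole seconds (EDF stores fixed-length records).
    Physical ranges are set per channel to the observed amplitude extremes,
    so quantization error is bounded by ``(max - min) / 2**16`` per channel.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise FormatError("recording shorter than one 1-s EDF record")
    ns = rec.n_channels
    data = rec.samples[:, : n_records * spr]

    phys_min = np.minimum(data.min(axis=1), -1.0)
    phys_max = np.maximum(data.max(axis=1), 1.0)
    # guard degenerate flat channels
    flat = phys_max - phys_min <= 0
    phys_max[flat] = phys_min[flat] + 1.0

    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    digital = np.round(
        (data - phys_min[:, None]) * scale[:, None] + _EDF_DIG_MIN
    ).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(rec.subject_id or "X X X X", 80),
            _edf_field("Startdate 01-JAN-2000 X X alphamark", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (1 + ns)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),
            _edf_field(str(ns), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(_edf_field(lb, 16) for lb in rec.channel_labels),
            b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(ns)),
            b"".join(_edf_field("uV", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_min),
            b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_max),
            b"".join(_edf_field(str(_EDF_DIG_MIN), 8) for _ in range(ns)),
            b"".join(_edf_field(str(_EDF_DIG_MAX), 8) for _ in range(ns)),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field(str(spr), 8) for _ in range(ns)),
            b"".join(_edf_field("", 32) for _ in range(ns)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # records: for each second, each signal's samples back to back
        blocks = digital.reshape(ns, n_records, spr)
        fh.write(np.ascontiguousarray(blocks.transpose(1, 0, 2)).tobytes())


def read_edf(path: str | os.PathLike) -> Recording:
    """Read an EDF file into a :class:`Recording` (uV, labels normalized)."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = [normalize_label(lb) for lb in raw.ch_names]
    data = raw.get_data() * 1e6  # mne returns volts
    return Recording(
        channel_labels=labels,
        sampling_rate=float(raw.info["sfreq"]),
        samples=data,
        reference="other",
        subject_id=Path(path).stem,
    )


def write_matrix(rec: Recording, path: str | os.PathLike) -> None:
    """Write the plain-matrix CSV plus its YAML sidecar."""
    path = Path(path)
    header = ",".join(rec.channel_labels)
    np.savetxt(path, rec.samples.T, delimiter=",", header=header, comments="")
    sidecar = {
        "sampling_rate": float(rec.sampling_rate),
        "units": "uV",
        "reference": rec.reference,
        "subject_id": rec.subject_id,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def read_matrix(path: str | os.PathLike) -> Recording:
    """Read the plain-matrix CSV format (requires the YAML sidecar)."""
    path = Path(path)
    sidecar_path = path.with_suffix(".yaml")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path.name} (sampling rate)")
    meta = yaml.safe_load(sidecar_path.read_text())
    if not isinstance(meta, dict) or "sampling_rate" not in meta:
        raise FormatError("sidecar must define sampling_rate")
    with open(path) as fh:
        header = fh.readline().strip()
    labels = [normalize_label(lb) for lb in header.split(",")]
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim == 1:
        data = data[:, None]
    return Recording(
        channel_labels=labels,
        sampling_rate=float(meta["sampling_rate"]),
        samples=data.T,
        reference=str(meta.get("reference", "other")),
        subject_id=str(meta.get("subject_id", path.stem)),
    )


def read_recording(path: str | os.PathLike, format: str | None = None) -> Recording:
    """Read a recording, dispatching on ``format`` or the file extension.

    Raises :class:`FormatError` for unreadable files or recordings with
    fewer than two channels (a single channel cannot be re-referenced or
    paired for coherence).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "matrix")
    if fmt == "edf":
        rec = read_edf(path)
    elif fmt == "matrix":
        rec = read_matrix(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if rec.n_channels < 2:
        raise FormatError(f"{path.name}: need >= 2 channels, got {rec.n_channels}")
    return rec
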