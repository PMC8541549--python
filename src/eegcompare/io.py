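"""Reading and writing recordings, events, montages and result tables.

Two on-disk formats for the signal itself:

* EDF (European Data Format, 16-bit) — written by a compact EDF writer in
  this module, read back through :func:`mne.io.read_raw_edf`. EDF stores
  integral data records, so signals are padded to a whole number of records
  on write and cropped back using the JSON sidecar on load.
* A delimited text matrix (header line = channel labels, then one row of
  samples per channel) — lossless round-trip.

Events travel as tab-separated text (onset_sample, onset_s, label), the
montage as tab-separated label/x/y, and recording metadata (sample rate,
system, subject, task, reference, true sample count) as a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, canonical_label
from .recording import EventList, Recording

logger = logging.getLogger(__name__)

_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767


# ---------------------------------------------------------------------------
# EDF writing

def _fit_ascii_float(v: float, width: int = 8) -> str:
    """Shortest decimal representation of v that fits the header field."""
    for prec in range(width, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= width:
            return s
    return f"{v:.0e}"[:width]


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path, physical_dimension: str = "uV") -> Path:
    """Write a recording as 16-bit EDF with 1 s data records.

    The last record is padded with the channel's final value; the true sample
    count is restored from the metadata sidecar by :func:`load_session`.
    """
    path = Path(path)
    if recording.n_samples == 0:
        raise ValueError("cannot write an empty recording")
    sr = recording.sample_rate
    if abs(sr - round(sr)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    spr = int(round(sr))  # samples per 1 s record
    n_rec = int(np.ceil(recording.n_samples / spr))
    n_ch = recording.n_channels

    data = recording.data
    pad = n_rec * spr - recording.n_samples
    if pad:
        data = np.concatenate([data, np.repeat(data[:, -1:], pad, axis=1)], axis=1)

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field(f"Startdate X {recording.system} {recording.task}", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_ch), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    labels = b"".join(_edf_field(l, 16) for l in recording.channel_labels)
    transducer = b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(n_ch))
    dim = b"".join(_edf_field(physical_dimension, 8) for _ in range(n_ch))
    phys_min = b"".join(_edf_field(_fit_ascii_float(v), 8) for v in pmin)
    phys_max = b"".join(_edf_field(_fit_ascii_float(v), 8) for v in pmax)
    dig_min = b"".join(_edf_field(_EDF_DIG_MIN, 8) for _ in range(n_ch))
    dig_max = b"".join(_edf_field(_EDF_DIG_MAX, 8) for _ in range(n_ch))
    prefilter = b"".join(_edf_field("", 80) for _ in range(n_ch))
    n_samp = b"".join(_edf_field(spr, 8) for _ in range(n_ch))
    reserved = b"".join(_edf_field("", 32) for _ in range(n_ch))

    # physical -> digital, clipping guards the odd rounding overshoot;
    # the scale uses the header's (ascii-rounded) range for consistency
    pmin_r = np.array([float(_fit_ascii_float(v)) for v in pmin])
    pmax_r = np.array([float(_fit_ascii_float(v)) for v in pmax])
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax_r - pmin_r)[:, None]
    digital = np.clip(
        np.rint((data - pmin_r[:, None]) * scale + _EDF_DIG_MIN),
        _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dim + phys_min + phys_max
                 + dig_min + dig_max + prefilter + n_samp + reserved)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    return path


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (data in μV, sample_rate, labels)."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns SI volts
    return data, float(raw.info["sfreq"]), [canonical_label(c) for c in raw.ch_names]


# ---------------------------------------------------------------------------
# delimited matrix

def write_delimited(recording: Recording, path) -> Path:
    """Lossless text matrix: header = labels, one row of samples per channel."""
    path = Path(path)
    if recording.n_samples == 0:
        raise ValueError("cannot write an empty recording")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(recording.channel_labels) + "\n")
        for row in recording.data:
            fh.write("\t".join(np.format_float_scientific(v, precision=17)
                               for v in row) + "\n")
    return path


def read_delimited(path) -> tuple[np.ndarray, list[str]]:
    with open(path, encoding="utf-8") as fh:
        labels = [canonical_label(l) for l in fh.readline().rstrip("\n").split("\t")]
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.shape[0] != len(labels):
        raise ValueError(f"{path}: {data.shape[0]} rows but {len(labels)} labels")
    return data, labels


# ---------------------------------------------------------------------------
# events / montage / metadata sidecars

def write_events(events: EventList, sample_rate: float, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "onset_sample": events.onsets,
        "onset_s": events.onsets / sample_rate,
        "label": events.labels,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_events(path) -> EventList:
    df = pd.read_csv(path, sep="\t")
    if not {"onset_sample", "label"} <= set(df.columns):
        raise ValueError(f"{path}: events file needs onset_sample and label columns")
    return EventList(df["onset_sample"].to_numpy(dtype=np.int64),
                     df["label"].astype(str).tolist())


def write_montage(montage: Montage, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "label": montage.labels,
        "x": montage.positions[:, 0],
        "y": montage.positions[:, 1],
    }).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_montage(path) -> Montage:
    df = pd.read_csv(path, sep="\t")
    return Montage(df["label"].astype(str).tolist(),
                   df[["x", "y"]].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# sessions

def session_basename(recording: Recording) -> str:
    return f"sub{recording.subject_id:02d}_{recording.system}_{recording.task}"


def write_session(recording: Recording, out_dir, format: str = "edf") -> dict[str, Path]:
    """Write one recording plus its sidecars; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = session_basename(recording)
    if format == "edf":
        data_path = write_edf(recording, out_dir / f"{base}.edf")
    elif format == "delimited":
        data_path = write_delimited(recording, out_dir / f"{base}.tsv")
    else:
        raise ValueError(f"unknown format {format!r}")
    paths = {
        "data": data_path,
        "events": write_events(recording.events, recording.sample_rate,
                               out_dir / f"{base}_events.tsv"),
        "meta": out_dir / f"{base}_meta.json",
    }
    meta = {
        "sample_rate": recording.sample_rate,
        "n_samples": recording.n_samples,
        "system": recording.system,
        "subject_id": recording.subject_id,
        "task": recording.task,
        "reference_label": recording.reference_label,
        "format": format,
    }
    paths["meta"].write_text(json.dumps(meta, indent=1))
    if recording.montage is not None:
        paths["montage"] = write_montage(recording.montage,
                                         out_dir / f"montage_{recording.system}.tsv")
    return paths


def load_session(data_path, montage_path=None) -> Recording:
    """Load a session written by :func:`write_session` back into a Recording.

    The JSON sidecar is authoritative for sample rate and true length; a
    sample-rate mismatch with the EDF header is an error, not a guess.
    """
    data_path = Path(data_path)
    base = data_path.with_suffix("")
    meta_path = base.parent / (base.name + "_meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar {meta_path} not found")
    meta = json.loads(meta_path.read_text())

    if data_path.suffix.lower() == ".edf":
        data, sr, labels = read_edf(data_path)
        if abs(sr - meta["sample_rate"]) > 1e-6:
            raise ValueError(
                f"sample-rate mismatch: EDF header {sr} Hz vs sidecar "
                f"{meta['sample_rate']} Hz")
        data = data[:, :meta["n_samples"]]
    else:
        data, labels = read_delimited(data_path)
        sr = meta["sample_rate"]

    events_path = base.parent / (base.name + "_events.tsv")
    events = read_events(events_path) if events_path.exists() else None

    montage = None
    if montage_path is not None:
        montage = read_montage(montage_path)
        missing = set(labels) - set(montage.labels)
        if missing:
            raise ValueError(f"channels missing from montage: {sorted(missing)}")
        montage = montage.subset(labels)

    return Recording(data=data, sample_rate=meta["sample_rate"],
                     channel_labels=labels, events=events,
                     system=meta["system"], subject_id=meta["subject_id"],
                     task=meta["task"], reference_label=meta["reference_label"],
                     montage=montage)


# ---------------------------------------------------------------------------
# result tables

def export_table(result, path) -> Path:
    """Write any tabular result as tab-separated text (>= 10 significant digits).

    Accepts a pandas DataFrame/Series or an object exposing ``to_frame()``.
    """
    path = Path(path)
    if isinstance(result, pd.Series):
        result = result.to_frame()
    if not isinstance(result, pd.DataFrame):
        to_frame = getattr(result, "to_frame", None)
        if to_frame is None:
            raise TypeError(f"cannot export {type(result).__name__} as a table")
        result = to_frame()
    path.parent.mkdir(parents=True, exist_ok=True)
    result.to_csv(path, sep="\t", index=bool(result.index.name
                                             or not result.index.equals(
                                                 pd.RangeIndex(len(result)))),
                  float_format="%.12g")
    return path
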