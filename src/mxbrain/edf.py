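"""EDF (European Data Format) output, EDF input via mne, and cohort manifests.

The writer emits plain 16-bit EDF with one-second data records, which is
all the synthetic cohorts need; reading goes through mne's EDF reader so
round-trips are checked against an independent implementation.  Quantisation
error is bounded by the per-channel physical range divided by 2^16.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .recording import Cohort, EegRecording


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: EegRecording, path: str | Path) -> None:
    """Write one recording as plain EDF (int16, 1 s data records).

    Requires an integer sampling rate; the recording is truncated to a
    whole number of seconds."""
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError(f"EDF writer needs an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_records = recording.n_samples // fs
    if n_records < 1:
        raise ParameterError("recording shorter than one EDF data record (1 s)")
    data = recording.data[:, : n_records * fs]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    phys_max = np.ceil(phys_max * 1.05)  # headroom so extremes are representable
    dig_max, dig_min = 32767, -32768
    scale = phys_max / dig_max
    digital = np.clip(np.round(data / scale[:, None]), dig_min, dig_max).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field(recording.subject_id or "X", 80),
            _field(f"Startdate 01-JAN-2000 {recording.group or 'X'}", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    labels = b"".join(_field(ch, 16) for ch in recording.channel_labels)
    transducer = b"".join(_field("AgAgCl electrode", 80) for _ in range(n_ch))
    dim = b"".join(_field("uV", 8) for _ in range(n_ch))
    pmin = b"".join(_field(f"{-m:.6g}"[:8], 8) for m in phys_max)
    pmax = b"".join(_field(f"{m:.6g}"[:8], 8) for m in phys_max)
    dmin = b"".join(_field(str(dig_min), 8) for _ in range(n_ch))
    dmax = b"".join(_field(str(dig_max), 8) for _ in range(n_ch))
    prefilter = b"".join(_field("", 80) for _ in range(n_ch))
    spr = b"".join(_field(str(fs), 8) for _ in range(n_ch))
    reserved = b"".join(_field("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dim + pmin + pmax + dmin + dmax
                 + prefilter + spr + reserved)
        for rec in range(n_records):
            block = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(struct.pack(f"<{n_ch * fs}h", *block.ravel()))


def read_edf(path: str | Path) -> EegRecording:
    """Read an EDF file through mne; voltages returned in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    data = raw.get_data() * 1e6  # mne stores volts
    return EegRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        subject_id=Path(path).stem,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path, seed: int | None = None) -> pd.DataFrame:
    """Write one EDF per subject plus a TSV manifest
    (subject_id, group, file, seed); returns the manifest frame."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(cohort):
        fname = f"{rec.subject_id or f'sub-{i:02d}'}.edf"
        write_edf(rec, out / fname)
        rows.append((rec.subject_id, rec.group, fname, f"{seed}:{i}" if seed is not None else ""))
    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "file", "seed"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_cohort(in_dir: str | Path) -> Cohort:
    """Load a cohort from a manifest directory written by :func:`write_cohort`."""
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.tsv", sep="\t")
    recs = []
    for _, row in manifest.iterrows():
        rec = read_edf(src / row["file"])
        rec.subject_id = row["subject_id"]
        rec.group = row["group"]
        recs.append(rec)
    return Cohort(recs)


def write_bundle(cohort: Cohort, path: str | Path) -> None:
    """Lossless binary bundle (npz) of a cohort, for tests and caching."""
    arrays = {f"data_{i}": r.data for i, r in enumerate(cohort)}
    np.savez_compressed(
        path,
        n=len(cohort),
        fs=cohort.recordings[0].fs if len(cohort) else 0.0,
        subject_ids=np.array(cohort.subject_ids),
        groups=np.array(cohort.groups),
        channel_labels=np.array(cohort.recordings[0].channel_labels if len(cohort) else []),
        **arrays,
    )


def read_bundle(path: str | Path) -> Cohort:
    with np.load(path, allow_pickle=False) as z:
        n = int(z["n"])
        fs = float(z["fs"])
        labels = tuple(str(c) for c in z["channel_labels"])
        recs = [
            EegRecording(
                data=z[f"data_{i}"],
                fs=fs,
                channel_labels=labels,
                subject_id=str(z["subject_ids"][i]),
                group=str(z["groups"][i]),
            )
            for i in range(n)
        ]
    return Cohort(recs)
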