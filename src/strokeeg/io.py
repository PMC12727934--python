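"""Cohort I/O: CSV + manifest directories and EDF files.

A cohort directory holds one numeric CSV per subject (header row =
channel labels, one row per sample) plus ``manifest.tsv`` with columns
``subject_id, group, fs, file``.  EDF (European Data Format, 16-bit) is
supported as an input format through mne; a minimal EDF writer is
included for exporting records and building round-trip fixtures.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import EEGRecord

MANIFEST_NAME = "manifest.tsv"
MIN_FS = 40.0  # 2 x the highest analysis band edge (beta hi = 20 Hz)


class CohortFormatError(ValueError):
    pass


def write_cohort(records: list[EEGRecord], out_dir) -> Path:
    """Write records as per-subject CSVs plus a manifest; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.subject_id}.csv"
        pd.DataFrame(rec.samples, columns=rec.channels).to_csv(
            out / fname, index=False
        )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "fs": rec.fs,
                "file": fname,
            }
        )
    pd.DataFrame(rows).to_csv(out / MANIFEST_NAME, sep="\t", index=False)
    return out


def _read_csv_record(path: Path, fs: float, row) -> EEGRecord:
    df = pd.read_csv(path)
    return EEGRecord(
        samples=df.to_numpy(dtype=float),
        fs=fs,
        channels=[str(c) for c in df.columns],
        group=str(row["group"]),
        subject_id=str(row["subject_id"]),
    )


def read_edf(path, group: str = "", subject_id: str = "", channels: list[str] | None = None) -> EEGRecord:
    """Read an EDF file into an :class:`EEGRecord`.

    ``channels`` selects channels by label (all by default).  Signal
    values are returned in microvolts.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels:
        missing = set(channels) - set(raw.ch_names)
        if missing:
            raise CohortFormatError(
                f"{path}: channels not found: {sorted(missing)}"
            )
        raw.pick(channels)
    data = raw.get_data() * 1e6  # mne returns volts; EDF writer uses uV
    return EEGRecord(
        samples=data.T,
        fs=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
        group=group,
        subject_id=subject_id or Path(path).stem,
    )


def load_cohort(input_dir, channels: list[str] | None = None) -> list[EEGRecord]:
    """Load a cohort from a manifest directory (CSV and/or EDF files)."""
    d = Path(input_dir)
    manifest = d / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {d}")
    mf = pd.read_csv(manifest, sep="\t")
    required = {"subject_id", "group", "fs", "file"}
    if not required <= set(mf.columns):
        raise CohortFormatError(
            f"manifest missing columns: {sorted(required - set(mf.columns))}"
        )
    records = []
    for _, row in mf.iterrows():
        path = d / str(row["file"])
        if not path.exists():
            raise FileNotFoundError(f"manifest references missing file: {path}")
        fs = float(row["fs"])
        if fs <= MIN_FS:
            raise CohortFormatError(
                f"{path}: fs={fs} Hz <= {MIN_FS} Hz (2 x highest band edge)"
            )
        if path.suffix.lower() == ".edf":
            rec = read_edf(
                path,
                group=str(row["group"]),
                subject_id=str(row["subject_id"]),
                channels=channels,
            )
            if abs(rec.fs - fs) > 1e-6:
                raise CohortFormatError(
                    f"{path}: EDF sampling rate {rec.fs} != manifest fs {fs}"
                )
        elif path.suffix.lower() in (".csv", ".tsv"):
            rec = _read_csv_record(path, fs, row)
            if channels:
                missing = set(channels) - set(rec.channels)
                if missing:
                    raise CohortFormatError(
                        f"{path}: channels not found: {sorted(missing)}"
                    )
                idx = [rec.channels.index(c) for c in channels]
                rec = EEGRecord(
                    samples=rec.samples[:, idx],
                    fs=rec.fs,
                    channels=list(channels),
                    group=rec.group,
                    subject_id=rec.subject_id,
                )
        else:
            raise CohortFormatError(f"unreadable format: {path.suffix!r} ({path})")
        records.append(rec)
    return records


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(record: EEGRecord, path) -> Path:
    """Write a record as a 16-bit EDF file (signal units: microvolts).

    A deliberately minimal writer: one-second data records, integer
    sampling rates only; trailing samples beyond the last whole second
    are dropped.  Amplitudes are linearly mapped onto the full 16-bit
    digital range per channel, so the round-trip error is bounded by the
    quantization step.
    """
    path = Path(path)
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise CohortFormatError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s data record
    n_records = record.n_samples // spr
    if n_records < 1:
        raise CohortFormatError("record shorter than one EDF data record (1 s)")
    nch = record.n_channels
    x = record.samples[: n_records * spr]

    phys_min = np.floor(x.min(axis=0))
    phys_max = np.ceil(x.max(axis=0))
    same = phys_max <= phys_min
    phys_max[same] = phys_min[same] + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((x - phys_min) * scale + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header_bytes = 256 + 256 * nch
    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field(record.subject_id or "X", 80))
        f.write(_edf_field(f"Startdate 01-JAN-2000 {record.group or 'X'}", 80))
        f.write(_edf_field("01.01.00", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(header_bytes, 8))
        f.write(_edf_field("", 44))
        f.write(_edf_field(n_records, 8))
        f.write(_edf_field(1, 8))  # data record duration, s
        f.write(_edf_field(nch, 4))
        for ch in record.channels:
            f.write(_edf_field(ch, 16))
        for _ in range(nch):
            f.write(_edf_field("", 80))  # transducer
        for _ in range(nch):
            f.write(_edf_field("uV", 8))
        for v in phys_min:
            f.write(_edf_field(_fmt8(v), 8))
        for v in phys_max:
            f.write(_edf_field(_fmt8(v), 8))
        for _ in range(nch):
            f.write(_edf_field(dig_min, 8))
        for _ in range(nch):
            f.write(_edf_field(dig_max, 8))
        for _ in range(nch):
            f.write(_edf_field("", 80))  # prefiltering
        for _ in range(nch):
            f.write(_edf_field(spr, 8))
        for _ in range(nch):
            f.write(_edf_field("", 32))
        for rec_i in range(n_records):
            chunk = digital[rec_i * spr : (rec_i + 1) * spr]  # (spr, nch)
            f.write(chunk.T.tobytes())
    return path


def _fmt8(v: float) -> str:
    """Format a physical min/max into <= 8 ascii chars."""
    s = f"{v:.8g}"
    if len(s) > 8:
        s = f"{v:.2e}"
    if len(s) > 8:
        raise CohortFormatError(f"cannot format {v} in 8 characters")
    return s
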