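"""Core in-memory containers: EEG records and per-subject metric tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_SAMPLES = 1000


@dataclass
class EEGRecord:
    """One subject's EEG signal.

    Attributes
    ----------
    samples : ndarray, shape (n_times, n_channels)
        Signal in arbitrary amplitude units. Single-channel signals may be
        passed as 1-D arrays and are reshaped to a column.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Channel labels, one per column.
    group : str
        Experimental group label.
    subject_id : str
    """

    samples: np.ndarray
    fs: float
    channels: list[str] = field(default_factory=lambda: ["ch0"])
    group: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValueError("samples must be 1-D or 2-D (time x channels)")
        if not np.isfinite(self.samples).all():
            raise ValueError(f"record {self.subject_id!r}: non-finite samples")
        if self.samples.shape[0] < MIN_SAMPLES:
            raise ValueError(
                f"record {self.subject_id!r}: need >= {MIN_SAMPLES} samples, "
                f"got {self.samples.shape[0]}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.samples.shape[1]:
            raise ValueError("channel labels do not match sample columns")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class MetricTable:
    """Per-subject x per-band values of one metric (RP, LZC or SampEn).

    ``data`` has columns ``subject_id, group, band, value`` with one row per
    subject x band.  RP values are fractions in [0, 1]; LZC and SampEn are
    unitless.
    """

    metric_name: str
    data: pd.DataFrame

    _COLUMNS = ("subject_id", "group", "band", "value")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"MetricTable missing columns: {sorted(missing)}")
        dup = self.data.duplicated(subset=["subject_id", "band"])
        if dup.any():
            raise ValueError("duplicate subject x band rows in MetricTable")
        if self.metric_name == "RP":
            vals = self.data["value"].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError("RP values must lie in [0, 1]")

    def group_values(self, band: str, group_order: list[str]) -> list[np.ndarray]:
        """Values per group for one band, in the requested group order."""
        sub = self.data[self.data["band"] == band]
        out = []
        for g in group_order:
            v = sub.loc[sub["group"] == g, "value"].to_numpy(dtype=float)
            if v.size == 0:
                raise ValueError(f"group {g!r} missing from table for band {band!r}")
            out.append(v)
        return out

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, metric_name: str | None = None) -> "MetricTable":
        df = pd.read_csv(path, sep="\t")
        name = metric_name or df.attrs.get("metric_name", "metric")
        return cls(metric_name=name, data=df)
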