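"""Band decomposition and relative power.

Relative power (RP) of a band is the proportion of spectral power inside
the band relative to the power in a total reference range::

    RP_band = P_band / P_total

with the total range defaulting to 1-20 Hz, the union of the four
analysis bands, so that the four band RPs partition unity.

Filtering is zero-phase (forward-backward 4th-order Butterworth); power
spectra are averaged modified periodograms (Welch, 2 s Hann windows,
50% overlap, per-window mean removal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import CANONICAL_BANDS, TOTAL_RANGE, BandDefinition
from .records import EEGRecord, MetricTable

#: Seconds discarded at each end of a filtered signal before epoching,
#: to drop filter edge transients.
EDGE_DISCARD_S = 1.0


class InvalidBandError(ValueError):
    """Band incompatible with the sampling rate (Nyquist violation)."""


class SignalLengthError(ValueError):
    """Signal too short for the requested operation."""


class UndefinedRPError(ValueError):
    """Relative power undefined (zero total power)."""


@dataclass
class SpectralEstimate:
    """A one-sided power spectral density estimate.

    ``psd`` has shape (n_freqs, n_channels) in units^2/Hz on the strictly
    increasing frequency grid ``freqs`` (Hz).
    """

    freqs: np.ndarray
    psd: np.ndarray
    fs: float
    method_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.psd.ndim == 1:
            self.psd = self.psd[:, None]
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.psd < -1e-15):
            raise ValueError("psd must be nonnegative")


def _check_band(band: BandDefinition, fs: float) -> None:
    if band.hi >= fs / 2:
        raise InvalidBandError(
            f"band {band.name!r} ({band.lo}-{band.hi} Hz) exceeds Nyquist "
            f"frequency {fs / 2} Hz"
        )


def bandpass(
    x: np.ndarray,
    fs: float,
    band: BandDefinition,
    order: int = 4,
    check_length: bool = True,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    Applies an ``order``-th order Butterworth band-pass forward and backward
    (``sosfiltfilt``), doubling the effective roll-off and cancelling phase
    distortion — important for the symbolic/embedding analyses downstream.
    The output has the same length as the input; the first and last
    :data:`EDGE_DISCARD_S` seconds contain edge transients and should be
    excluded by callers (the table builders do).

    Parameters
    ----------
    x : array, shape (n,) or (n, n_channels)
    fs : sampling rate, Hz
    band : the pass band; must lie below Nyquist
    """
    _check_band(band, fs)
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if check_length and n < 10 * fs / band.lo:
        raise SignalLengthError(
            f"signal too short for band {band.name!r}: {n} samples "
            f"< 10 cycles of {band.lo} Hz at fs={fs}"
        )
    sos = sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def estimate_psd(
    x: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> SpectralEstimate:
    """Welch averaged-periodogram PSD estimate.

    Each window is mean-detrended and Hann-tapered; the density
    normalization satisfies Parseval's relation, i.e. the integral of the
    PSD over [0, fs/2] approximates the signal variance.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    nperseg = int(round(window_s * fs))
    if n < 2 * nperseg:
        raise SignalLengthError(
            f"signal length {n} < 2 windows of {nperseg} samples"
        )
    noverlap = int(round(overlap * nperseg))
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        axis=0,
    )
    return SpectralEstimate(
        freqs=freqs,
        psd=psd,
        fs=fs,
        method_params={
            "method": "welch",
            "window": window,
            "window_s": window_s,
            "overlap": overlap,
        },
    )


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Trapezoid-integrated power in [lo, hi] per channel.

    Band edges off the frequency grid are handled by linear interpolation,
    which keeps the integral additive across adjacent bands sharing an edge.
    """
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError(
            f"band ({lo}, {hi}) outside estimated frequency span "
            f"({freqs[0]}, {freqs[-1]})"
        )
    inner = (freqs > lo) & (freqs < hi)
    f_grid = np.concatenate(([lo], freqs[inner], [hi]))
    p_lo = np.array([np.interp(lo, freqs, psd[:, c]) for c in range(psd.shape[1])])
    p_hi = np.array([np.interp(hi, freqs, psd[:, c]) for c in range(psd.shape[1])])
    p_grid = np.vstack([p_lo[None, :], psd[inner, :], p_hi[None, :]])
    return np.trapezoid(p_grid, f_grid, axis=0)


def relative_power(
    est: SpectralEstimate,
    band: BandDefinition,
    total_range: tuple[float, float] = TOTAL_RANGE,
) -> float:
    """Fraction of power in ``band`` relative to ``total_range``.

    Returns a value in [0, 1], averaged over channels.  Raises
    :class:`UndefinedRPError` when the total power is zero.
    """
    lo_t, hi_t = total_range
    if not (lo_t <= band.lo < band.hi <= hi_t):
        raise ValueError(
            f"band ({band.lo}, {band.hi}) not contained in total range {total_range}"
        )
    p_band = _band_power(est.freqs, est.psd, band.lo, band.hi)
    p_total = _band_power(est.freqs, est.psd, lo_t, hi_t)
    if np.any(p_total <= 0):
        raise UndefinedRPError("zero total power in the reference range")
    return float(np.mean(np.clip(p_band / p_total, 0.0, 1.0)))


def epoch_slices(n: int, fs: float, epoch_s: float, discard_s: float = 0.0):
    """Non-overlapping epoch slices after discarding ``discard_s`` at each end."""
    d = int(round(discard_s * fs))
    ep = int(round(epoch_s * fs))
    start, stop = d, n - d
    out = []
    while start + ep <= stop:
        out.append(slice(start, start + ep))
        start += ep
    return out


def rp_table(
    cohort: list[EEGRecord],
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
    total_range: tuple[float, float] = TOTAL_RANGE,
    epoch_s: float = 4.0,
    window_s: float = 2.0,
) -> MetricTable:
    """Per-subject band relative power averaged over epochs and channels.

    Each record is split into non-overlapping ``epoch_s``-second epochs; the
    PSD and the band RPs are computed per epoch and channel, then averaged.
    """
    rows = []
    for rec in cohort:
        try:
            slices = epoch_slices(rec.n_samples, rec.fs, epoch_s)
            if not slices:
                raise SignalLengthError(
                    f"record shorter than one {epoch_s} s epoch"
                )
            per_band: dict[str, list[float]] = {b.name: [] for b in bands}
            for sl in slices:
                est = estimate_psd(rec.samples[sl], rec.fs, window_s=window_s)
                for b in bands:
                    per_band[b.name].append(relative_power(est, b, total_range))
            for b in bands:
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "group": rec.group,
                        "band": b.name,
                        "value": float(np.mean(per_band[b.name])),
                    }
                )
        except Exception as e:
            raise type(e)(f"subject {rec.subject_id!r}: {e}") from e
    return MetricTable(metric_name="RP", data=pd.DataFrame(rows))
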