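"""Lempel-Ziv complexity and sample entropy of EEG epochs.

Lempel-Ziv complexity (LZC) counts the phrases c(n) of the exhaustive
production history of a symbol sequence (Lempel & Ziv 1976, via the
Kaspar-Schuster scan) and normalizes by the random-sequence asymptote
b(n) = n / log_alpha(n)::

    LZC = c(n) * log_alpha(n) / n

so i.i.d. uniform sequences approach 1 while periodic sequences fall
toward 0.  Real-valued epochs are symbolized before parsing; the default
rule is binary thresholding at the epoch median.

Sample entropy (SampEn) is the negative log conditional probability that
epochs matching for m consecutive points (Chebyshev distance <= r,
self-matches excluded) still match for m+1 points::

    SampEn(m, r, N) = -ln(A / B)

where B counts template pairs of length m within tolerance r and A the
same for length m+1.  Defaults are the field-standard m=2 and
r = 0.2 x epoch SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .bands import CANONICAL_BANDS, BandDefinition
from .records import EEGRecord, MetricTable
from .spectral import EDGE_DISCARD_S, bandpass, epoch_slices

MIN_LZC_LENGTH = 10
MIN_SAMPEN_LENGTH = 100

#: Minimum number of cycles of a band's lower edge required per epoch;
#: epochs are lengthened (doubled) for slow bands until satisfied.
MIN_CYCLES_PER_EPOCH = 8


class SymbolizationError(ValueError):
    pass


@dataclass
class LZCParams:
    """Symbolization and normalization choices for LZC.

    ``symbolization``: "median" (binary by epoch median) or "quantile"
    (alphabet_size symbols by epoch quantiles).
    """

    symbolization: str = "median"
    alphabet_size: int = 2

    def __post_init__(self) -> None:
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")
        if self.symbolization not in ("median", "quantile"):
            raise ValueError(f"unknown symbolization {self.symbolization!r}")
        if self.symbolization == "median" and self.alphabet_size != 2:
            raise ValueError("median symbolization implies alphabet_size=2")


@dataclass
class SampEnParams:
    """Embedding dimension and tolerance for sample entropy.

    ``r`` is expressed as a fraction of the epoch standard deviation; the
    distance between templates is the Chebyshev (max-coordinate) metric.
    """

    m: int = 2
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be > 0")


def symbolize(epoch: np.ndarray, params: LZCParams | None = None) -> np.ndarray:
    """Map a real-valued epoch to a symbol sequence (uint8 array).

    The default rule emits 1 where the sample exceeds the epoch median and
    0 otherwise; a constant epoch therefore yields an all-zeros sequence
    (callers may detect this degenerate case with :func:`is_degenerate`).
    The quantile rule generalizes this to ``alphabet_size`` symbols.
    """
    params = params or LZCParams()
    epoch = np.asarray(epoch, dtype=float)
    if epoch.size < 2:
        raise SymbolizationError("epoch must contain at least 2 samples")
    if not np.isfinite(epoch).all():
        raise SymbolizationError("epoch contains non-finite values")
    if params.symbolization == "median":
        return (epoch > np.median(epoch)).astype(np.uint8)
    # quantile rule: symbol k for values in the k-th quantile bin
    qs = np.quantile(epoch, np.linspace(0, 1, params.alphabet_size + 1)[1:-1])
    return np.searchsorted(qs, epoch, side="left").astype(np.uint8)


def is_degenerate(symbols: np.ndarray) -> bool:
    """True when the symbol sequence uses a single symbol (e.g. constant epoch)."""
    return bool(np.all(symbols == symbols[0]))


@njit(cache=True)
def _lz76_phrases(s: np.ndarray) -> int:
    """Kaspar-Schuster scan counting exhaustive-history phrases."""
    n = s.shape[0]
    c = 1
    i = 0  # start of history prefix candidate
    k = 1  # current extension length
    k_max = 1
    p = 1  # start of the current phrase
    while p + k <= n:
        if s[i + k - 1] == s[p + k - 1]:
            k += 1
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == p:  # no prefix reproduces the phrase: new phrase
                c += 1
                p += k_max
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    if k > 1 or (p < n and k_max > 1):
        c += 1
    return c


def lzc_raw(symbols) -> int:
    """Number of phrases c(n) in the exhaustive LZ76 parse of a sequence.

    Accepts a string over a finite alphabet or an integer array.
    """
    if isinstance(symbols, str):
        if len(symbols) == 0:
            raise ValueError("empty symbol sequence")
        arr = np.frombuffer(symbols.encode("latin-1"), dtype=np.uint8)
    else:
        arr = np.asarray(symbols, dtype=np.uint8)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("symbol sequence must be a non-empty 1-D sequence")
    if arr.size == 1:
        return 1
    return int(_lz76_phrases(arr))


def lzc_normalized(symbols, alphabet_size: int = 2) -> float:
    """Normalized Lempel-Ziv complexity c(n) * log_alpha(n) / n.

    The normalizer n / log_alpha(n) is the asymptotic phrase count of an
    i.i.d. uniform random sequence over an alphabet of size alpha, so random
    sequences score near 1 and strictly periodic ones near 0.
    """
    if isinstance(symbols, str):
        n = len(symbols)
    else:
        n = len(symbols)
    if n < MIN_LZC_LENGTH:
        raise ValueError(f"sequence too short for normalized LZC: {n} < {MIN_LZC_LENGTH}")
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be >= 2")
    c = lzc_raw(symbols)
    return c * math.log(n, alphabet_size) / n


@njit(cache=True)
def _sampen_counts(x: np.ndarray, m: int, r: float):
    """Template-pair match counts (B at length m, A at length m+1).

    Pairs are over distinct template start indices i != j in
    0..N-m-1 (counted once each), Chebyshev tolerance r; self-matches are
    excluded by construction.  Candidate pairs are enumerated through a
    sliding window over the first template coordinate in sorted order,
    which skips most non-matching pairs outright; the remaining
    coordinates are verified directly.
    """
    n = x.shape[0]
    n_templates = n - m  # templates of length m+1 start at 0..n-m-1
    order = np.argsort(x[:n_templates])
    b = 0
    a = 0
    lo = 0
    for pos in range(n_templates):
        i = order[pos]
        xi = x[i]
        while x[order[lo]] < xi - r:
            lo += 1
        for q in range(lo, pos):
            j = order[q]
            ok = True
            for k in range(1, m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return b, a


def sampen(
    epoch: np.ndarray, params: SampEnParams | None = None
) -> float:
    """Sample entropy -ln(A/B) of one epoch.

    ``params.r`` is scaled by the epoch standard deviation before matching.
    Returns ``nan`` when no template pairs match at either length (entropy
    undefined); a constant epoch returns 0 exactly (all pairs match at both
    lengths).
    """
    params = params or SampEnParams()
    x = np.ascontiguousarray(epoch, dtype=np.float64)
    n = x.shape[0]
    if n < MIN_SAMPEN_LENGTH:
        raise ValueError(
            f"epoch too short for SampEn: {n} < {MIN_SAMPEN_LENGTH}"
        )
    if not np.isfinite(x).all():
        raise ValueError("epoch contains non-finite values")
    r_abs = params.r * float(np.std(x))
    b, a = _sampen_counts(x, params.m, r_abs)
    if b == 0 or a == 0:
        return float("nan")
    return float(-math.log(a / b)) + 0.0  # +0.0 normalizes -0.0


def _epoch_s_for_band(band: BandDefinition, epoch_s: float) -> float:
    """Epoch length guaranteeing >= MIN_CYCLES_PER_EPOCH cycles of band.lo."""
    out = epoch_s
    while out * band.lo < MIN_CYCLES_PER_EPOCH:
        out *= 2
    return out


@dataclass
class ComplexityResult:
    """A metric table plus per-subject counts of excluded (undefined) epochs."""

    table: MetricTable
    excluded_epochs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["subject_id", "band", "n_excluded", "n_epochs"]
        )
    )


def complexity_tables(
    cohort: list[EEGRecord],
    metrics: tuple[str, ...] = ("LZC", "SampEn"),
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
    lzc_params: LZCParams | None = None,
    sampen_params: SampEnParams | None = None,
    epoch_s: float = 4.0,
) -> dict[str, ComplexityResult]:
    """Band-wise complexity per subject: filter, epoch, score, average.

    For each record and band the signal is zero-phase band-pass filtered,
    1 s edges are discarded, the remainder is cut into non-overlapping
    epochs (lengthened for slow bands so each holds at least
    :data:`MIN_CYCLES_PER_EPOCH` cycles of the band's lower edge), each
    requested metric is computed per epoch and channel, and epoch values
    are averaged.  Both metrics share one filtering pass.  Epochs with
    undefined sample entropy are excluded from the average and tallied
    per subject x band in the result.
    """
    for metric in metrics:
        if metric not in ("LZC", "SampEn"):
            raise ValueError(f"metric must be 'LZC' or 'SampEn', got {metric!r}")
    lzc_params = lzc_params or LZCParams()
    sampen_params = sampen_params or SampEnParams()

    rows: dict[str, list[dict]] = {m: [] for m in metrics}
    excluded: dict[str, list[dict]] = {m: [] for m in metrics}
    for rec in cohort:
        for band in bands:
            try:
                eps = _epoch_s_for_band(band, epoch_s)
                filt = bandpass(rec.samples, rec.fs, band)
                slices = epoch_slices(
                    rec.n_samples, rec.fs, eps, discard_s=EDGE_DISCARD_S
                )
                if not slices:
                    raise ValueError(f"record too short for one {eps} s epoch")
                vals: dict[str, list[float]] = {m: [] for m in metrics}
                n_excl = {m: 0 for m in metrics}
                for sl in slices:
                    for ch in range(filt.shape[1]):
                        ep = filt[sl, ch]
                        for metric in metrics:
                            if metric == "LZC":
                                sym = symbolize(ep, lzc_params)
                                v = lzc_normalized(sym, lzc_params.alphabet_size)
                            else:
                                v = sampen(ep, sampen_params)
                            if np.isnan(v):
                                n_excl[metric] += 1
                            else:
                                vals[metric].append(v)
                n_total = len(slices) * filt.shape[1]
                for metric in metrics:
                    if n_excl[metric]:
                        excluded[metric].append(
                            {
                                "subject_id": rec.subject_id,
                                "band": band.name,
                                "n_excluded": n_excl[metric],
                                "n_epochs": n_total,
                            }
                        )
                    rows[metric].append(
                        {
                            "subject_id": rec.subject_id,
                            "group": rec.group,
                            "band": band.name,
                            "value": float(np.mean(vals[metric]))
                            if vals[metric]
                            else float("nan"),
                        }
                    )
            except Exception as e:
                raise type(e)(
                    f"subject {rec.subject_id!r}, band {band.name!r}: {e}"
                ) from e
    out = {}
    for metric in metrics:
        excl_df = (
            pd.DataFrame(excluded[metric])
            if excluded[metric]
            else pd.DataFrame(columns=["subject_id", "band", "n_excluded", "n_epochs"])
        )
        out[metric] = ComplexityResult(
            table=MetricTable(metric_name=metric, data=pd.DataFrame(rows[metric])),
            excluded_epochs=excl_df,
        )
    return out


def complexity_table(
    cohort: list[EEGRecord],
    metric: str,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
    lzc_params: LZCParams | None = None,
    sampen_params: SampEnParams | None = None,
    epoch_s: float = 4.0,
) -> ComplexityResult:
    """Single-metric convenience wrapper around :func:`complexity_tables`."""
    return complexity_tables(
        cohort,
        metrics=(metric,),
        bands=bands,
        lzc_params=lzc_params,
        sampen_params=sampen_params,
        epoch_s=epoch_s,
    )[metric]
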