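"""Frequency-band definitions for quantitative EEG.

The canonical analysis bands are delta (1-4 Hz), theta (4-8 Hz),
alpha (8-13 Hz) and beta (13-20 Hz).  They tile the 1-20 Hz range,
so relative powers computed against that total range sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency interval in Hz.

    Parameters
    ----------
    name : str
        Band label, e.g. ``"delta"``.
    lo, hi : float
        Lower and upper band edges in Hz, ``0 < lo < hi``.
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


DELTA = BandDefinition("delta", 1.0, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 20.0)

#: Canonical band set in canonical order.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (DELTA, THETA, ALPHA, BETA)

#: Total frequency range for the relative-power denominator: the union
#: of the four canonical bands.
TOTAL_RANGE: tuple[float, float] = (1.0, 20.0)

_BY_NAME = {b.name: b for b in CANONICAL_BANDS}
_ALIASES = {"δ": "delta", "θ": "theta", "α": "alpha", "β": "beta"}


def get_band(name: str) -> BandDefinition:
    """Look up a canonical band by name (Greek letters accepted)."""
    key = _ALIASES.get(name, name).lower()
    try:
        return _BY_NAME[key]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; known: {sorted(_BY_NAME)}"
        ) from None


def band_order_index(name: str) -> int:
    """Position of a band in the canonical delta, theta, alpha, beta order."""
    return [b.name for b in CANONICAL_BANDS].index(_ALIASES.get(name, name).lower())
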