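"""Synthetic EEG cohorts with stroke-like group structure.

Generates seeded multi-subject surrogate EEG whose band-power and
complexity contrasts reproduce, in direction, the group differences seen
in rodent middle-cerebral-artery-occlusion (MCAO) studies of
transcranial direct-current stimulation (tDCS): elevated delta relative
power and depressed signal complexity after occlusion, partial
restoration under tDCS, and sham stimulation indistinguishable from the
untreated lesion group.

Signal model per subject (all components independently seeded)::

    x(t) = sqrt(1 - q) * osc(t) + sqrt(q) * pink(t) + noise_sd * w(t)

where ``osc`` is a unit-variance weighted sum of per-band carriers,
``pink`` unit-variance 1/f broadband noise, ``q`` the broadband variance
fraction and ``w`` white measurement noise.  Each band carrier mixes
band-limited Gaussian noise with a phase-random sinusoid near the band
center::

    carrier_b = sqrt(1 - rho) * bandnoise_b + sqrt(rho) * sin(2 pi f_b t + phi)

The rhythmicity ``rho`` controls how stereotyped (predictable) the
band's oscillation is, and is the simulator's handle on Lempel-Ziv
complexity and sample entropy: pathological over-synchronization is
modeled as high rhythmicity, so the lesioned profile scores low on both
complexity metrics in every band while leaving relative power (set by
the band weights and ``q``) essentially untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bands import CANONICAL_BANDS, BandDefinition, get_band
from .records import EEGRecord
from .spectral import InvalidBandError, bandpass

GROUP_NAMES = ("Control", "MCAO", "MCAO_tDCS", "MCAO_Sham")


@dataclass(frozen=True)
class GroupProfile:
    """Simulator parameters for one experimental group.

    Parameters
    ----------
    name : str
        Group label.
    band_weights : dict
        Band name -> nonnegative amplitude weight (unitless).  Weights set
        the relative variance each band carrier contributes to the
        oscillatory component.
    broadband_frac : float in [0, 1]
        Fraction of structured-signal variance carried by the 1/f
        broadband component.
    noise_sd : float
        White measurement-noise standard deviation, in units of the
        (unit-variance) structured signal.
    rhythmicity : float in [0, 1]
        Variance fraction of each band carrier contributed by a
        phase-random near-center sinusoid; 0 = band-limited noise only.
    """

    name: str
    band_weights: dict[str, float]
    broadband_frac: float
    noise_sd: float = 0.1
    rhythmicity: float = 0.0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.band_weights.values()):
            raise ValueError(f"profile {self.name!r}: negative band weight")
        if not 0 <= self.broadband_frac <= 1:
            raise ValueError(f"profile {self.name!r}: broadband_frac outside [0, 1]")
        if all(w == 0 for w in self.band_weights.values()) and self.broadband_frac == 0:
            raise ValueError(
                f"profile {self.name!r}: no signal content "
                "(all band weights zero and broadband_frac = 0)"
            )
        if not 0 <= self.rhythmicity <= 1:
            raise ValueError(f"profile {self.name!r}: rhythmicity outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError(f"profile {self.name!r}: negative noise_sd")


def default_profiles() -> list[GroupProfile]:
    """The calibrated group profiles (documented constants, frozen).

    Control has a broadly distributed spectrum, half-broadband, and weakly
    rhythmic oscillations.  MCAO concentrates power in delta, loses
    broadband richness, and becomes strongly rhythmic (hence low
    complexity).  MCAO_tDCS sits midway back toward Control on every
    parameter; MCAO_Sham equals MCAO.
    """
    control = GroupProfile(
        name="Control",
        band_weights={"delta": 1.0, "theta": 1.0, "alpha": 1.2, "beta": 0.8},
        broadband_frac=0.50,
        noise_sd=0.05,
        rhythmicity=0.10,
    )
    mcao = GroupProfile(
        name="MCAO",
        band_weights={"delta": 2.5, "theta": 0.6, "alpha": 0.5, "beta": 0.5},
        broadband_frac=0.015,
        noise_sd=0.05,
        rhythmicity=0.99,
    )
    tdcs = GroupProfile(
        name="MCAO_tDCS",
        band_weights={"delta": 1.75, "theta": 0.8, "alpha": 0.85, "beta": 0.65},
        broadband_frac=0.26,
        noise_sd=0.05,
        rhythmicity=0.54,
    )
    sham = replace(mcao, name="MCAO_Sham")
    return [control, mcao, tdcs, sham]


@dataclass
class SimConfig:
    """Cohort-level simulation settings.

    Defaults are desk-scale: 10 subjects per group, 60 s single-channel
    records at 250 Hz.
    """

    n_subjects_per_group: int = 10
    duration_s: float = 60.0
    fs: float = 250.0
    master_seed: int = 42
    profiles: list[GroupProfile] = field(default_factory=default_profiles)

    def __post_init__(self) -> None:
        hi = max(b.hi for b in CANONICAL_BANDS)
        if self.fs < 2 * hi:
            raise ValueError(f"fs={self.fs} < 2 x highest band edge ({2 * hi} Hz)")
        if self.duration_s * self.fs < 1000:
            raise ValueError("duration_s x fs must be >= 1000 samples")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate group names in profiles: {names}")


def _unit_variance(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate zero-variance component")
    return x / sd


def make_band_oscillation(
    band: BandDefinition, n: int, fs: float, seed
) -> np.ndarray:
    """Band-limited Gaussian noise with unit sample variance.

    White noise is zero-phase band-pass filtered to [band.lo, band.hi]
    and rescaled to sample variance 1.  Deterministic given ``seed`` (an
    int or a :class:`numpy.random.SeedSequence`).
    """
    if band.hi >= fs / 2:
        raise InvalidBandError(
            f"band ({band.lo}, {band.hi}) Hz outside Nyquist range for fs={fs}"
        )
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    return _unit_variance(bandpass(white, fs, band, check_length=False))


def make_pink_noise(n: int, fs: float, seed, f_ref: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f ("pink") noise via spectral shaping.

    White Gaussian noise is shaped in the frequency domain so its power
    density falls as 1/f above ``f_ref`` (flat below, zero at DC), then
    rescaled to sample variance 1.
    """
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, f_ref) / f_ref)
    amp[0] = 0.0
    return _unit_variance(np.fft.irfft(spec * amp, n))


def _band_carrier(
    band: BandDefinition, n: int, fs: float, rhythmicity: float, ss: np.random.SeedSequence
) -> np.ndarray:
    """Noise/sinusoid mixture carrier for one band, unit variance."""
    ss_noise, ss_tone = ss.spawn(2)
    parts = []
    if rhythmicity < 1.0:
        parts.append(
            np.sqrt(1.0 - rhythmicity) * make_band_oscillation(band, n, fs, ss_noise)
        )
    if rhythmicity > 0.0:
        rng = np.random.default_rng(ss_tone)
        # frequency in the middle third of the band; random phase
        f0 = band.lo + band.width * rng.uniform(1 / 3, 2 / 3)
        phi = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        tone = np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + phi)  # unit variance
        parts.append(np.sqrt(rhythmicity) * _unit_variance(tone))
    return _unit_variance(sum(parts))


def generate_subject(
    profile: GroupProfile,
    duration_s: float,
    fs: float,
    seed,
    subject_id: str | None = None,
    return_components: bool = False,
) -> EEGRecord:
    """Simulate one subject's single-channel record from a group profile.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; all
    randomness derives from it.  With ``return_components=True`` the
    scaled oscillatory, broadband and white-noise components are attached
    as a dict in ``record.components`` for variance bookkeeping.
    """
    n = int(round(duration_s * fs))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_bands, ss_pink, ss_white = ss.spawn(3)
    band_seeds = ss_bands.spawn(len(CANONICAL_BANDS))

    q = profile.broadband_frac
    osc = np.zeros(n)
    have_osc = False
    for band, bss in zip(CANONICAL_BANDS, band_seeds):
        w = profile.band_weights.get(band.name, 0.0)
        if w > 0:
            osc = osc + w * _band_carrier(band, n, fs, profile.rhythmicity, bss)
            have_osc = True
    osc_part = np.sqrt(1.0 - q) * _unit_variance(osc) if (have_osc and q < 1) else np.zeros(n)
    pink_part = np.sqrt(q) * make_pink_noise(n, fs, ss_pink) if q > 0 else np.zeros(n)
    white_part = (
        profile.noise_sd * np.random.default_rng(ss_white).standard_normal(n)
        if profile.noise_sd > 0
        else np.zeros(n)
    )
    x = osc_part + pink_part + white_part
    rec = EEGRecord(
        samples=x,
        fs=fs,
        channels=["ch0"],
        group=profile.name,
        subject_id=subject_id or f"{profile.name}_s0",
    )
    if return_components:
        rec.components = {  # type: ignore[attr-defined]
            "oscillatory": osc_part,
            "broadband": pink_part,
            "white": white_part,
        }
    return rec


def subject_seed(master_seed: int, group_index: int, subject_index: int) -> np.random.SeedSequence:
    """Deterministic per-subject seed derivation.

    Subject (g, s) of a cohort with master seed M gets
    ``SeedSequence(entropy=M, spawn_key=(g, s))`` — reproducible across
    platforms and independent across subjects.
    """
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(group_index, subject_index))


def generate_cohort(config: SimConfig) -> list[EEGRecord]:
    """Simulate the full cohort: n_subjects_per_group records per profile."""
    records = []
    for g, profile in enumerate(config.profiles):
        for s in range(config.n_subjects_per_group):
            records.append(
                generate_subject(
                    profile,
                    config.duration_s,
                    config.fs,
                    subject_seed(config.master_seed, g, s),
                    subject_id=f"{profile.name}_{s:02d}",
                )
            )
    return records
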