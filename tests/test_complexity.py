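"""Lempel-Ziv complexity and sample entropy against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import lz76_phrases_bruteforce, sampen_bruteforce
from strokeeg.complexity import (
    LZCParams,
    SampEnParams,
    complexity_table,
    complexity_tables,
    is_degenerate,
    lzc_normalized,
    lzc_raw,
    sampen,
    symbolize,
)


class TestSymbolize:
    def test_median_rule(self):
        assert symbolize([1, 5, 2, 7]).tolist() == [0, 1, 0, 1]

    def test_constant_epoch_is_all_zero_and_degenerate(self):
        sym = symbolize(np.ones(50))
        assert sym.tolist() == [0] * 50
        assert is_degenerate(sym)
        assert not is_degenerate(symbolize([1, 5, 2, 7]))

    def test_tertile_rule(self):
        sym = symbolize(np.arange(1, 10), LZCParams(symbolization="quantile", alphabet_size=3))
        assert sym.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_too_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            symbolize([1.0])


class TestLZC:
    @pytest.mark.parametrize(
        "s,expected",
        [("0001101001000101", 6), ("0", 1), ("0000000000", 2)],
    )
    def test_known_phrase_counts(self, s, expected):
        assert lzc_raw(s) == expected
        assert lz76_phrases_bruteforce(s) == expected

    def test_exhaustive_oracle_agreement_short_binary(self):
        for n in range(1, 10):
            for bits in itertools.product("01", repeat=n):
                s = "".join(bits)
                assert lzc_raw(s) == lz76_phrases_bruteforce(s)

    @given(st.text(alphabet="012", min_size=1, max_size=200))
    def test_oracle_agreement_random_ternary(self, s):
        assert lzc_raw(s) == lz76_phrases_bruteforce(s)

    def test_accepts_integer_arrays(self):
        arr = np.array([0, 0, 0, 1, 1, 0, 1, 0, 0, 1, 0, 0, 0, 1, 0, 1], dtype=np.uint8)
        assert lzc_raw(arr) == 6

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            lzc_raw("")

    def test_normalized_random_near_one(self, rng):
        s = rng.integers(0, 2, 10000).astype(np.uint8)
        assert 0.85 <= lzc_normalized(s) <= 1.15

    def test_normalized_periodic_near_zero(self):
        assert lzc_normalized("01" * 5000) <= 0.02

    def test_normalized_decreases_with_length_for_periodic(self):
        vals = [lzc_normalized("01" * k) for k in (10, 100, 1000)]
        assert vals[0] > vals[1] > vals[2]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lzc_normalized("01010")

    def test_amplitude_invariance_through_symbolization(self, rng):
        x = rng.standard_normal(500)
        a = lzc_normalized(symbolize(x))
        b = lzc_normalized(symbolize(3.7 * x + 11.0))
        assert a == b


class TestSampEn:
    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            x = rng.standard_normal(150)
            assert sampen(x, SampEnParams(m=2, r=0.2)) == pytest.approx(
                sampen_bruteforce(x, 2, 0.2), abs=1e-12
            )

    def test_matches_oracle_on_correlated_signal(self, rng):
        x = np.cumsum(rng.standard_normal(200))
        assert sampen(x) == pytest.approx(sampen_bruteforce(x), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_oracle_agreement_property(self, seed):
        x = np.random.default_rng(seed).standard_normal(120)
        assert sampen(x) == pytest.approx(sampen_bruteforce(x), abs=1e-12)

    def test_constant_epoch_zero(self):
        assert sampen(np.full(200, 3.3)) == 0.0

    def test_iid_gaussian_analytic_value(self):
        # For i.i.d. data, A/B -> one-coordinate match probability
        # 2*Phi(r/sqrt(2)) - 1; with r = 0.2 SD this gives about 2.19.
        from scipy.stats import norm

        expected = -math.log(2 * norm.cdf(0.2 / math.sqrt(2)) - 1)
        vals = [
            sampen(np.random.default_rng(s).standard_normal(3000))
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(expected, abs=0.1)

    def test_monotone_nonincreasing_in_r(self, rng):
        x = rng.standard_normal(300)
        vals = [sampen(x, SampEnParams(m=2, r=r)) for r in (0.1, 0.2, 0.4, 0.8)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(250)
        assert sampen(x) == pytest.approx(sampen(5.0 * x + 2.0), rel=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sampen(np.arange(50.0))

    def test_undefined_when_no_matches(self):
        # a ramp with tolerance below the step size: no off-diagonal matches
        x = np.arange(100.0)
        assert math.isnan(sampen(x, SampEnParams(m=2, r=0.005)))


class TestComplexityTable:
    def test_single_subject_single_band(self, small_cohort):
        from strokeeg.bands import ALPHA

        res = complexity_table(small_cohort[:1], "LZC", bands=(ALPHA,))
        assert len(res.table.data) == 1
        assert res.table.data.iloc[0]["band"] == "alpha"

    def test_tables_share_filtering_and_match_single_calls(self, small_cohort):
        from strokeeg.bands import THETA

        both = complexity_tables(small_cohort[:2], bands=(THETA,))
        solo = complexity_table(small_cohort[:2], "SampEn", bands=(THETA,))
        assert np.allclose(
            both["SampEn"].table.data["value"], solo.table.data["value"]
        )

    def test_noise_more_complex_than_rhythm(self, rng):
        """White noise scores above near-pure sinusoids in every band.

        The rhythmic signal carries one tone per analysis band (2.5, 6,
        10.5 and 16 Hz) plus 5% noise, so each band-filtered version is
        tone-dominated; band-filtered white noise should always score
        higher on both complexity metrics.
        """
        from strokeeg.bands import CANONICAL_BANDS
        from strokeeg.records import EEGRecord

        fs, n = 250.0, 15000
        t = np.arange(n) / fs
        noise = EEGRecord(rng.standard_normal(n), fs, subject_id="noise")
        tones = sum(np.sin(2 * np.pi * f * t + p) for f, p in
                    [(2.5, 0.0), (6.0, 1.0), (10.5, 2.0), (16.0, 3.0)])
        tone = EEGRecord(
            tones + 0.05 * rng.standard_normal(n), fs, subject_id="tone"
        )
        for metric in ("LZC", "SampEn"):
            res = complexity_table([noise, tone], metric)
            piv = res.table.data.pivot(index="band", columns="subject_id", values="value")
            for band in [b.name for b in CANONICAL_BANDS]:
                assert piv.loc[band, "noise"] > piv.loc[band, "tone"]

    def test_unknown_metric_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            complexity_table(small_cohort[:1], "PermEn")

    def test_error_names_subject_and_band(self):
        from strokeeg.records import EEGRecord

        rec = EEGRecord(np.random.default_rng(0).standard_normal(1200), 250.0, subject_id="s7")
        with pytest.raises(ValueError, match="s7.*delta"):
            complexity_table([rec], "LZC")
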