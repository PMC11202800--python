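"""Empirical mode decomposition: extrema, envelopes, sifting, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecpdh.emd import (
    EMDConfig,
    NotEnoughExtrema,
    count_zero_crossings,
    envelope_mean,
    extract_emd_block,
    find_extrema,
    imf_stats,
    is_imf,
    sift,
)
from ecpdh.errors import InvalidInputError

from _emd_oracle import naive_emd
from conftest import make_record


class TestExtrema:
    @pytest.mark.parametrize(
        "signal,maxima,minima",
        [
            ([0, 1, 0, 1, 0], [1, 3], [2]),
            ([1, 2, 3, 4], [], []),
            ([0, 2, 2, 0], [1], []),          # plateau midpoint (floor)
            ([0, 2, 2, 2, 0], [2], []),
            ([3, 1, 1, 3], [], [1]),
            ([0, 1], [], []),                 # too short for an interior
        ],
    )
    def test_examples(self, signal, maxima, minima):
        ma, mi = find_extrema(np.asarray(signal, dtype=float))
        assert ma.tolist() == maxima
        assert mi.tolist() == minima

    def test_matches_brute_force_on_random_signals(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 40))
            x = np.round(x, 1)  # provoke plateaus
            ma, mi = find_extrema(x)
            for i in ma:
                left = x[:i][x[:i] != x[i]]
                right = x[i + 1:][x[i + 1:] != x[i]]
                assert left.size and right.size
                assert x[i] > left[-1] and x[i] > right[0]
            for i in mi:
                left = x[:i][x[:i] != x[i]]
                right = x[i + 1:][x[i + 1:] != x[i]]
                assert x[i] < left[-1] and x[i] < right[0]


class TestEnvelope:
    def test_antisymmetric_signal_has_near_zero_mean(self):
        t = np.arange(64.)
        x = np.sin(2 * np.pi * 2 * t / 64)
        m = envelope_mean(x)
        assert np.max(np.abs(m)) < 0.05

    def test_constant_plus_sine_recovers_constant(self):
        t = np.arange(128.)
        x = 3.0 + np.sin(2 * np.pi * 8 * t / 128)
        m = envelope_mean(x)
        assert np.max(np.abs(m - 3.0)) < 0.05

    def test_minimal_extrema_still_defined(self):
        # exactly 2 interior maxima and 2 minima
        x = np.array([0, 2, -0.5, 1.5, -2, 1.8, 0.1], dtype=float)
        m = envelope_mean(x)
        assert m.shape == x.shape and np.all(np.isfinite(m))

    def test_no_extrema_raises(self):
        with pytest.raises(NotEnoughExtrema):
            envelope_mean(np.arange(10.))


class TestIsImf:
    def test_full_sine_period_is_imf(self):
        t = np.arange(32.)
        assert is_imf(np.sin(2 * np.pi * t / 32))

    def test_monotone_ramp_is_not(self):
        assert not is_imf(np.arange(8.))

    def test_offset_sine_fails_envelope_condition(self):
        t = np.arange(32.)
        x = np.sin(2 * np.pi * t / 32) + 5.0
        # the count condition alone would pass; the envelope mean (~5)
        # exceeds the tolerance times the unit amplitude
        m = envelope_mean(x)
        assert np.max(np.abs(m)) > 1.0
        assert not is_imf(x)

    def test_zero_crossing_counter_ignores_exact_zeros(self):
        assert count_zero_crossings(np.array([1.0, 0.0, -1.0, 1.0])) == 2


class TestSift:
    def test_monotone_signal_yields_no_imfs(self):
        x = np.linspace(0, 5, 16)
        out = sift(x)
        assert out.imfs == []
        np.testing.assert_array_equal(out.residual, x)

    def test_too_short_signal_passes_through(self):
        x = np.array([1.0, 3.0, 2.0])
        out = sift(x)
        assert out.imfs == [] and np.array_equal(out.residual, x)

    def test_first_imf_captures_fast_component(self):
        t = np.arange(64.)
        fast = np.sin(2 * np.pi * 6 * t / 64)
        out = sift(fast + 0.05 * t)
        assert len(out.imfs) >= 1
        assert np.corrcoef(out.imfs[0], fast)[0, 1] > 0.9

    def test_deterministic_bitwise(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=32)
        a, b = sift(x), sift(x)
        assert len(a.imfs) == len(b.imfs)
        for u, v in zip(a.imfs, b.imfs):
            np.testing.assert_array_equal(u, v)

    @given(
        arrays(
            np.float64,
            st.integers(6, 48),
            elements=st.floats(-10, 10, allow_nan=False),
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_reconstruction_is_exact(self, x):
        out = sift(x)
        rec = out.reconstruct()
        scale = max(np.ptp(x), 1e-12)
        assert np.max(np.abs(rec - x)) <= 1e-9 * scale

    def test_every_returned_imf_is_valid(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(200):
            x = rng.normal(size=int(rng.integers(6, 65)))
            for imf in sift(x).imfs:
                assert is_imf(imf)
                checked += 1
        assert checked > 200

    def test_respects_max_imfs(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=64)
        out = sift(x, EMDConfig(max_imfs=1))
        assert len(out.imfs) <= 1


class TestOracleAgreement:
    def test_loose_agreement_with_independent_sifter(self):
        """Two EMD variants with different boundary policies should agree
        on the dominant oscillation of smooth two-tone signals."""
        rng = np.random.default_rng(11)
        corrs, count_diffs = [], []
        for _ in range(25):
            t = np.arange(64.)
            x = (
                rng.uniform(0.5, 2) * np.sin(2 * np.pi * rng.integers(4, 10) * t / 64 + rng.uniform(0, 6))
                + rng.uniform(0.5, 2) * np.sin(2 * np.pi * t / 64 + rng.uniform(0, 6))
                + 0.1 * rng.normal(size=64)
            )
            ours = sift(x)
            theirs, _ = naive_emd(x)
            count_diffs.append(abs(len(ours.imfs) - len(theirs)))
            if ours.imfs and theirs:
                corrs.append(abs(np.corrcoef(ours.imfs[0], theirs[0])[0, 1]))
        assert len(corrs) >= 20
        assert np.median(corrs) >= 0.9
        assert np.median(count_diffs) <= 1


class TestStats:
    def test_hand_computed_example(self):
        s = imf_stats(np.array([1.0, 2.0, 3.0]), lag=1)
        assert s.mean == pytest.approx(2.0)
        assert s.variance == pytest.approx(1.0)
        assert s.energy == pytest.approx(14.0)
        assert s.autocorr == pytest.approx(8.0)  # 1*2 + 2*3

    def test_zero_sequence(self):
        s = imf_stats(np.zeros(6))
        assert (s.mean, s.variance, s.energy, s.autocorr) == (0, 0, 0, 0)

    def test_constant_sequence(self):
        c = 2.5
        s = imf_stats(np.full(8, c))
        assert s.variance == 0.0
        assert s.energy == pytest.approx(8 * c**2)

    def test_matches_brute_force_formulas(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(2, 40))
            x = rng.normal(size=n)
            m = int(rng.integers(0, n))
            s = imf_stats(x, lag=m)
            mean = sum(x) / n
            var = sum((v - mean) ** 2 for v in x) / (n - 1)
            energy = sum(v * v for v in x)
            ac = sum(x[i] * x[i + m] for i in range(n - m))
            assert s.mean == pytest.approx(mean, rel=1e-12)
            assert s.variance == pytest.approx(var, rel=1e-12, abs=1e-15)
            assert s.energy == pytest.approx(energy, rel=1e-12)
            assert s.autocorr == pytest.approx(ac, rel=1e-12, abs=1e-12)

    def test_error_conditions(self):
        with pytest.raises(InvalidInputError):
            imf_stats(np.array([1.0]))
        with pytest.raises(InvalidInputError):
            imf_stats(np.arange(4.0), lag=4)


class TestEmdBlock:
    def test_default_block_has_43_entries(self):
        block = extract_emd_block(make_record(0))
        assert block.shape == (43,)
        assert np.all(np.isfinite(block))

    def test_constant_signals_zero_filled(self):
        rec = make_record(
            0,
            asa_complex=np.full(8, 3.0), asa_unbound=np.full(8, 1.0),
            asa_delta=np.full(8, 2.0), dssp=np.full(6, 0.5),
        )
        assert not extract_emd_block(rec).any()

    def test_monotone_signal_zeroes_its_group(self):
        rec = make_record(0, asa_delta=np.linspace(0, 7, 8))
        block = extract_emd_block(rec)
        # d_ASA occupies slots 24..35 of the EMD block layout
        assert not block[24:36].any()
        assert block[:24].any()
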