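"""Loss-module tests, anchored by an independent brute-force MCC oracle.

The oracle computes the same statistic a completely different way: bandpass
both signals by explicit frequency-bin masking, then evaluate the normalized
cross-correlation at every integer lag by direct time-domain summation over
zero-padded sequences, take the maximum, and scale by the in-band power
ratio. The FFT implementation must agree to 1e-6 relative.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rppglite.losses import (
    LOSS_KINDS,
    bandpass_mask,
    loss_value,
    loss_value_with_grad,
    mcc,
    mcc_with_grad,
    neg_pcc,
    neg_pcc_with_grad,
)
from rppglite.signal import BandpassSpec, HR_BAND, Signal1D, mean_center


def _bandlimit(values: np.ndarray, fs: float, band: BandpassSpec) -> np.ndarray:
    """Keep only in-band frequency content (full-FFT bin masking)."""
    n = len(values)
    spec = np.fft.fft(values)
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    spec[(np.abs(freqs) < band.f_lo) | (np.abs(freqs) > band.f_hi)] = 0.0
    return np.fft.ifft(spec).real


def mcc_bruteforce(y: Signal1D, yhat: Signal1D, band: BandpassSpec) -> float:
    """Time-domain lag-scan oracle for the MCC statistic."""
    n = len(y)
    yc = y.values - y.values.mean()
    hc = yhat.values - yhat.values.mean()
    sigma_y = np.sqrt(np.mean(yc**2))
    sigma_h = np.sqrt(np.mean(hc**2))
    # cpr from the reference: in-band power over total non-DC power
    spec = np.fft.fft(yc)
    freqs = np.fft.fftfreq(n, d=1.0 / y.fs)
    power = np.abs(spec) ** 2
    in_band = (np.abs(freqs) >= band.f_lo) & (np.abs(freqs) <= band.f_hi)
    cpr = power[in_band].sum() / (power.sum() - power[0])
    # bandpass both signals by explicit bin masking on their own grid, then
    # scan every integer lag of the zero-padded sequences by direct summation
    m = 1
    while m < 2 * n:
        m *= 2
    yb = np.concatenate([_bandlimit(yc, y.fs, band), np.zeros(m - n)])
    hb = np.concatenate([_bandlimit(hc, y.fs, band), np.zeros(m - n)])
    best = -np.inf
    for lag in range(m):
        c = float(np.sum(np.roll(yb, -lag) * hb))
        best = max(best, c)
    return cpr * best / (n * sigma_y * sigma_h)


class TestBandpassMask:
    def test_single_bin_band(self):
        mask = bandpass_mask(8, 8.0, BandpassSpec(0.9, 1.1))
        # only the +-1 Hz bins (indices 1 and 7)
        assert mask.tolist() == [0, 1, 0, 0, 0, 0, 0, 1]

    def test_full_band_minus_dc(self):
        # odd n_fft: no Nyquist bin, so a band up to just below fs/2 covers
        # every non-DC bin
        mask = bandpass_mask(15, 8.0, BandpassSpec(0.25, 3.999))
        assert mask[0] == 0
        assert mask[1:].sum() == 14

    def test_counts_match_bin_enumeration(self):
        n_fft, fs = 600, 30.0
        mask = bandpass_mask(n_fft, fs, HR_BAND)
        freqs = np.fft.fftfreq(n_fft, d=1.0 / fs)
        expected = sum(1 for f in freqs if HR_BAND.f_lo <= abs(f) <= HR_BAND.f_hi)
        assert mask.sum() == expected

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_mask(64, 4.0, BandpassSpec(0.5, 2.5))


class TestMeanCenter:
    def test_constant_signal_maps_to_zero(self):
        out = mean_center(Signal1D(np.array([5.0, 5, 5, 5]), 10.0))
        assert np.allclose(out.values, 0.0)

    def test_idempotent_on_zero_mean(self, rng):
        v = rng.normal(size=100)
        v -= v.mean()
        out = mean_center(Signal1D(v, 30.0))
        assert np.allclose(out.values, v, atol=1e-14)

    def test_output_mean_below_machine_eps(self, rng):
        out = mean_center(Signal1D(rng.normal(size=100) + 17.3, 30.0))
        assert abs(out.values.mean()) < 1e-12


class TestMcc:
    def test_self_correlation_of_in_band_tone(self, make_tone):
        s = make_tone(1.5)
        comp = mcc(s, s)
        assert comp.mcc == pytest.approx(1.0, abs=1e-3)
        assert comp.cpr == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_spectral_support(self, make_tone):
        y = make_tone(1.5)
        yhat = make_tone(10.0)  # outside 0.667-3 Hz
        assert abs(mcc(y, yhat).mcc) < 1e-2

    def test_lag_max_absorbs_delay(self, rng):
        """A k-sample delay costs only the k/N overlap loss, never the phase.

        Linear (zero-padded) correlation of a delayed copy irreducibly loses
        the non-overlapping k/N fraction of correlation mass; the lag max
        removes the *phase* penalty (a half-period delay would otherwise
        score about -1). The score must sit at the overlap envelope
        (1 - k/N) and the winning lag must recover the delay.
        """
        fs, n = 30.0, 256
        base = _bandlimit(rng.normal(size=n), fs, BandpassSpec(1.0, 2.0))
        y = Signal1D(base, fs)
        ref = mcc(y, y).mcc
        for k in (5, 20, n // 4):
            # delayed window of the same underlying signal (non-wrapping)
            delayed = Signal1D(np.concatenate([np.zeros(k), base[: n - k]]), fs)
            comp = mcc(y, delayed)
            envelope = (1 - k / n) * ref
            assert comp.mcc >= envelope - 0.05 * ref
            assert comp.mcc <= ref * 1.01 + 1e-9
            # the winning lag matches the physical delay
            m = len(comp.cross_corr)
            lag = comp.lag_max if comp.lag_max <= m // 2 else comp.lag_max - m
            assert abs(abs(lag) - k) <= 2

    def test_half_period_delay_not_penalized(self, make_tone):
        """Without the lag max a half-period shift would score -1; with it
        the score stays near +1 (up to the small overlap loss)."""
        fs, hz, n = 30.0, 1.5, 300
        half_period = int(round(fs / hz / 2))  # 10 samples
        y = make_tone(hz, fs, n)
        shifted = make_tone(hz, fs, n, phase=np.pi)
        comp = mcc(y, shifted)
        assert comp.mcc > 0.95
        assert neg_pcc(y, shifted) == pytest.approx(1.0, abs=1e-6)  # contrast
        assert half_period > 0

    @pytest.mark.parametrize("pair_seed", range(4))
    def test_matches_bruteforce_oracle_spot(self, pair_seed):
        rng = np.random.default_rng(pair_seed)
        fs, n = 30.0, 300
        y = Signal1D(rng.normal(size=n), fs)
        yhat = Signal1D(rng.normal(size=n), fs)
        fast = mcc(y, yhat).mcc
        slow = mcc_bruteforce(y, yhat, HR_BAND)
        assert fast == pytest.approx(slow, rel=1e-6, abs=1e-12)

    def test_scale_invariance(self, rng):
        fs, n = 30.0, 200
        y = Signal1D(rng.normal(size=n), fs)
        yhat = Signal1D(rng.normal(size=n), fs)
        ref = mcc(y, yhat).mcc
        for a, b in ((2.0, 3.0), (0.1, 7.0), (123.0, 0.02)):
            scaled = mcc(Signal1D(a * y.values, fs), Signal1D(b * yhat.values, fs)).mcc
            assert scaled == pytest.approx(ref, abs=1e-9)

    def test_bounded_by_cpr_for_in_band_signals(self, rng):
        fs, n = 30.0, 256
        y = Signal1D(_bandlimit(rng.normal(size=n), fs, BandpassSpec(1.0, 2.5)), fs)
        yhat = Signal1D(_bandlimit(rng.normal(size=n), fs, BandpassSpec(1.0, 2.5)), fs)
        comp = mcc(y, yhat)
        assert abs(comp.mcc) <= comp.cpr + 1e-6

    def test_degenerate_inputs_rejected(self, make_tone):
        flat = Signal1D(np.ones(300), 30.0)
        with pytest.raises(ValueError, match="degenerate"):
            mcc(make_tone(1.5), flat)
        with pytest.raises(ValueError, match="length mismatch"):
            mcc(make_tone(1.5, n=300), make_tone(1.5, n=200))

    def test_gradient_matches_finite_differences(self, rng):
        fs, n = 30.0, 64
        y = Signal1D(rng.normal(size=n), fs)
        h = rng.normal(size=n)
        _, grad = mcc_with_grad(y, Signal1D(h, fs))
        eps = 1e-7
        for i in rng.integers(0, n, size=6):
            hp, hm = h.copy(), h.copy()
            hp[i] += eps
            hm[i] -= eps
            fd = (mcc(y, Signal1D(hp, fs)).mcc - mcc(y, Signal1D(hm, fs)).mcc) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-9)


class TestNegPcc:
    def test_identical_signals(self, make_tone):
        s = make_tone(1.2)
        assert neg_pcc(s, s) == pytest.approx(-1.0, abs=1e-12)

    def test_anticorrelated_signals(self, make_tone):
        s = make_tone(1.2)
        assert neg_pcc(s, Signal1D(-s.values, s.fs)) == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_formula(self, rng):
        fs, n = 30.0, 150
        a, b = rng.normal(size=n), rng.normal(size=n)
        expected = -np.corrcoef(a, b)[0, 1]
        assert neg_pcc(Signal1D(a, fs), Signal1D(b, fs)) == pytest.approx(
            expected, abs=1e-10
        )

    def test_gradient_matches_finite_differences(self, rng):
        fs, n = 30.0, 50
        y = Signal1D(rng.normal(size=n), fs)
        h = rng.normal(size=n)
        _, grad = neg_pcc_with_grad(y, Signal1D(h, fs))
        eps = 1e-7
        for i in rng.integers(0, n, size=5):
            hp, hm = h.copy(), h.copy()
            hp[i] += eps
            hm[i] -= eps
            fd = (neg_pcc(y, Signal1D(hp, fs)) - neg_pcc(y, Signal1D(hm, fs))) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-6, abs=1e-10)


class TestLossValue:
    def test_mse_of_identical_signals_is_zero(self, make_tone):
        s = make_tone(1.5)
        assert loss_value("mse", s, s) == 0.0

    def test_negmcc_self_correlation(self, make_tone):
        s = make_tone(1.5)
        assert loss_value("negmcc", s, s) == pytest.approx(-1.0, abs=1e-3)

    def test_all_kinds_finite_and_sign_symmetric(self, rng):
        fs, n = 30.0, 120
        y = Signal1D(rng.normal(size=n), fs)
        yhat = Signal1D(rng.normal(size=n), fs)
        values = {k: loss_value(k, y, yhat) for k in LOSS_KINDS}
        assert all(np.isfinite(v) for v in values.values())
        assert values["negmcc"] == -values["mcc"]

    def test_unknown_kind_rejected(self, make_tone):
        s = make_tone(1.0)
        with pytest.raises(ValueError, match="unknown loss kind"):
            loss_value("huber", s, s)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_mcc_oracle_equivalence_random_pairs(seed):
    """FFT MCC equals the direct lag-scan oracle on arbitrary random pairs."""
    rng = np.random.default_rng(seed)
    fs, n = 30.0, 128
    y = Signal1D(rng.normal(size=n), fs)
    yhat = Signal1D(rng.normal(size=n), fs)
    assert mcc(y, yhat).mcc == pytest.approx(
        mcc_bruteforce(y, yhat, HR_BAND), rel=1e-6, abs=1e-12
    )


def test_masked_cross_spectrum_is_hermitian(rng):
    """The masked cross-spectrum inverse transform is real (Hermitian input)."""
    fs, n = 30.0, 100
    yc = rng.normal(size=n)
    hc = rng.normal(size=n)
    m = 256
    mask = bandpass_mask(m, fs, HR_BAND)
    cross = mask * np.fft.fft(yc, m) * np.conj(np.fft.fft(hc, m))
    assert np.allclose(cross, np.conj(cross[(m - np.arange(m)) % m]))
    back = np.fft.ifft(cross)
    assert np.max(np.abs(back.imag)) <= 1e-9 * np.max(np.abs(back.real))
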