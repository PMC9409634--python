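import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import signal as sps_signal

from hrvpart.errors import ParameterError, SubjectMismatchError
from hrvpart.indices import (
    HRVIndexSet,
    delta,
    dfa_alpha1,
    hrv_indices,
    resample_tachogram,
    sampen,
    spectral_indices,
    time_domain,
)
from hrvpart.preprocess import NNSeries
from hrvpart.synth import RRGenParams, fractal_noise, generate_rr


class TestTimeDomain:
    def test_constant_series_has_zero_variability(self):
        mean_nn, sdnn, rmssd, pnn20 = time_domain(np.full(300, 800.0))
        assert (mean_nn, sdnn, rmssd, pnn20) == (800.0, 0.0, 0.0, 0.0)

    def test_alternating_50ms_series(self):
        x = np.tile([800.0, 850.0], 150)
        mean_nn, sdnn, rmssd, pnn20 = time_domain(x)
        assert rmssd == pytest.approx(50.0)
        assert pnn20 == pytest.approx(100.0)

    def test_pnn20_is_strictly_greater_than_20ms(self):
        x = np.tile([800.0, 820.0], 150)  # all successive diffs exactly 20 ms
        assert time_domain(x)[3] == 0.0

    def test_length_guard(self):
        with pytest.raises(ParameterError):
            time_domain([800.0])

    def test_matches_naive_loop_oracle(self, rng):
        """Independent elementwise-loop computation, 20 random series."""
        for _ in range(20):
            x = rng.uniform(600, 1100, size=rng.integers(50, 400))
            mean_nn, sdnn, rmssd, pnn20 = time_domain(x)
            n = len(x)
            o_mean = sum(x) / n
            o_sd = (sum((v - o_mean) ** 2 for v in x) / (n - 1)) ** 0.5
            sq = [(x[i + 1] - x[i]) ** 2 for i in range(n - 1)]
            o_rmssd = (sum(sq) / (n - 1)) ** 0.5
            o_pnn = 100.0 * sum(abs(x[i + 1] - x[i]) > 20 for i in range(n - 1)) / (n - 1)
            assert mean_nn == pytest.approx(o_mean, rel=1e-9)
            assert sdnn == pytest.approx(o_sd, rel=1e-6)
            assert rmssd == pytest.approx(o_rmssd, rel=1e-6)
            assert pnn20 == pytest.approx(o_pnn, rel=1e-9)


class TestResampleTachogram:
    def test_constant_series_stays_constant(self):
        grid, values = resample_tachogram(np.full(100, 800.0))
        assert np.all(values == 800.0)
        assert grid[0] == pytest.approx(0.8)

    def test_two_intervals_interpolate_linearly(self):
        grid, values = resample_tachogram(np.array([500.0, 1000.0]))
        expected = 500.0 + (grid - 0.5) / 1.0 * 500.0
        np.testing.assert_allclose(values, expected)

    def test_sinusoidal_rr_keeps_its_frequency(self):
        nn = generate_rr(
            RRGenParams(n_beats=512, mean_nn=800, amp_lf=50, f_lf=0.10,
                        amp_hf=0, noise_sd=0, fractal_alpha=0.5)
        )
        grid, values = resample_tachogram(nn)
        spec = np.abs(np.fft.rfft(values - values.mean()))
        freqs = np.fft.rfftfreq(len(values), d=1 / 3.0)
        peak = freqs[np.argmax(spec)]
        assert peak == pytest.approx(0.10, abs=freqs[1])


class TestSpectralIndices:
    def test_pure_lf_sinusoid_concentrates_in_lf_band(self):
        nn = generate_rr(
            RRGenParams(mean_nn=800, amp_lf=50, amp_hf=0, noise_sd=0,
                        fractal_alpha=0.5)
        )
        lf, hf, lfn, hfn, lf_hf, est = spectral_indices(nn)
        assert lfn >= 95.0
        assert lf_hf >= 19.0
        assert np.all(est.psd >= 0)

    def test_pure_hf_sinusoid_concentrates_in_hf_band(self):
        nn = generate_rr(
            RRGenParams(mean_nn=800, amp_lf=0, amp_hf=50, noise_sd=0,
                        fractal_alpha=0.5)
        )
        assert spectral_indices(nn)[3] >= 95.0

    def test_normalized_units_sum_to_100(self, rng):
        x = rng.uniform(700, 900, 300)
        lf, hf, lfn, hfn, *_ = spectral_indices(x)
        assert lfn + hfn == pytest.approx(100.0, abs=1e-9)

    def test_zero_power_flags_normalized_units(self):
        lf, hf, lfn, hfn, lf_hf, _ = spectral_indices(np.full(300, 800.0))
        assert lf == 0 and hf == 0
        assert np.isnan(lfn) and np.isnan(hfn) and np.isnan(lf_hf)

    def test_too_short_record_rejected(self):
        with pytest.raises(ParameterError, match="64"):
            spectral_indices(np.full(50, 800.0))

    def test_matches_independent_welch_oracle(self, rng):
        """Hand-rolled segment-averaged periodogram, same conventions."""
        for _ in range(5):
            x = rng.uniform(650, 1050, 300)
            lf, hf, *_ = spectral_indices(x)
            grid, values = resample_tachogram(x)
            v = values - values.mean()
            nper = 256
            w = sps_signal.get_window("hann", nper)
            step = nper - nper // 2
            acc = np.zeros(nper // 2 + 1)
            segs = [v[i:i + nper] for i in range(0, len(v) - nper + 1, step)]
            for s in segs:
                s = s - s.mean()
                X = np.fft.rfft(s * w)
                pxx = np.abs(X) ** 2 / (3.0 * np.sum(w**2))
                pxx[1:-1] *= 2
                acc += pxx
            psd = acc / len(segs)
            freqs = np.fft.rfftfreq(nper, d=1 / 3.0)
            m_lf = (freqs >= 0.04) & (freqs < 0.15)
            m_hf = (freqs >= 0.15) & (freqs <= 0.40)
            assert lf == pytest.approx(np.trapezoid(psd[m_lf], freqs[m_lf]), rel=1e-6)
            assert hf == pytest.approx(np.trapezoid(psd[m_hf], freqs[m_hf]), rel=1e-6)


class TestDfaAlpha1:
    def test_white_noise_reads_one_half(self):
        nn = generate_rr(
            RRGenParams(n_beats=2**14, mean_nn=800, amp_lf=0, amp_hf=0,
                        noise_sd=20, fractal_alpha=0.5, seed=3)
        )
        assert dfa_alpha1(nn) == pytest.approx(0.5, abs=0.05)

    def test_one_over_f_surrogate_reads_near_one(self):
        nn = generate_rr(
            RRGenParams(n_beats=2**14, mean_nn=800, amp_lf=0, amp_hf=0,
                        noise_sd=20, fractal_alpha=1.0, seed=4)
        )
        assert dfa_alpha1(nn) == pytest.approx(1.0, abs=0.1)

    def test_constant_series_is_flagged(self):
        assert np.isnan(dfa_alpha1(np.full(300, 800.0)))

    def test_shuffling_moves_alpha_toward_one_half(self, rng):
        x = 800 + 25 * fractal_noise(2048, 1.2, rng)
        a_orig = dfa_alpha1(x)
        a_shuf = dfa_alpha1(rng.permutation(x))
        assert abs(a_shuf - 0.5) < abs(a_orig - 0.5)

    def test_length_guard(self):
        with pytest.raises(ParameterError):
            dfa_alpha1(np.full(50, 800.0))


def _sampen_bruteforce(x, m, r):
    """Literal O(n²) template-count definition (independent oracle)."""
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    return -np.log(a / b) if a and b else float("nan")


class TestSampen:
    def test_alternating_series_is_perfectly_predictable(self):
        x = np.tile([800.0, 850.0], 150)
        assert sampen(x) == pytest.approx(0.0, abs=1e-12)

    def test_equals_bruteforce_oracle_exactly(self, rng):
        x = 800 + 30 * rng.standard_normal(300)
        r = 0.2 * np.std(x, ddof=1)
        assert sampen(x) == _sampen_bruteforce(x, 2, r)

    def test_constant_series_is_flagged(self):
        assert np.isnan(sampen(np.full(300, 800.0)))

    def test_length_guard(self):
        with pytest.raises(ParameterError):
            sampen([800.0, 810.0, 820.0])


class TestScaleEquivariance:
    @given(st.floats(min_value=0.5, max_value=2.0))
    def test_scaling_intervals_scales_indices_consistently(self, c):
        """meanNN/SDNN/RMSSD scale with c; α₁ and SampEn are invariant.

        These hold exactly: DFA's log-slope and SampEn's SD-relative
        tolerance are insensitive to the unit of the intervals.
        """
        rng = np.random.default_rng(99)
        x = 800 + 30 * fractal_noise(300, 0.9, rng)
        td, td_c = time_domain(x), time_domain(c * x)
        for i in range(3):
            assert td_c[i] == pytest.approx(c * td[i], rel=1e-9)
        assert dfa_alpha1(c * x) == pytest.approx(dfa_alpha1(x), rel=1e-9)
        assert sampen(c * x) == pytest.approx(sampen(x), rel=1e-12)

    def test_band_power_scales_with_c_squared_for_in_band_tone(self):
        """LF power ∝ c² when the (time-stretched) tone stays in band.

        Scaling intervals by c scales the tachogram's value axis by c
        (power by c²) and stretches its time axis by ~c, so the fixed
        physical bands only see a clean c² when the oscillation remains
        inside the band after stretching.
        """
        base = generate_rr(
            RRGenParams(mean_nn=800, amp_lf=50, amp_hf=0, noise_sd=0,
                        fractal_alpha=0.5)
        )
        lf1, _, lfn1, *_ = spectral_indices(base)
        c = 1.2  # 0.10 Hz -> ~0.083 Hz, still in the LF band
        lf2, _, lfn2, *_ = spectral_indices(c * base.intervals)
        assert lf2 / lf1 == pytest.approx(c**2, rel=0.05)
        assert lfn1 >= 95 and lfn2 >= 95


class TestDelta:
    def _index_set(self, **kw):
        defaults = dict(
            mean_nn=900.0, sdnn=40.0, rmssd=30.0, pnn20=40.0, lf=500.0,
            hf=700.0, lfn=41.7, hfn=58.3, lf_hf=0.71, alpha1=0.9,
            sampen=1.5, subject_id="s1", posture="supine",
        )
        defaults.update(kw)
        return HRVIndexSet(**defaults)

    def test_identical_sets_give_zero(self):
        a = self._index_set()
        b = self._index_set(posture="standing")
        d = delta(a, b)
        assert all(v == 0.0 for v in d.as_dict().values())

    def test_mean_nn_delta_in_seconds(self):
        a = self._index_set(mean_nn=1000.0)
        b = self._index_set(mean_nn=800.0, posture="standing")
        d = delta(a, b)
        assert d.d_mean_nn == pytest.approx(200.0)
        assert d.d_mean_nn_s == pytest.approx(0.2)

    def test_subject_mismatch_rejected(self):
        a = self._index_set()
        b = self._index_set(subject_id="s2")
        with pytest.raises(SubjectMismatchError):
            delta(a, b)

    def test_nan_flags_propagate(self):
        a = self._index_set(sampen=float("nan"))
        b = self._index_set(posture="standing")
        assert np.isnan(delta(a, b).d_sampen)

    def test_normalized_delta_mirror_identity(self):
        """Δlfn = -Δhfn whenever both postures have band power."""
        sup = generate_rr(RRGenParams(seed=11), posture="supine", subject_id="s")
        sta = generate_rr(RRGenParams(seed=12, mean_nn=700), posture="standing",
                          subject_id="s")
        d = delta(hrv_indices(sup), hrv_indices(sta))
        assert d.d_lfn == pytest.approx(-d.d_hfn, abs=1e-9)
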