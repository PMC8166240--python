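import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maldimtu.errors import DegenerateInputError, ParameterError
from maldimtu.preprocess import (
    ParamSet,
    average_replicates,
    detect_peaks,
    estimate_noise,
    normalize_tic,
    smooth,
    subtract_baseline,
)

from conftest import mk_spectrum


def _grid_spectrum(intensity, start=2000.0, step=1.0, **kw):
    intensity = np.asarray(intensity, dtype=float)
    mz = start + step * np.arange(intensity.size)
    return mk_spectrum(mz, intensity, **kw)


class TestSmooth:
    def test_constant_unchanged(self):
        sp = _grid_spectrum(np.full(50, 3.0))
        out = smooth(sp, 5)
        assert np.allclose(out.intensity, 3.0)

    def test_cubic_reproduced_exactly(self):
        x = np.arange(60, dtype=float)
        cubic = 1e-3 * x**3 - 0.05 * x**2 + x + 40
        sp = _grid_spectrum(cubic)
        out = smooth(sp, 5)
        assert np.allclose(out.intensity, cubic, atol=1e-8)

    def test_noise_reduced(self):
        rng = np.random.default_rng(42)
        x = np.arange(500, dtype=float)
        clean = 100 * np.exp(-0.5 * ((x - 250) / 5.0) ** 2) + 10
        noisy = clean + rng.normal(0, 2.0, x.size)
        sp = _grid_spectrum(np.clip(noisy, 0, None))
        out = smooth(sp, 4)
        sd_before = np.std(sp.intensity - clean)
        sd_after = np.std(out.intensity - clean)
        assert sd_after < sd_before

    def test_window_too_long(self):
        sp = _grid_spectrum(np.ones(9))
        with pytest.raises(ParameterError):
            smooth(sp, 5)

    def test_half_window_minimum(self):
        sp = _grid_spectrum(np.ones(50))
        with pytest.raises(ParameterError):
            smooth(sp, 1)

    def test_negative_clipped(self):
        rng = np.random.default_rng(0)
        sp = _grid_spectrum(np.clip(rng.normal(0.1, 1, 200), 0, None))
        out = smooth(sp, 5)
        assert np.all(out.intensity >= 0)


def _opening_oracle(y, half_window):
    """Brute-force flat erosion followed by dilation (edge = nearest)."""
    n = len(y)
    eroded = [min(y[max(0, i - half_window): i + half_window + 1])
              for i in range(n)]
    return np.array([max(eroded[max(0, i - half_window): i + half_window + 1])
                     for i in range(n)])


class TestSubtractBaseline:
    def test_flat_spectrum_zeroed(self):
        sp = _grid_spectrum(np.full(30, 7.0))
        out = subtract_baseline(sp, 3)
        assert np.allclose(out.intensity, 0.0)

    def test_single_spike_preserved(self):
        y = np.zeros(31)
        y[15] = 50.0
        out = subtract_baseline(_grid_spectrum(y), 2)
        assert np.array_equal(out.intensity, y)

    def test_ramp_with_peaks_vs_oracle(self):
        rng = np.random.default_rng(7)
        y = np.linspace(0, 10, 50)
        peaks_at = [10, 25, 40]
        for i in peaks_at:
            y[i] += 30.0
        sp = _grid_spectrum(y)
        hw = 4
        out = subtract_baseline(sp, hw)
        expected = y - _opening_oracle(y, hw)
        assert np.allclose(out.intensity, expected)
        for i in peaks_at:  # narrow peaks retained within 1% of height
            assert out.intensity[i] >= 0.99 * 30.0

    @given(st.lists(st.floats(0, 100), min_size=12, max_size=60),
           st.integers(1, 5))
    @settings(max_examples=50, deadline=None)
    def test_matches_oracle_and_idempotent(self, values, hw):
        y = np.asarray(values)
        sp = _grid_spectrum(y)
        if 2 * hw + 1 > len(y):
            return
        once = subtract_baseline(sp, hw)
        assert np.allclose(once.intensity, y - _opening_oracle(y, hw))
        twice = subtract_baseline(once, hw)
        assert np.allclose(twice.intensity, once.intensity)
        assert np.all(once.intensity >= 0)


class TestNormalizeTic:
    def test_examples(self):
        assert np.allclose(normalize_tic(_grid_spectrum([2, 2])).intensity,
                           [0.5, 0.5])
        assert np.allclose(normalize_tic(_grid_spectrum([1, 3])).intensity,
                           [0.25, 0.75])

    def test_sums_to_one(self):
        rng = np.random.default_rng(1)
        sp = _grid_spectrum(rng.uniform(0, 10, 100))
        assert normalize_tic(sp).intensity.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_tic(_grid_spectrum(np.zeros(10)))


class TestEstimateNoise:
    def test_gaussian_consistency(self):
        rng = np.random.default_rng(123)
        sp = _grid_spectrum(np.abs(rng.normal(100, 1.0, 10_000)))
        assert 0.95 <= estimate_noise(sp) <= 1.05

    def test_constant_zero(self):
        assert estimate_noise(_grid_spectrum(np.full(20, 5.0))) == 0.0

    def test_robust_to_single_spike(self):
        y = np.zeros(10)
        y[-1] = 100.0
        assert estimate_noise(_grid_spectrum(y)) == 0.0

    def test_needs_ten_points(self):
        with pytest.raises(ParameterError):
            estimate_noise(_grid_spectrum(np.ones(5)))


def _detect_oracle(intensity, half_window, snr, noise):
    """Exhaustive scan: strict window max with ties broken toward lower m/z."""
    hits = []
    threshold = snr * noise
    n = len(intensity)
    for i in range(n):
        if intensity[i] <= 0 or intensity[i] < threshold:
            continue
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        ok = True
        for j in range(lo, hi):
            if j == i:
                continue
            if intensity[j] > intensity[i] or (
                intensity[j] == intensity[i] and j < i
            ):
                ok = False
                break
        if ok:
            hits.append(i)
    return hits


class TestDetectPeaks:
    def test_single_gaussian_one_peak(self):
        x = np.arange(200, dtype=float)
        rng = np.random.default_rng(5)
        y = 100 * np.exp(-0.5 * ((x - 100) / 4.0) ** 2) + np.abs(
            rng.normal(0, 1, 200))
        sp = _grid_spectrum(y)
        pl = detect_peaks(sp, half_window=10, snr=10)
        assert len(pl) == 1
        assert pl.peaks[0].mz == sp.mz[np.argmax(y)]

    def test_close_apices_taller_wins(self):
        y = 0.01 * (np.arange(40) % 2)  # tiny floor so noise > 0
        y[20], y[23] = 10.0, 8.0
        pl = detect_peaks(_grid_spectrum(y), half_window=5, snr=2)
        assert [p.intensity for p in pl.peaks] == [pytest.approx(10.0, abs=0.1)]

    def test_thirty_peak_oracle(self):
        rng = np.random.default_rng(99)
        x = np.arange(1000, dtype=float)
        y = np.abs(rng.normal(0, 1, 1000))
        for pos in rng.choice(np.arange(20, 980), 30, replace=False):
            y[pos] += rng.uniform(5, 50)
        sp = _grid_spectrum(y)
        pl = detect_peaks(sp, half_window=7, snr=3)
        noise = estimate_noise(sp)
        oracle = _detect_oracle(y, 7, 3, noise)
        assert [p.mz for p in pl.peaks] == [sp.mz[i] for i in oracle]

    @given(st.integers(0, 2**31 - 1), st.integers(1, 12),
           st.floats(1.0, 6.0))
    @settings(max_examples=25, deadline=None)
    def test_random_spectra_match_oracle(self, seed, hw, snr):
        rng = np.random.default_rng(seed)
        y = np.round(np.abs(rng.normal(0, 2, 300)), 1)  # ties occur
        sp = _grid_spectrum(y)
        pl = detect_peaks(sp, half_window=hw, snr=snr)
        oracle = _detect_oracle(y, hw, snr, estimate_noise(sp))
        assert [p.mz for p in pl.peaks] == [sp.mz[i] for i in oracle]

    def test_zero_noise_infinite_snr_flag(self):
        y = np.zeros(30)
        y[15] = 10.0
        # constant background -> MAD 0 -> noise 0
        pl = detect_peaks(_grid_spectrum(y), half_window=3, snr=3)
        assert pl.infinite_snr
        assert pl.peaks[0].snr == np.inf


class TestAverageReplicates:
    def test_single_identity(self):
        sp = _grid_spectrum([1.0, 2.0, 3.0])
        assert average_replicates([sp]) is sp

    def test_two_spectra_mean(self):
        a = _grid_spectrum([1.0, 3.0])
        b = _grid_spectrum([3.0, 1.0])
        assert np.allclose(average_replicates([a, b]).intensity, [2.0, 2.0])

    def test_offset_grids_interpolated(self):
        mz_a = np.array([2000.0, 2001.0, 2002.0, 2003.0, 2004.0])
        ia = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
        mz_b = mz_a + 0.5
        ib = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        a = mk_spectrum(mz_a, ia)
        b = mk_spectrum(mz_b, ib)
        # manual linear interpolation of b onto a's grid (np.interp clamps ends)
        b_interp = np.array([1.0, 2.0, 4.0, 6.0, 8.0])
        expected = (ia + b_interp) / 2.0
        assert np.allclose(average_replicates([a, b]).intensity, expected)

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            average_replicates([])


def test_paramset_validation():
    with pytest.raises(ParameterError):
        ParamSet(0, 10, 10, 0.002, 3, 10, 3)
    with pytest.raises(ParameterError):
        ParamSet(5, 10, 10, -1.0, 3, 10, 3)
    with pytest.raises(ParameterError):
        ParamSet(5, 10, 10, 0.002, 0, 10, 3)


def test_pipeline_outputs_satisfy_invariants(small_library, default_params):
    from maldimtu.preprocess import preprocess_spectrum

    spectra, _, _ = small_library
    for sp in spectra[:4]:
        pl = preprocess_spectrum(sp, default_params)
        mzs = pl.mz
        assert np.all(np.diff(mzs) > 0)
        assert np.all(pl.intensity > 0)
        assert np.all(pl.snr >= 0)
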