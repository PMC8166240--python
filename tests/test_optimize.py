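import numpy as np
import pandas as pd
import pytest

from maldimtu.errors import ParameterError, ValidationError
from maldimtu.optimize import (
    ParamRanges,
    objective_bts,
    objective_discrimination,
    pair_labels_from_identity,
    qc_filter,
    run_loop1,
    run_loop2,
    sample_params,
)
from maldimtu.preprocess import Peak, PeakList
from maldimtu.synth import SynthConfig, generate_bts, generate_qc_set

from conftest import mk_spectrum


class TestSampleParams:
    def test_seeded_determinism(self):
        r = ParamRanges()
        assert sample_params(r, 42) == sample_params(r, 42)

    def test_degenerate_range(self):
        r = ParamRanges(smooth_halfwindow=(7, 7), peak_snr=(3.5, 3.5))
        for seed in range(5):
            p = sample_params(r, seed)
            assert p.smooth_halfwindow == 7
            assert p.peak_snr == 3.5

    def test_within_bounds(self):
        r = ParamRanges()
        for seed in range(50):
            p = sample_params(r, seed)
            assert 2 <= p.smooth_halfwindow <= 25
            assert 10 <= p.baseline_halfwindow <= 200
            assert 2e-4 <= p.align_tolerance <= 1e-2
            assert 1 <= p.align_snr <= 10

    def test_integer_uniformity(self):
        # 1,000 draws over [1, 10]: every value seen, counts within
        # binomial 99% bounds (p = 0.1, n = 1000 -> 100 +- 2.576 * 9.49)
        r = ParamRanges(smooth_halfwindow=(1, 10))
        rng = np.random.default_rng(7)
        draws = [sample_params(r, rng).smooth_halfwindow for _ in range(1000)]
        counts = np.bincount(draws, minlength=11)[1:]
        assert (counts > 0).all()
        lo = 100 - 2.576 * np.sqrt(1000 * 0.1 * 0.9)
        hi = 100 + 2.576 * np.sqrt(1000 * 0.1 * 0.9)
        assert np.all((counts >= lo) & (counts <= hi))

    def test_invalid_ranges(self):
        with pytest.raises(ParameterError):
            ParamRanges(smooth_halfwindow=(10, 2))
        with pytest.raises(ParameterError):
            ParamRanges(align_tolerance=(-1e-3, 1e-2))


class TestObjectiveBTS:
    def test_identical_bts_unit_jaccard(self, default_params):
        cfg = SynthConfig(grid_step=2.0, seed=5, noise_sd=0.0,
                          drift_per_target=0.0)
        bts = generate_bts(cfg, n_targets=2, replicates_per_target=2)
        res = objective_bts(bts, default_params)
        assert res.mean_jaccard == pytest.approx(1.0)
        assert not res.failed

    def test_disjoint_ranges_zero(self, default_params):
        lo = mk_spectrum(np.arange(2000, 2300, 1.0),
                         np.abs(np.random.default_rng(0).normal(1, 0.1, 300)),
                         sid="b1", group="bts_reference", target="T1")
        hi = mk_spectrum(np.arange(9000, 9300, 1.0),
                         np.abs(np.random.default_rng(1).normal(1, 0.1, 300)),
                         sid="b2", group="bts_reference", target="T2")
        res = objective_bts([lo, hi], default_params)
        assert res.mean_jaccard == 0.0

    def test_needs_two_targets(self, default_params, bts_spectra):
        one_target = [s for s in bts_spectra if s.target_id == "T1"]
        with pytest.raises(ParameterError):
            objective_bts(one_target, default_params)

    def test_extreme_params_fail_softly(self, bts_spectra):
        from maldimtu.preprocess import ParamSet

        # smoothing window far longer than the spectrum would raise deep
        # inside; the objective converts that to a zero score
        huge = ParamSet(50_000, 10, 10, 0.002, 3.0, 10, 3.0)
        res = objective_bts(bts_spectra, huge)
        assert res.failed
        assert res.mean_jaccard == 0.0


class TestLoop1:
    def test_single_iteration_is_best(self, bts_spectra):
        trace, best = run_loop1(bts_spectra, ParamRanges(), n_iter=1, seed=3)
        assert len(trace) == 1
        assert best.as_dict() == {
            k: trace.iloc[0][k] for k in best.as_dict()
        }

    def test_running_max_non_decreasing(self, bts_spectra):
        trace, _ = run_loop1(bts_spectra, ParamRanges(), n_iter=8, seed=1)
        running = trace["mean_jaccard"].cummax()
        assert (np.diff(running) >= 0).all()

    def test_reproducible(self, bts_spectra):
        t1, b1 = run_loop1(bts_spectra, ParamRanges(), n_iter=5, seed=9)
        t2, b2 = run_loop1(bts_spectra, ParamRanges(), n_iter=5, seed=9)
        pd.testing.assert_frame_equal(t1, t2)
        assert b1 == b2

    def test_tolerance_recovery_across_seeds(self):
        # drift of 8e-4 between targets: bins are grouped about their mean,
        # so tolerances below ~drift/2 = 4e-4 cannot match shared peaks
        # (and cannot find warp references either); the best draw must land
        # above that floor (10% slack for peak-position noise)
        cfg = SynthConfig(grid_step=2.0, seed=2, noise_sd=0.5)
        bts = generate_bts(cfg, n_targets=2, replicates_per_target=2,
                           target_drifts=np.array([0.0, 8e-4]))
        hits = 0
        for seed in range(20):
            _, best = run_loop1(bts, ParamRanges(), n_iter=15, seed=seed)
            if best.align_tolerance >= 0.9 * 4e-4:
                hits += 1
        assert hits >= 19


def _mk_peaklist(sid, intensities, snrs):
    peaks = [Peak(2000.0 + 10 * i, v, s)
             for i, (v, s) in enumerate(zip(intensities, snrs))]
    return PeakList(sid, peaks)


class TestQCFilter:
    def test_too_few_peaks_fails(self):
        pl = _mk_peaklist("x", [10] * 12, [100] * 12)
        rep = qc_filter([pl])
        assert rep.failed_ids == ["x"]

    def test_low_median_snr_fails(self):
        snrs = [14.9] * 10 + [10.0] * 10
        intens = list(range(20, 0, -1))
        pl = _mk_peaklist("x", intens, snrs)
        rep = qc_filter([pl])
        assert not rep.frame["passed"].iloc[0]
        assert rep.frame["median_snr_top10"].iloc[0] == pytest.approx(14.9)

    def test_passing_spectrum(self):
        pl = _mk_peaklist("x", [10] * 15, [20] * 15)
        assert qc_filter([pl]).passed_ids == ["x"]

    def test_empty_peaklist_fails_not_errors(self):
        rep = qc_filter([PeakList("e", [])])
        assert rep.failed_ids == ["e"]

    def test_fewer_than_topk_uses_all(self):
        pl = _mk_peaklist("x", [10] * 13, [16] * 13)
        rep = qc_filter([pl], top_k=20)
        assert rep.frame["median_snr_top10"].iloc[0] == pytest.approx(16.0)
        assert rep.passed_ids == ["x"]

    def test_planted_failures_detected_exactly(self, default_params):
        cfg = SynthConfig(grid_step=2.0, seed=13)
        spectra, bad_ids = generate_qc_set(cfg, n_good=20, n_bad=6)
        from maldimtu.preprocess import preprocess_spectrum

        peaklists = [preprocess_spectrum(sp, default_params) for sp in spectra]
        rep = qc_filter(peaklists)
        assert sorted(rep.failed_ids) == sorted(bad_ids)

    def test_purity(self):
        # the decision for one spectrum ignores all others
        good = _mk_peaklist("g", [10] * 15, [20] * 15)
        bad = _mk_peaklist("b", [10] * 5, [2] * 5)
        alone = qc_filter([good]).frame.iloc[0]
        together = qc_filter([bad, good]).frame.iloc[1]
        assert alone["passed"] == together["passed"]
        assert alone["median_snr_top10"] == together["median_snr_top10"]


class TestDiscrimination:
    @staticmethod
    def _as_matrices(within_vals, between_vals):
        n = len(within_vals) + len(between_vals) + 1
        sim = np.eye(n)
        within = np.zeros((n, n), dtype=bool)
        k = 0
        pairs = [(v, True) for v in within_vals] + [
            (v, False) for v in between_vals]
        coords = [(i, j) for i in range(n) for j in range(i + 1, n)][: len(pairs)]
        valid = np.zeros((n, n), dtype=bool)
        for (i, j), (v, w) in zip(coords, pairs):
            sim[i, j] = sim[j, i] = v
            within[i, j] = within[j, i] = w
            valid[i, j] = valid[j, i] = True
        return sim, within, valid

    def test_separable_zero(self):
        sim, within, valid = self._as_matrices([0.9, 0.9], [0.1, 0.1])
        assert objective_discrimination(sim, within, valid) == 0.0

    def test_identical_distributions_half(self):
        sim, within, valid = self._as_matrices([0.5, 0.5], [0.5, 0.5])
        assert objective_discrimination(sim, within, valid) == pytest.approx(0.5)

    def test_hand_worked_quarter(self):
        sim, within, valid = self._as_matrices([0.8, 0.6], [0.7])
        assert objective_discrimination(sim, within, valid) == pytest.approx(0.25)

    def test_bruteforce_threshold_oracle(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(0.4, 1.0, 7)
        b = rng.uniform(0.0, 0.7, 9)
        sim, within, valid = self._as_matrices(list(w), list(b))
        got = objective_discrimination(sim, within, valid)
        grid = np.linspace(-0.1, 1.1, 20_001)
        oracle = min((np.mean(w < t) + np.mean(b >= t)) / 2 for t in grid)
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0.3, 1.0, 5)
        b = rng.uniform(0.0, 0.8, 5)
        sim, within, valid = self._as_matrices(list(w), list(b))
        base = objective_discrimination(sim, within, valid)
        sim2 = sim**3  # strictly monotone on [0, 1]
        assert objective_discrimination(sim2, within, valid) == pytest.approx(base)

    def test_empty_class_errors(self):
        sim, within, valid = self._as_matrices([0.9], [0.1])
        with pytest.raises(ValidationError, match="between"):
            objective_discrimination(sim, within | True, valid)
        with pytest.raises(ValidationError, match="within"):
            objective_discrimination(sim, within & False, valid)


class TestPairLabels:
    def test_threshold_and_validity(self, small_library):
        _, truth, identity = small_library
        ids = list(truth["isolate_id"]) + ["missing"]
        within, valid = pair_labels_from_identity(ids, identity)
        n = len(ids)
        assert not valid[:, -1].any()  # unknown isolate invalidates its pairs
        same = truth["species"].to_numpy()
        for i in range(len(same)):
            for j in range(i + 1, len(same)):
                assert within[i, j] == (same[i] == same[j])


class TestLoop2:
    def test_single_iteration(self, small_library):
        spectra, _, identity = small_library
        trace, best = run_loop2(spectra, identity, ParamRanges(), 1, seed=2)
        assert len(trace) == 1

    def test_running_min_non_increasing_and_reproducible(self, small_library):
        spectra, _, identity = small_library
        trace, best = run_loop2(spectra, identity, ParamRanges(), 6, seed=4)
        running = trace["overlap"].cummin()
        assert (np.diff(running) <= 0).all()
        trace2, best2 = run_loop2(spectra, identity, ParamRanges(), 6, seed=4)
        pd.testing.assert_frame_equal(trace, trace2)
        assert best == best2
        assert (trace["total_bins"] >= 0).all()
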