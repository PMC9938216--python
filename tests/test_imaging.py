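"""Trace normalization, peak detection, co-activation null, synchrony, evoked fits."""

import numpy as np
import pytest
from scipy import stats

import silamnet as sn
from silamnet.containers import EventRaster, TraceMatrix
from silamnet.imaging import (
    detect_network_events,
    detect_peaks,
    evoked_response,
    mc_coactivity_threshold,
    normalize_dff,
    pairwise_correlation,
    pairwise_delay,
    split_synchrony_events,
)


def tm(x, fs=2.0, kind="calcium_culture", units="raw"):
    return TraceMatrix(traces=np.atleast_2d(np.asarray(x, float)), fs=fs,
                       kind=kind, units=units)


class TestNormalize:
    def test_constant_trace_maps_to_zero(self):
        d = normalize_dff(tm(np.full((3, 100), 5.0)))
        assert np.allclose(d.traces, 0.0)
        assert d.units == "dff"

    def test_step_recovered_as_fractional_change(self):
        x = np.ones(400)
        x[200:260] = 1.2
        d = normalize_dff(tm(x), baseline_window_s=100.0)
        assert d.traces[0, 225:235].mean() == pytest.approx(0.20, rel=0.01)

    def test_nonpositive_baseline_is_an_error(self):
        x = np.ones(100)
        x[40:60] = -1.0
        with pytest.raises(ValueError):
            normalize_dff(tm(x), baseline_window_s=10.0)

    def test_window_must_cover_three_frames(self):
        with pytest.raises(ValueError):
            normalize_dff(tm(np.ones(100)), baseline_window_s=0.5)


class TestDetectPeaks:
    def test_planted_template_amplitude_recovered_within_one_percent(self):
        cfg = sn.SynthConfig(seed=3, n_rois=5, duration_s=300, trace_noise_sd=0.0,
                             drift_amplitude=0.0, event_rate_hz=0.005,
                             network_event_rate_hz=0.0, coactive_fraction=0.0)
        _, truth, _ = sn.gen_traces(cfg)
        raster = detect_peaks(normalize_dff(sn.gen_traces(cfg)[0]))
        amps = raster.events["amplitude"].to_numpy()
        assert len(amps) == truth.raster.sum()
        np.testing.assert_allclose(amps, cfg.transient_amplitude, rtol=0.01)

    def test_subthreshold_bump_not_detected(self):
        x = np.zeros(200)
        x[100:] = 0.10 * np.exp(-np.arange(100) / 4.0)
        d = tm(x, units="dff")
        raster = detect_peaks(d, min_amplitude=0.15)
        assert raster.raster.sum() == 0

    def test_two_separated_bumps_counted_twice(self):
        x = np.zeros(400)
        for onset in (100, 300):
            x[onset:] += 0.5 * np.exp(-np.arange(400 - onset) / 3.0)
        raster = detect_peaks(tm(x, units="dff"), min_amplitude=0.15)
        assert raster.raster.sum() == 2

    def test_kind_specific_default_thresholds(self):
        x = np.zeros(300)
        x[150:] = 0.05 * np.exp(-np.arange(150) / 3.0)
        assert detect_peaks(tm(x, units="dff", kind="calcium_culture")).raster.sum() == 0
        assert detect_peaks(tm(x, units="dff", kind="glutamate")).raster.sum() == 1

    def test_raw_traces_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(tm(np.ones(50)))


class TestMCThreshold:
    def test_empty_raster_threshold_zero_with_flag(self):
        r = EventRaster(raster=np.zeros((5, 100), bool), fs=2.0)
        res = mc_coactivity_threshold(r, seed=0)
        assert res.threshold == 0 and res.empty_raster

    def test_single_roi_cannot_exceed_one(self):
        raster = np.zeros((1, 200), bool)
        raster[0, [10, 50, 90]] = True
        res = mc_coactivity_threshold(EventRaster(raster=raster, fs=2.0), seed=0)
        assert res.threshold <= 1

    def test_matches_analytic_binomial_tail(self):
        # iid raster: co-active count per frame ~ Binomial(100, 0.01)
        oracle = int(stats.binom.ppf(0.999, 100, 0.01))
        rng = np.random.default_rng(0)
        raster = EventRaster(raster=rng.random((100, 1200)) < 0.01, fs=2.0)
        res = mc_coactivity_threshold(raster, seed=0)
        assert abs(res.threshold - oracle) <= 1

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(7)
        raster = EventRaster(raster=rng.random((40, 500) ) < 0.02, fs=2.0)
        a = mc_coactivity_threshold(raster, seed=42)
        b = mc_coactivity_threshold(raster, seed=42)
        assert a.threshold == b.threshold
        assert a.percentile_value == b.percentile_value

    def test_circular_scheme_preserves_counts(self):
        rng = np.random.default_rng(3)
        raster = EventRaster(raster=rng.random((20, 300)) < 0.03, fs=2.0)
        res = mc_coactivity_threshold(raster, seed=1, scheme="circular")
        assert res.threshold >= 1


class TestNetworkEvents:
    def test_single_global_frame_is_one_event(self):
        raster = np.zeros((10, 100), bool)
        raster[:, 50] = True
        ev = detect_network_events(EventRaster(raster=raster, fs=2.0), threshold=5)
        assert len(ev.events) == 1
        assert ev.events["n_coactive"].iloc[0] == 10

    def test_threshold_above_max_coactivity_gives_no_events(self):
        raster = np.zeros((4, 100), bool)
        raster[:2, 30] = True
        ev = detect_network_events(EventRaster(raster=raster, fs=2.0), threshold=3)
        assert len(ev.events) == 0

    def test_contiguous_run_merged_into_single_event(self):
        raster = np.zeros((6, 100), bool)
        raster[:3, 40] = True
        raster[3:, 41] = True
        ev = detect_network_events(EventRaster(raster=raster, fs=2.0), threshold=3)
        assert len(ev.events) == 1
        assert ev.events["n_coactive"].iloc[0] == 6

    def test_planted_events_recovered_with_expected_size(self):
        cfg = sn.SynthConfig(seed=5)
        tmx, _, times = sn.gen_traces(cfg)
        raster = detect_peaks(normalize_dff(tmx))
        thr = mc_coactivity_threshold(raster, seed=5)
        ev = detect_network_events(raster, max(thr.threshold, 1))
        big = ev.events[ev.events["n_coactive"] > thr.threshold * 2]
        assert len(big) >= 0.9 * len(times)
        expected = int(np.ceil(cfg.coactive_fraction * cfg.n_rois))
        assert big["n_coactive"].mean() == pytest.approx(expected, rel=0.15)


class TestSynchrony:
    def test_duplicated_trace_perfectly_correlated(self, rng):
        x = rng.normal(size=500)
        s = pairwise_correlation(tm(np.vstack([x, x]), units="dff"))
        assert s.pairwise_r[0, 1] == pytest.approx(1.0)

    def test_independent_noise_near_zero_mean_r(self, rng):
        d = tm(rng.normal(size=(10, 10000)), units="dff")
        s = pairwise_correlation(d)
        assert abs(s.mean_r) < 0.02

    def test_constant_trace_excluded(self, rng):
        x = np.vstack([rng.normal(size=300), np.full(300, 2.0), rng.normal(size=300)])
        s = pairwise_correlation(tm(x, units="dff"))
        assert s.excluded_rois == [1]
        assert np.isnan(s.pairwise_r[0, 1])

    def test_mean_r_invariant_to_affine_rescaling(self, rng):
        x = rng.normal(size=(5, 400))
        base = pairwise_correlation(tm(x, units="dff")).mean_r
        x2 = x.copy()
        x2[2] = 3.5 * x2[2] + 10.0
        assert pairwise_correlation(tm(x2, units="dff")).mean_r == pytest.approx(base)

    def test_mean_r_increases_with_coactive_fraction(self):
        means = []
        for cf in (0.1, 0.3, 0.6):
            cfg = sn.SynthConfig(seed=7, coactive_fraction=cf, n_rois=60,
                                 duration_s=300)
            tmx, _, _ = sn.gen_traces(cfg)
            means.append(pairwise_correlation(normalize_dff(tmx)).mean_r)
        assert means[0] < means[1] < means[2]


class TestPairwiseDelay:
    def _raster(self, trains, n_frames=200, fs=10.0):
        r = np.zeros((len(trains), n_frames), bool)
        for i, t in enumerate(trains):
            r[i, t] = True
        return EventRaster(raster=r, fs=fs)

    def test_identical_trains_zero_delay(self):
        md, _ = pairwise_delay(self._raster([[20, 60, 100], [20, 60, 100]]))
        assert md == 0.0

    def test_constant_offset_recovered(self):
        md, _ = pairwise_delay(self._raster([[20, 60, 100, 140], [25, 65, 105, 145]]))
        assert md == pytest.approx(0.5, abs=0.1)

    def test_out_of_window_pair_excluded(self):
        md, mat = pairwise_delay(self._raster([[10], [150]]), window_s=2.1)
        assert np.isnan(mat[0, 1])
        assert np.isnan(md)


class TestSplitSynchrony:
    def _trace_with_peaks(self, amps, n=600, fs=2.0):
        x = np.zeros(n)
        for i, a in enumerate(amps):
            onset = 50 + i * 100
            x[onset:] += a * np.exp(-np.arange(n - onset) / 4.0)
        return x

    def test_all_high_when_above_cut(self):
        out = split_synchrony_events(self._trace_with_peaks([0.3, 0.31, 0.35]), fs=2.0)
        assert len(out["high"]) == 3 and len(out["low"]) == 0

    def test_exact_cut_assigned_low(self):
        x = np.zeros(200)
        x[100] = 0.2  # single-frame peak of exactly the cut amplitude
        out = split_synchrony_events(x, fs=2.0, cut=0.2)
        assert len(out["low"]) == 1 and len(out["high"]) == 0

    def test_mixed_amplitudes_split(self):
        out = split_synchrony_events(self._trace_with_peaks([0.1, 0.4]), fs=2.0)
        assert len(out["high"]) == 1 and len(out["low"]) == 1


class TestEvoked:
    def _trace(self, tau_s=2.0, amp=0.8, fs=20.0, f0=2.0, n=600, stim=100):
        t = np.arange(n) / fs
        x = np.full(n, f0)
        x[stim:] = f0 * (1 + amp * np.exp(-(t[stim:] - t[stim]) / tau_s))
        return x

    def test_decay_half_life_from_tau(self):
        # tau = 2 s -> T1/2 = ln2 * tau = 1.386 s
        er = evoked_response(self._trace(tau_s=2.0), fs=20.0, stim_frame=100)
        assert er.t_half_s == pytest.approx(np.log(2.0) * 2.0, rel=0.02)

    def test_flat_post_stimulus_flags_fit(self):
        x = np.full(400, 3.0)
        er = evoked_response(x, fs=20.0, stim_frame=100)
        assert er.peak_amplitude == pytest.approx(0.0, abs=1e-12)
        assert er.fit_failed and np.isnan(er.t_half_s)

    def test_doubling_amplitude_scales_linearly_leaves_t_half(self):
        e1 = evoked_response(self._trace(amp=0.5), fs=20.0, stim_frame=100)
        e2 = evoked_response(self._trace(amp=1.0), fs=20.0, stim_frame=100)
        assert e2.peak_amplitude == pytest.approx(2 * e1.peak_amplitude, rel=1e-6)
        assert e2.auc == pytest.approx(2 * e1.auc, rel=1e-6)
        assert e2.t_half_s == pytest.approx(e1.t_half_s, rel=1e-3)

    def test_stim_inside_baseline_rejected(self):
        with pytest.raises(ValueError):
            evoked_response(np.ones(200), fs=20.0, stim_frame=30, baseline_frames=50)


class TestNullCalibrationAndRecovery:
    def test_null_fraction_of_suprathreshold_frames_small(self):
        tot_frames = 0
        tot_above = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            raster = EventRaster(raster=rng.random((100, 1200)) < 0.01, fs=2.0)
            res = mc_coactivity_threshold(raster, seed=seed)
            counts = raster.coactive_counts()
            tot_above += int((counts >= res.threshold).sum())
            tot_frames += raster.n_frames
        assert tot_above / tot_frames < 0.005

    def test_planted_network_events_recovered(self):
        planted = recovered = spurious = 0
        for seed in range(10):
            cfg = sn.SynthConfig(seed=seed)  # study-like: 150 ROIs, 60% recruitment
            tmx, _, times = sn.gen_traces(cfg)
            raster = detect_peaks(normalize_dff(tmx))
            thr = mc_coactivity_threshold(raster, seed=seed)
            ev = detect_network_events(raster, max(thr.threshold, 1))
            starts = ev.events["start_frame"].to_numpy() / tmx.fs
            ends = ev.events["end_frame"].to_numpy() / tmx.fs
            matched = np.zeros(len(times), bool)
            for s, e in zip(starts, ends):
                hit = np.flatnonzero((times > s - 2.0) & (times < e + 2.0) & ~matched)
                if len(hit):
                    matched[hit[0]] = True
                else:
                    spurious += 1
            planted += len(times)
            recovered += int(matched.sum())
        assert recovered >= 0.9 * planted
        assert spurious <= 0.1 * (recovered + spurious)
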