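"""Event schedules, the double-gamma HRF, noise generation and run assembly."""

import numpy as np
import pytest

import looplight as ll
from looplight.design import zscore_time
from looplight.errors import InvalidDesignError, InvalidMaskError, InvalidParameterError


class TestSchedule:
    def test_equal_type_counts_per_run(self, rng):
        sched = ll.generate_schedule(12, 25, n_runs=5, rng=rng)
        for r in range(5):
            ev = sched.for_run(r)
            assert len(ev) == 60
            counts = ev["event_type"].value_counts()
            assert (counts == 5).all() and len(counts) == 12

    def test_total_event_conservation(self, rng):
        sched = ll.generate_schedule(15, 50, n_runs=5, rng=rng)
        assert len(sched.events) == 15 * 50

    def test_gaps_follow_isi_set(self, rng):
        sched = ll.generate_schedule(12, 25, n_runs=5, event_duration=1.0, rng=rng)
        for r in range(5):
            onsets = sched.for_run(r)["onset_s"].to_numpy()
            gaps = np.diff(onsets)
            assert np.all(np.isin(gaps, [8.0, 10.0, 12.0]))
            assert (np.diff(onsets) > 0).all()

    def test_indivisible_repetitions_rejected(self, rng):
        with pytest.raises(InvalidDesignError):
            ll.generate_schedule(12, 24, n_runs=5, rng=rng)

    def test_deterministic_under_seed(self):
        a = ll.generate_schedule(12, 25, rng=np.random.default_rng(3))
        b = ll.generate_schedule(12, 25, rng=np.random.default_rng(3))
        assert a.events.equals(b.events)

    def test_tsv_roundtrip(self, tmp_path, rng):
        sched = ll.generate_schedule(6, 10, n_runs=5, rng=rng)
        path = tmp_path / "run0.tsv"
        sched.to_tsv(path, run=0)
        back = ll.EventSchedule.read_run_tsv(path)
        orig = sched.for_run(0)[["onset_s", "duration_s", "event_type"]]
        assert np.allclose(back[["onset_s", "duration_s"]], orig[["onset_s", "duration_s"]])
        assert (back["event_type"].to_numpy() == orig["event_type"].to_numpy()).all()


class TestHRF:
    def test_peak_location_and_normalization(self, hrf):
        t = np.arange(len(hrf.samples)) * hrf.dt
        peak_t = t[np.argmax(hrf.samples)]
        assert 4.0 <= peak_t <= 7.0
        assert hrf.samples.max() == 1.0

    def test_near_zero_at_onset(self, hrf):
        assert abs(hrf.samples[0]) < 1e-6

    def test_undershoot_negative_lobe(self, hrf):
        t = np.arange(len(hrf.samples)) * hrf.dt
        window = hrf.samples[(t >= 12) & (t <= 20)]
        assert window.min() < 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            ll.double_gamma_hrf(ll.HRFParams(peak_dispersion=0.0))
        with pytest.raises(InvalidParameterError):
            ll.double_gamma_hrf(duration=10.0)


class TestNoise:
    def test_zero_parameters_give_zero_volume(self, rng):
        mask = np.ones((4, 4, 4), bool)
        vol = ll.generate_noise(mask, 10, ll.NoiseParams(0.0, 0.0, 0.0, smooth_fwhm_mm=0.0), rng)
        assert not vol.data.any()

    def test_ar1_autocorrelation(self, rng):
        mask = np.ones((3, 3, 3), bool)
        params = ll.NoiseParams(sigma_system=1.0, ar1_coef=0.5, drift_amplitude=0.0, smooth_fwhm_mm=0.0)
        vol = ll.generate_noise(mask, 5000, params, rng)
        x = vol.data[mask]
        xc = x - x.mean(axis=1, keepdims=True)
        ac1 = (xc[:, 1:] * xc[:, :-1]).sum() / (xc**2).sum()
        assert abs(ac1 - 0.5) < 0.05

    def test_unsmoothed_voxels_independent(self, rng):
        mask = np.ones((3, 3, 3), bool)
        params = ll.NoiseParams(1.0, 0.0, 0.0, smooth_fwhm_mm=0.0)
        vol = ll.generate_noise(mask, 2000, params, rng)
        c = np.corrcoef(vol.data[mask])
        off = ~np.eye(c.shape[0], dtype=bool)
        assert np.abs(c[off]).mean() < 0.05

    def test_smoothing_induces_spatial_correlation_but_keeps_scale(self, rng):
        mask = np.ones((8, 8, 8), bool)
        params = ll.NoiseParams(1.0, 0.0, 0.0, smooth_fwhm_mm=6.0, voxel_size_mm=3.0)
        vol = ll.generate_noise(mask, 400, params, rng)
        x = vol.data[mask]
        # neighbors along x correlate
        a = vol.data[3, 4, 4]
        b = vol.data[4, 4, 4]
        assert np.corrcoef(a, b)[0, 1] > 0.3
        assert abs(x.std(axis=1).mean() - 1.0) < 0.1

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(InvalidMaskError):
            ll.generate_noise(np.zeros((3, 3, 3), bool), 10, ll.NoiseParams(), rng)


class TestSimulateRun:
    def _setup(self, psc, small_masks, zero_noise, hrf, zscore, seed=11):
        brain, roi, _ = small_masks
        runs, events = ll.simulate_session(
            6, 10, psc, brain, roi, zero_noise, hrf, participant=0, base_seed=seed,
            n_runs=5, zscore=zscore,
        )
        return brain, roi, runs, events

    def test_zero_noise_no_zscore_equals_pure_signal(self, small_masks, zero_noise, hrf):
        from looplight.design import event_regressors

        from looplight.grid import _rng

        brain, roi, runs, events = self._setup(1.0, small_masks, zero_noise, hrf, zscore=False)
        vol, ev = runs[0], events[0]
        pts = ll.make_circle_points(6)
        emb = ll.make_orthonormal_embedding(int(roi.sum()), _rng(11, "embedding", 0))
        pat = ll.place_patterns(ll.embed_and_scale(pts, emb, 1.0), roi)
        reg = event_regressors(ev, hrf, vol.n_timepoints, vol.tr, 6)
        expected = np.zeros(vol.data.shape)
        coords = np.unravel_index(pat.roi_voxels, brain.shape)
        expected[coords] = (reg @ pat.patterns).T
        assert np.allclose(vol.data, expected, atol=1e-12)

    def test_zscore_normalizes_every_active_voxel(self, small_masks, hrf):
        brain, roi, _ = small_masks
        noise = ll.NoiseParams(1.0, 0.3, 0.2, smooth_fwhm_mm=0.0)
        runs, _ = ll.simulate_session(6, 10, 0.5, brain, roi, noise, hrf, 0, 13, n_runs=5)
        x = runs[0].data[brain]
        assert np.allclose(x.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(x.std(axis=1), 1.0, atol=1e-9)

    def test_constant_series_zscores_to_zero(self):
        mask = np.ones((2, 2, 2), bool)
        data = np.full((2, 2, 2, 5), 3.0)
        assert not zscore_time(data, mask).any()

    def test_linearity_in_signal_amplitude(self, small_masks, hrf, rng):
        """simulate(psc=a) - simulate(psc=0) under the same seed is pure signal."""
        brain, roi, _ = small_masks
        noise = ll.NoiseParams(1.0, 0.3, 0.1, smooth_fwhm_mm=0.0)
        zero_noise = ll.NoiseParams(0.0, 0.0, 0.0, smooth_fwhm_mm=0.0)
        pts = ll.make_circle_points(6)
        emb = ll.make_orthonormal_embedding(int(roi.sum()), rng)
        sched = ll.generate_schedule(6, 10, n_runs=5, rng=rng)
        ev = sched.for_run(0)
        vols = {}
        for psc, np_ in ((0.5, noise), (0.0, noise), ("pure", zero_noise)):
            pat = ll.place_patterns(
                ll.embed_and_scale(pts, emb, 0.5 if psc == "pure" else psc), roi
            )
            vols[psc] = ll.simulate_run(
                ev, pat, hrf, np_, brain, run_duration=sched.run_duration,
                rng=np.random.default_rng(99), zscore=False,
            )
        diff = vols[0.5].data - vols[0.0].data
        assert np.allclose(diff, vols["pure"].data, atol=1e-9)

    def test_masked_out_voxels_stay_zero(self, small_masks, hrf):
        brain, roi, _ = small_masks
        noise = ll.NoiseParams(1.0, 0.2, 0.1, smooth_fwhm_mm=0.0)
        runs, _ = ll.simulate_session(6, 10, 0.5, brain, roi, noise, hrf, 0, 19)
        assert not runs[0].data[~brain].any()
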