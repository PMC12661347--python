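"""Detection: masks, extraction, deconvolution, screening."""

import numpy as np
import pytest

from catrack import detection as det
from catrack import synthetic as syn
from catrack.masks import CellMask

from conftest import masks_from_field


class TestDetectMasks:
    def test_blank_image_no_masks(self):
        assert det.detect_masks(np.zeros((64, 64))) == []

    def test_separated_blobs_found_with_accurate_centroids(self):
        rng = np.random.default_rng(0)
        field = syn.generate_field(20, seed=31, fov_um=(256, 256),
                                   pixel_size_um=(1.0, 1.0), n_planes=1,
                                   min_separation_um=25.0)
        img = syn.render_frame(field, 0, np.ones(field.n_cells))
        img = img + 0.01 * rng.standard_normal(img.shape)
        masks = det.detect_masks(img)
        assert len(masks) == 20
        found = np.array([m.centroid_px for m in masks])
        truth = field.centroids_px()
        for t in truth:
            d = np.sqrt(((found - t) ** 2).sum(axis=1)).min()
            assert d <= 1.0

    def test_small_component_removed(self):
        img = np.zeros((64, 64))
        img[10:11, 10:13] = 1.0  # 3 px^2 blob
        masks = det.detect_masks(img, min_size_px2=5, min_hole_px2=0)
        assert masks == []

    def test_monotone_in_min_size(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(size=(96, 96)) ** 4
        counts = [len(det.detect_masks(img, min_size_px2=s, min_hole_px2=0))
                  for s in (1, 3, 6, 12, 24)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_even_block_rejected(self):
        with pytest.raises(ValueError):
            det.detect_masks(np.zeros((32, 32)), block_px=10)


class TestCountCells:
    def test_matches_ground_truth_on_clean_render(self):
        field = syn.generate_field(30, seed=32, fov_um=(256, 256),
                                   pixel_size_um=(1.0, 1.0), n_planes=1,
                                   min_separation_um=22.0)
        truth = syn.make_session_truth(field, 30, seed=33,
                                       background_amplitude=0.0,
                                       noise_gain=0.0, read_noise_sd=0.002)
        session, _ = syn.render_session(field, truth, 30)
        assert det.count_cells(session) == 30

    def test_empty_field_counts_zero(self):
        field = syn.generate_field(0, seed=1, fov_um=(64, 64),
                                   pixel_size_um=(1.0, 1.0), n_planes=1)
        truth = syn.make_session_truth(field, 5, seed=2, noise_gain=0.0,
                                       background_amplitude=0.0,
                                       read_noise_sd=0.0)
        session, _ = syn.render_session(field, truth, 5)
        assert det.count_cells(session) == 0

    def test_deterministic_across_identical_sessions(self, rendered_session):
        _, _, session, _ = rendered_session
        assert det.count_cells(session) == det.count_cells(session)


class TestExtractComponents:
    def test_raw_trace_proportional_to_known_trace(self):
        # movie = footprint x known trace, no noise
        rng = np.random.default_rng(2)
        trace = 1.0 + rng.uniform(size=100)
        fp = np.zeros((32, 32))
        fp[10:15, 10:15] = rng.uniform(0.5, 1.0, size=(5, 5))
        movie = fp[None] * trace[:, None, None]
        mask = CellMask(pixels=np.argwhere(fp > 0))
        comps, _ = det.extract_components(movie, [mask], gamma=0.8)
        raw = comps[0].raw_trace
        ratio = raw / trace
        assert np.ptp(ratio) / ratio.mean() < 1e-6

    def test_rank1_background_recovered(self):
        rng = np.random.default_rng(3)
        bmap = rng.uniform(0.2, 1.0, size=(24, 24))
        bmap /= bmap.max()
        btrace = 1.0 + 0.5 * np.sin(np.arange(200) / 10.0)
        movie = bmap[None] * btrace[:, None, None]
        comps, bg = det.extract_components(movie, [], gamma=0.8)
        recon = bg.spatial_map[None] * bg.temporal_trace[:, None, None]
        resid = movie - recon
        ev = 1 - resid.var() / movie.var()
        assert ev >= 0.99
        # temporal trace recovered up to scale
        r = np.corrcoef(bg.temporal_trace, btrace)[0, 1]
        assert r > 0.999

    def test_disjoint_cells_traces_independent(self):
        field = syn.generate_field(6, seed=34, fov_um=(96, 96),
                                   pixel_size_um=(1.0, 1.0), n_planes=1,
                                   min_separation_um=30.0)
        truth = syn.make_session_truth(field, 500, seed=35,
                                       spike_rate_hz=0.3,
                                       background_amplitude=0.05)
        session, true_traces = syn.render_session(field, truth, 500)
        masks = masks_from_field(field)
        comps, _ = det.extract_components(session.movie[:, 0], masks)
        for i in range(6):
            for j in range(i + 1, 6):
                r_true = np.corrcoef(true_traces[i], true_traces[j])[0, 1]
                r_rec = np.corrcoef(comps[i].raw_trace,
                                    comps[j].raw_trace)[0, 1]
                assert abs(r_rec - r_true) <= 0.05

    def test_fully_overlapped_mask_flagged(self):
        movie = np.random.default_rng(4).uniform(size=(20, 16, 16)) + 1.0
        big = CellMask(pixels=[(r, c) for r in range(4, 10)
                               for c in range(4, 10)])
        inner = CellMask(pixels=[(6, 6), (6, 7), (7, 6)])
        comps, _ = det.extract_components(movie, [big, inner], gamma=0.8)
        assert "fully_overlapped" in comps[1].flags
        assert comps[1].raw_trace.size == 20


class TestDeconvolveAR1:
    def test_impulse_response_inverted_exactly(self):
        g = 0.5
        trace = g ** np.arange(20)
        den, spk = det.deconvolve_ar1(trace, g, lam=0.0)
        expected = np.zeros(20)
        expected[0] = 1.0
        assert np.abs(spk - expected).max() <= 1e-8
        assert np.abs(den - trace).max() <= 1e-8

    def test_zero_trace_zero_spikes(self):
        den, spk = det.deconvolve_ar1(np.zeros(50), 0.9)
        assert not spk.any() and not den.any()

    @pytest.mark.parametrize("gamma", [0.6, 0.9, 0.95])
    def test_noiseless_multi_spike_roundtrip(self, gamma):
        rng = np.random.default_rng(5)
        s = np.zeros(300)
        idx = rng.choice(300, size=12, replace=False)
        s[idx] = rng.uniform(0.5, 2.0, size=12)
        trace = syn.simulate_calcium(s, gamma)
        den, spk = det.deconvolve_ar1(trace, gamma, lam=0.0)
        assert np.abs(spk - s).max() <= 1e-8

    def test_noisy_two_spike_recovery(self):
        g = 0.9
        s = np.zeros(100)
        s[10], s[50] = 1.0, 0.5
        rng = np.random.default_rng(6)
        trace = syn.simulate_calcium(s, g) + 0.01 * rng.standard_normal(100)
        den, spk = det.deconvolve_ar1(trace, g, lam=0.05)
        found = np.flatnonzero(spk > 0.1)
        assert set(found) == {10, 50}
        assert abs(spk[10] - 1.0) <= 0.1
        assert abs(spk[50] - 0.5) <= 0.05

    def test_denoised_satisfies_ar1_recursion(self):
        rng = np.random.default_rng(7)
        trace = np.maximum(rng.standard_normal(200), 0)
        g = 0.8
        den, spk = det.deconvolve_ar1(trace, g, lam=0.1, debias=False)
        recon = syn.simulate_calcium(spk, g)
        assert np.abs(recon - den).max() <= 1e-8
        assert (spk >= 0).all()

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            det.deconvolve_ar1(np.zeros(5), 1.0)


class TestGammaEstimate:
    def test_recovers_generating_coefficient(self):
        rng = np.random.default_rng(8)
        g = 0.85
        s = (rng.uniform(size=3000) < 0.02) * rng.uniform(0.5, 1.5, 3000)
        trace = syn.simulate_calcium(s, g) + 0.02 * rng.standard_normal(3000)
        est = det.estimate_gamma(trace)
        assert abs(est - g) <= 0.1


class TestEvaluateComponent:
    def _component_from_trace(self, trace, movie_shape=(None, 24, 24)):
        mask = CellMask(pixels=[(r, c) for r in range(10, 14)
                                for c in range(10, 14)])
        n = trace.size
        movie = np.zeros((n, 24, 24))
        fp = mask.to_image((24, 24)).astype(float)
        movie += fp[None] * trace[:, None, None]
        comps, _ = det.extract_components(movie + 1e-3, [mask], gamma=0.85)
        return comps[0], movie + 1e-3

    def test_pure_noise_rarely_scores_above_reject_threshold(self):
        hits = 0
        n_draws = 200
        for seed in range(n_draws):
            rng = np.random.default_rng(1000 + seed)
            noise = rng.gamma(2.0, 0.05, size=400)
            comp, movie = self._component_from_trace(noise)
            snr, _ = det.evaluate_component(comp, movie)
            if snr < 0.5:
                hits += 1
        assert hits >= 0.95 * n_draws

    def test_large_transient_scores_above_accept_threshold(self):
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            noise = rng.gamma(2.0, 0.05, size=400)
            scale = noise.std()
            s = np.zeros(400)
            s[200] = 10 * scale
            trace = noise + syn.simulate_calcium(s, 0.85)
            comp, movie = self._component_from_trace(trace)
            snr, _ = det.evaluate_component(comp, movie)
            assert snr > 1.2

    def test_footprint_identical_to_active_image_gives_r_of_one(self):
        rng = np.random.default_rng(9)
        trace = np.zeros(100)
        trace[40:60] = 2.0
        comp, movie = self._component_from_trace(trace)
        det.evaluate_component(comp, movie)
        assert comp.rvalue == pytest.approx(1.0, abs=1e-6)


class TestClassifyComponents:
    @pytest.mark.parametrize("snr,r,expected", [
        (1.3, 0.2, "accepted"),   # high SNR alone accepts
        (0.4, 0.9, "rejected"),   # low SNR rejects regardless of r
        (0.9, 0.5, "undecided"),  # neither region
        (0.6, 0.9, "accepted"),   # high r alone accepts
        (2.0, 0.05, "rejected"),  # low r rejects regardless of SNR
    ])
    def test_decision_table(self, snr, r, expected):
        assert det.classify_components((snr, r)) == expected

    def test_rejection_dominates_on_grid(self):
        snr = np.linspace(0, 3, 100)
        r = np.linspace(-1, 1, 100)
        for s in snr:
            decisions = det.classify_components([(s, rv) for rv in r])
            for rv, d in zip(r, decisions):
                if s < 0.5 or rv < 0.1:
                    assert d == "rejected"
                elif s > 1.2 or rv > 0.85:
                    assert d == "accepted"
                else:
                    assert d == "undecided"

    def test_misordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            det.classify_components((1.0, 0.5), accept_snr=0.4,
                                    reject_snr=0.5)
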