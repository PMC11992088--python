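import numpy as np
import pytest

from longcal.config import SimulationConfig
from longcal.demons import warp
from longcal.multisession import (align_sessions, build_session_summary,
                                  bv_similarity_score, groupwise_atlas,
                                  local_similarity_weights,
                                  multiscale_align_pair)
from longcal.simulate import blend_fovs, synth_vessel_baseline
from longcal.vessels import enhance_vessels


@pytest.fixture(scope="module")
def vessel_maps():
    cfg_a = SimulationConfig(fov_shape=(64, 80), seed=5)
    cfg_b = SimulationConfig(fov_shape=(64, 80), seed=99)
    img_a = synth_vessel_baseline(cfg_a, np.random.default_rng(5))
    img_b = synth_vessel_baseline(cfg_b, np.random.default_rng(99))
    return img_a, img_b


@pytest.fixture(scope="module")
def pair_summaries(misaligned_pair):
    _, videos, _ = misaligned_pair
    return [build_session_summary(v, fps=10.0, session_id=i)
            for i, v in enumerate(videos)]


def _centroid(img):
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    tot = img.sum()
    return np.array([(img * yy).sum() / tot, (img * xx).sum() / tot])


class TestSessionSummary:
    def test_shapes_consistent_and_deterministic(self, misaligned_pair):
        _, videos, _ = misaligned_pair
        s1 = build_session_summary(videos[0], fps=10.0)
        s2 = build_session_summary(videos[0], fps=10.0)
        assert s1.vessel_proj.values.shape == s1.neuron_proj.values.shape
        np.testing.assert_array_equal(s1.neuron_proj.values, s2.neuron_proj.values)

    def test_neuron_projection_overlaps_true_footprints(self, misaligned_pair):
        cfg, videos, truth = misaligned_pair
        summ = build_session_summary(videos[0], fps=10.0)
        proj = summ.neuron_proj.values
        fp_union = truth.footprints.sum(axis=0).reshape(cfg.fov_shape) > 0.2
        top = proj >= np.percentile(proj, 90)
        from scipy.ndimage import binary_dilation
        near = binary_dilation(fp_union, iterations=2)
        assert (top & near).sum() / top.sum() >= 0.8

    def test_pure_noise_video_has_no_seedable_structure(self):
        from longcal.config import ExtractionConfig
        from longcal.extract import find_seed_pixels, seed_projections
        rng = np.random.default_rng(0)
        noise = rng.normal(10, 1, size=(300, 48, 64))
        corr, pnr, _ = seed_projections(noise - noise.mean(axis=0), ExtractionConfig())
        assert len(find_seed_pixels(corr, pnr, ExtractionConfig())) == 0


class TestBVScore:
    def test_identical_rich_maps_above_threshold(self, vessel_maps):
        bv = enhance_vessels(vessel_maps[0]).values
        assert bv_similarity_score(bv, bv, seed=1).score >= 2.7

    def test_score_formula_recomputable(self, vessel_maps):
        bv_a = enhance_vessels(vessel_maps[0]).values
        bv_b = enhance_vessels(vessel_maps[1]).values
        out = bv_similarity_score(bv_a, bv_b, seed=2)
        recomputed = (out.c_obs - out.c_random.mean()) / out.c_random.std()
        assert out.score == pytest.approx(recomputed)
        assert len(out.c_random) == 100

    def test_independent_maps_near_zero(self, vessel_maps):
        bv_a = enhance_vessels(vessel_maps[0]).values
        bv_b = enhance_vessels(vessel_maps[1]).values
        scores = [bv_similarity_score(bv_a, bv_b, seed=s).score for s in range(20)]
        assert np.mean([abs(s) <= 2 for s in scores]) >= 0.95

    def test_monotone_nonincreasing_in_blend_degradation(self, vessel_maps):
        img_a, img_b = vessel_maps
        bv_a = enhance_vessels(img_a).values
        scores = []
        for w in (1.0, 0.8, 0.6, 0.4, 0.2):
            bv_w = enhance_vessels(blend_fovs(img_a, img_b, w)).values
            scores.append(bv_similarity_score(bv_a, bv_w, seed=3).score)
        assert all(b <= a + 0.3 for a, b in zip(scores, scores[1:]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bv_similarity_score(np.ones((10, 10)), np.ones((10, 10)))


class TestMultiscaleAlign:
    def test_identical_summaries_near_zero_field(self, pair_summaries):
        T = multiscale_align_pair(pair_summaries[0], pair_summaries[0])
        assert np.abs(T).max() < 0.1

    def test_recovers_known_misalignment(self, misaligned_pair, pair_summaries):
        cfg, videos, truth = misaligned_pair
        f1 = truth.misalignment_fields[1]
        T = multiscale_align_pair(pair_summaries[0], pair_summaries[1])
        dists = [np.hypot(*(_centroid(warp(warp(fp, f1), T)) - _centroid(fp)))
                 for fp in truth.footprint_images()]
        assert np.median(dists) < 1.0

    def test_unknown_schedule_rejected(self, pair_summaries):
        with pytest.raises(ValueError):
            multiscale_align_pair(pair_summaries[0], pair_summaries[1],
                                  schedule="bogus")


class TestWeightsAndAtlas:
    def test_identical_sessions_uniform_weights(self, rng):
        proj = rng.random((40, 50))
        W = local_similarity_weights([proj, proj.copy(), proj.copy()])
        for w in W:
            np.testing.assert_allclose(w, 1.0, atol=1e-9)

    def test_noise_session_downweighted(self, vessel_maps, rng):
        bv = enhance_vessels(vessel_maps[0]).values
        noise = rng.random(bv.shape)
        W = local_similarity_weights([bv, bv.copy(), noise])
        assert W[2].mean() < W[0].mean()
        assert W[2].mean() < W[1].mean()

    def test_weights_nonnegative_and_normalized(self, vessel_maps, rng):
        maps = [enhance_vessels(vessel_maps[0]).values,
                enhance_vessels(vessel_maps[1]).values,
                rng.random(vessel_maps[0].shape)]
        W = local_similarity_weights(maps)
        assert all((w >= 0).all() for w in W)
        np.testing.assert_allclose(np.sum(W, axis=0), len(maps), atol=1e-9)

    def test_two_sessions_uniform_weights_atlas_formula(self, rng):
        from longcal.simulate import gradient_gaussian_field
        f21 = gradient_gaussian_field((30, 40), 8.0, 2.0, rng)
        f12 = gradient_gaussian_field((30, 40), 8.0, 2.0, rng)
        sol = groupwise_atlas({(1, 0): f21, (0, 1): f12}, n_sessions=2)
        np.testing.assert_allclose(sol.to_atlas[0], -f21 / 2, atol=1e-12)
        np.testing.assert_allclose(sol.to_atlas[1], -f12 / 2, atol=1e-12)

    def test_zero_fields_zero_atlas(self):
        z = np.zeros((2, 20, 20))
        sol = groupwise_atlas({(0, 1): z, (1, 0): z, (0, 2): z, (2, 0): z,
                               (1, 2): z, (2, 1): z}, n_sessions=3)
        for f in sol.to_atlas:
            assert not f.any()

    def test_missing_pair_named(self):
        z = np.zeros((2, 10, 10))
        with pytest.raises(KeyError, match="1->0"):
            groupwise_atlas({(0, 1): z}, n_sessions=2)

    def test_atlas_centering_with_uniform_weights(self, rng):
        from longcal.simulate import gradient_gaussian_field
        N = 3
        fields = {}
        for s in range(N):
            for i in range(N):
                if i != s:
                    if (s, i) in fields:
                        fields[(i, s)] = -fields[(s, i)]
                    else:
                        fields[(i, s)] = gradient_gaussian_field((30, 40), 10.0,
                                                                 2.0, rng)
        sol = groupwise_atlas(fields, n_sessions=N)
        mean_field = np.mean(sol.to_atlas, axis=0)
        assert np.abs(mean_field).max() < 0.1


class TestAlignSessions:
    def test_identical_baselines_bv_mode_no_alerts(self, misaligned_pair):
        _, videos, _ = misaligned_pair
        aligned, atlas, report = align_sessions(videos, seed=0)
        assert report["mode"] == "bv+neuron"
        assert atlas.mode == "bv+neuron"
        assert len(aligned) == 2 and aligned[0].shape == videos[0].shape
        # report contract: per-pair scores, mode, and alignment metrics
        assert set(report) >= {"pair_scores", "mode", "alerts",
                               "pre_alignment", "post_alignment"}
        assert "crispness" in report["post_alignment"]

    def test_post_alignment_correlation_improves(self, misaligned_pair):
        _, videos, _ = misaligned_pair
        _, _, report = align_sessions(videos, seed=0)
        assert (report["post_alignment"]["spatial_correlation"] >
                report["pre_alignment"]["spatial_correlation"])

    def test_vessel_free_baselines_fall_back_to_neuron_only(self):
        cfg = SimulationConfig(fov_shape=(80, 96), n_neurons=25,
                               frames_per_session=250, n_sessions=2,
                               n_vessel_branches=0, misalign_amplitude_um=6.0,
                               seed=11)
        from longcal.simulate import render_sessions
        videos, _ = render_sessions(cfg)
        _, atlas, report = align_sessions(videos, seed=0)
        assert report["mode"] == "neuron-only"
        assert len(report["alerts"]) >= 1

    def test_single_session_rejected(self, misaligned_pair):
        _, videos, _ = misaligned_pair
        with pytest.raises(ValueError):
            align_sessions(videos[:1])
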