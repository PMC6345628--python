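"""Ground-truth guarantees of the synthetic scene/cohort/movie generators."""

import numpy as np
import pandas as pd
import pytest

import filomap as fm
from filomap.errors import ParameterError


def polyline_length(vertices):
    """Independent brute-force arc-length summation."""
    return float(sum(
        np.hypot(x1 - x0, y1 - y0)
        for (x0, y0), (x1, y1) in zip(vertices[:-1], vertices[1:])
    ))


class TestGenerateTraces:
    def test_zero_curvature_gives_straight_trace_of_exact_length(self):
        (trace,) = fm.generate_traces(1, (2.0, 2.0), pixel_size_um=0.04,
                                      curvature=0.0, seed=0)
        v = trace.vertices
        assert len(v) == 50
        # collinearity: all cross products of consecutive steps vanish
        steps = np.diff(v, axis=0)
        cross = steps[:-1, 0] * steps[1:, 1] - steps[:-1, 1] * steps[1:, 0]
        assert np.allclose(cross, 0.0, atol=1e-9)
        assert polyline_length(v) * trace.pixel_size_um == pytest.approx(2.0)

    def test_seed_determinism(self):
        a = fm.generate_traces(200, (1, 5), seed=7)
        b = fm.generate_traces(200, (1, 5), seed=7)
        assert all(np.array_equal(x.vertices, y.vertices) for x, y in zip(a, b))

    def test_arc_lengths_within_range_by_independent_summation(self):
        traces = fm.generate_traces(200, (1, 5), seed=7)
        for t in traces:
            length = polyline_length(t.vertices) * t.pixel_size_um
            assert 1.0 - 1e-9 <= length <= 5.0 + 1e-9
            assert length == pytest.approx(t.arc_length_um)

    @pytest.mark.parametrize("n,rng_um", [(0, (1, 5)), (-3, (1, 5)),
                                          (5, (0.1, 5)), (5, (3, 2))])
    def test_invalid_parameters_rejected(self, n, rng_um):
        with pytest.raises(ParameterError):
            fm.generate_traces(n, rng_um)


def _straight_trace(y=100.0, x0=140.0, x1=240.0, px=0.04):
    n = int(x1 - x0) + 1
    v = np.stack([np.linspace(x0, x1, n), np.full(n, y)], axis=1)
    return fm.FilopodiumTrace("t0", v, px)


class TestRenderScene:
    def test_uniform_class_constant_along_trace(self):
        trace = _straight_trace()
        scene = fm.render_scene([trace], fm.localization_class("uniform", detection_prob=1.0),
                                noise=fm.NoiseParams.off(), seed=0)
        prof = fm.sample_profile(scene.image, trace, require_normalized=False)
        poi = prof.intensities["poi"]
        assert poi.max() - poi.min() <= 1.0

    def test_absent_class_leaves_background_only(self):
        trace = _straight_trace()
        cls = fm.localization_class("absent", detection_prob=0.0)
        scene = fm.render_scene([trace], cls, noise=fm.NoiseParams.off(), seed=0)
        prof = fm.sample_profile(scene.image, trace, require_normalized=False)
        assert np.all(np.abs(prof.intensities["poi"] -
                             prof.intensities["poi"][0]) <= 1.0)
        assert prof.intensities["poi"].max() <= fm.IntensityParams().background + 1

    def test_tip_fold_recovered_by_direct_pixel_sampling(self, noisefree_tip_scene):
        scene = noisefree_tip_scene
        for trace in scene.traces[:4]:
            prof = fm.sample_profile(scene.image, trace, require_normalized=False)
            v = prof.intensities["poi"]
            k = max(1, int(round(0.15 * len(v))))
            ratio = v[:k].mean() / v[k:].mean()
            assert ratio == pytest.approx(4.0, rel=0.05)

    def test_myo10_punctum_sits_at_each_tip(self, noisefree_tip_scene):
        scene = noisefree_tip_scene
        myo = scene.image.channel("myo10").astype(float)
        for trace in scene.traces:
            x, y = trace.vertices[0]
            assert myo[int(round(y)), int(round(x))] > 20000

    def test_one_truth_record_per_trace(self, noisefree_tip_scene):
        assert len(noisefree_tip_scene.truth) == len(noisefree_tip_scene.traces)

    def test_out_of_bounds_trace_rejected(self):
        v = np.array([[500.0, 600.0], [520.0, 600.0]])
        trace = fm.FilopodiumTrace("oob", v, 0.04)
        with pytest.raises(fm.GeometryError):
            fm.render_scene([trace], fm.localization_class("uniform"),
                            image_shape=(512, 512))

    def test_seed_determinism_with_noise(self):
        trace = _straight_trace()
        cls = fm.localization_class("uniform")
        a = fm.render_scene([trace], cls, noise=fm.NoiseParams(), seed=3)
        b = fm.render_scene([trace], cls, noise=fm.NoiseParams(), seed=3)
        assert np.array_equal(a.image.data, b.image.data)


class TestBinnedCohort:
    def test_uniform_full_detection_gives_identical_flat_profiles(self):
        cohort = fm.generate_binned_cohort(
            100, fm.localization_class("uniform", detection_prob=1.0), seed=0)
        first = cohort.profiles[0].bins
        assert np.ptp(first) == 0.0
        assert all(np.array_equal(b.bins, first) for b in cohort.profiles)

    def test_positive_fraction_matches_binomial_oracle(self):
        p = 0.3
        cohort = fm.generate_binned_cohort(
            1000, fm.localization_class("uniform", detection_prob=p), seed=11)
        frac = sum(fm.is_positive(b) for b in cohort.profiles) / 1000
        sd = np.sqrt(p * (1 - p) / 1000)
        assert abs(frac - p) <= 3 * sd

    @pytest.mark.parametrize("fold", [2.0, 0.5, 3.5])
    def test_noise_free_tip_fold_exact_round_trip(self, fold):
        name = "tip_enriched" if fold > 1 else "shaft_enriched"
        cohort = fm.generate_binned_cohort(
            100, fm.localization_class(name, tip_fold=fold, detection_prob=1.0),
            noise_sd=0.0, seed=2)
        for b in cohort.profiles:
            assert fm.enrichment_ratio(b) == pytest.approx(fold, abs=1e-12)

    def test_seed_determinism(self):
        cls = fm.localization_class("shaft_subdomain")
        a = fm.generate_binned_cohort(50, cls, noise_sd=1000, seed=9)
        b = fm.generate_binned_cohort(50, cls, noise_sd=1000, seed=9)
        assert all(np.array_equal(x.bins, y.bins)
                   for x, y in zip(a.profiles, b.profiles))


class TestTipMovie:
    def test_single_stationary_spot_in_every_frame(self):
        stack, truth = fm.generate_tip_movie(
            1, fm.LifetimeMix(stable_fraction=1.0, mean_stable_s=1e7),
            n_frames=8, drift_um_per_frame=0.0, birth_window_frac=0.0, seed=4)
        assert truth.frame.nunique() == 8
        peaks = [np.unravel_index(np.argmax(fr), fr.shape) for fr in stack]
        assert all(p == peaks[0] for p in peaks)
        assert all(np.array_equal(fr, stack[0]) for fr in stack)

    def test_seed_determinism(self):
        a, _ = fm.generate_tip_movie(10, n_frames=12, seed=13)
        b, _ = fm.generate_tip_movie(10, n_frames=12, seed=13)
        assert np.array_equal(a, b)

    def test_lifetime_sample_mean_oracle(self):
        mix = fm.LifetimeMix(stable_fraction=1.0, mean_stable_s=60.0)
        _, truth = fm.generate_tip_movie(50, mix, n_frames=400,
                                         frame_interval_s=5.0, seed=17)
        drawn = truth.groupby("track_id").drawn_lifetime_s.first().to_numpy()
        se = drawn.std(ddof=1) / np.sqrt(len(drawn))
        assert abs(drawn.mean() - 60.0) <= 3 * se

    def test_truth_track_count_and_drift_bound(self):
        drift = 0.3
        _, truth = fm.generate_tip_movie(20, n_frames=30,
                                         drift_um_per_frame=drift, seed=3)
        assert truth.track_id.nunique() == 20
        for _, g in truth.groupby("track_id"):
            g = g.sort_values("frame")
            steps = np.hypot(np.diff(g.x_um), np.diff(g.y_um))
            assert np.all(steps <= drift + 1e-9)

    def test_density_warning_still_renders(self):
        with pytest.warns(UserWarning, match="density"):
            stack, truth = fm.generate_tip_movie(
                400, n_frames=3, image_shape=(64, 64), seed=1)
        assert stack.shape == (3, 64, 64)
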