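"""ROA detection: stabilization, smoothing, thresholds, labeling, filtering."""

import numpy as np
import pytest

from astroca import roa, synthetic
from astroca.config import DetectionParams, SimulationConfig
from astroca.datatypes import CompartmentMap, Movie

from _oracles import flood_fill_label


def movie_of(data, **kw):
    return Movie(np.asarray(data, dtype=float), **kw)


class TestVarianceStabilize:
    def test_square_root_values(self):
        m = movie_of(np.full((3, 2, 2), 4.0))
        m.data[1, 0, 0] = 2.0
        out = roa.variance_stabilize(m)
        assert out.data[0, 0, 0] == 2.0
        assert out.data[1, 0, 0] == pytest.approx(np.sqrt(2.0))
        assert roa.variance_stabilize(movie_of(np.zeros((3, 2, 2)))).data.max() == 0.0

    def test_negative_input_names_frame(self):
        data = np.ones((4, 2, 2))
        data[2, 1, 1] = -1.0
        with pytest.raises(ValueError, match="frame.*2"):
            roa.variance_stabilize(movie_of(data))

    def test_metadata_preserved(self):
        m = movie_of(np.ones((3, 2, 2)), fps=15.0, um_per_pixel=0.67)
        out = roa.variance_stabilize(m)
        assert (out.fps, out.um_per_pixel) == (15.0, 0.67)


class TestSmooth:
    def test_constant_movie_unchanged_everywhere(self):
        m = movie_of(np.full((30, 8, 8), 7.0))
        out = roa.smooth(m, DetectionParams())
        np.testing.assert_allclose(out.data, 7.0)

    def test_impulse_mass_conserved_in_interior(self):
        data = np.zeros((5, 21, 21))
        data[2, 10, 10] = 1.0
        out = roa.smooth(movie_of(data), DetectionParams(t_smooth_frames=1, s_smooth_pixels=2))
        np.testing.assert_allclose(out.data[2].sum(), 1.0)

    def test_window_longer_than_movie_rejected(self):
        with pytest.raises(ValueError, match="window"):
            roa.smooth(movie_of(np.ones((5, 4, 4))), DetectionParams(t_smooth_frames=14))


class TestThresholds:
    def test_constant_movie_thresholds_at_value(self):
        out = roa.estimate_thresholds(movie_of(np.full((6, 3, 3), 5.0)), DetectionParams())
        np.testing.assert_allclose(out, 5.0)

    def test_two_pixel_hand_computation(self):
        # traces [0,0,0,0] and [0,2,0,2]: per-pixel sample SDs {0, 1.1547},
        # median SD 0.5774; baselines {0, 1}; thresholds with k=4
        data = np.zeros((4, 1, 2))
        data[:, 0, 1] = [0, 2, 0, 2]
        out = roa.estimate_thresholds(movie_of(data), DetectionParams(k_threshold=4.0))
        np.testing.assert_allclose(out[0], [2.309401, 3.309401], atol=1e-6)

    def test_doubling_k_doubles_margin(self, rng):
        m = movie_of(rng.random((10, 4, 4)))
        base = np.median(m.data, axis=0)
        t1 = roa.estimate_thresholds(m, DetectionParams(k_threshold=2.0))
        t2 = roa.estimate_thresholds(m, DetectionParams(k_threshold=4.0))
        np.testing.assert_allclose(t2 - base, 2 * (t1 - base))

    def test_too_short_movie_rejected(self):
        with pytest.raises(ValueError):
            roa.estimate_thresholds(movie_of(np.ones((2, 2, 2))), DetectionParams())


class TestBinarize:
    def test_tie_is_inactive_and_shapes_checked(self):
        m = movie_of(np.full((3, 2, 2), 1.0))
        assert not roa.binarize(m, np.full((2, 2), 1.0)).any()
        with pytest.raises(ValueError, match="shape"):
            roa.binarize(m, np.ones((3, 3)))

    def test_raising_k_shrinks_active_set(self, rng):
        m = movie_of(rng.random((20, 6, 6)))
        masks = [
            roa.binarize(m, roa.estimate_thresholds(m, DetectionParams(k_threshold=k)))
            for k in (0.5, 1.0, 2.0)
        ]
        assert np.all(masks[2] <= masks[1]) and np.all(masks[1] <= masks[0])


class TestLabelEvents:
    def test_empty_mask(self):
        assert len(roa.label_events(np.zeros((4, 4, 4), dtype=bool))) == 0

    def test_diagonal_neighbors_depend_on_connectivity(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert len(roa.label_events(mask, connectivity=26)) == 1
        assert len(roa.label_events(mask, connectivity=6)) == 2

    def test_block_event_fields(self):
        mask = np.zeros((10, 5, 5), dtype=bool)
        mask[2:7, 1:4, 1:4] = True
        (ev,) = roa.label_events(mask, connectivity=26).events
        assert (ev.t_onset, ev.t_offset, ev.duration) == (2, 6, 5)
        assert ev.max_frame_area == 9
        np.testing.assert_array_equal(ev.frame_areas, [9] * 5)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_on_random_masks(self, connectivity, rng):
        for _ in range(40):
            mask = rng.random((6, 6, 6)) < rng.uniform(0.1, 0.5)
            got = roa.label_events(mask, connectivity)
            want = flood_fill_label(mask, connectivity)
            got_sets = sorted(
                [frozenset(map(tuple, ev.voxels.tolist())) for ev in got], key=sorted
            )
            want_sets = sorted([frozenset(c) for c in want], key=sorted)
            assert got_sets == want_sets


class TestFilterEvents:
    def make(self, mask):
        return roa.label_events(mask, 26)

    def test_short_event_removed_boundary_retained(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[0:2, 0:3, 0:3] = True  # 2 frames -> removed
        out = roa.filter_events(self.make(mask), DetectionParams())
        assert len(out) == 0
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[0:3, 0, 0:3] = True  # 3 frames, 3 px/frame -> retained
        out = roa.filter_events(self.make(mask), DetectionParams())
        assert len(out) == 1

    def test_long_thin_event_removed_by_area_rule(self):
        mask = np.zeros((12, 4, 4), dtype=bool)
        mask[0:10, 1, 1] = True  # 10 frames but 1 px/frame
        assert len(roa.filter_events(self.make(mask), DetectionParams())) == 0

    def test_matches_explicit_filter_on_random_masks(self, rng):
        params = DetectionParams()
        for _ in range(25):
            mask = rng.random((7, 7, 7)) < 0.35
            events = self.make(mask)
            kept = roa.filter_events(events, params)
            expect = [
                ev
                for ev in events
                if ev.duration >= 3 and ev.max_frame_area >= 3
            ]
            assert len(kept) == len(expect)
            for ev in kept:
                assert ev.duration >= 3 and ev.max_frame_area >= 3


class TestDensityAndFrequency:
    def test_counting_example(self, small_cmap):
        mask = np.zeros((3, 16, 16), dtype=bool)
        mask[1, 2:4, 2] = True  # 2 of 16 soma pixels
        d = roa.roa_density(mask, small_cmap, "soma")
        assert d.values[1] == pytest.approx(100 * 2 / 16)
        assert d.values[0] == 0.0

    def test_empty_region_rejected(self, small_cmap):
        with pytest.raises(ValueError, match="endfoot"):
            roa.roa_density(np.zeros((2, 16, 16), dtype=bool), small_cmap, "endfoot")

    def test_union_density_is_pixel_weighted_mean(self, small_cmap, rng):
        mask = rng.random((5, 16, 16)) < 0.3
        soma = roa.roa_density(mask, small_cmap, "soma")
        proc = roa.roa_density(mask, small_cmap, "process")
        union_mask = small_cmap.region_mask("soma") | small_cmap.region_mask("process")
        n_union = union_mask.sum()
        expect = (
            soma.values * soma.n_region_pixels + proc.values * proc.n_region_pixels
        ) / n_union
        got = 100.0 * mask[:, union_mask].sum(axis=1) / n_union
        np.testing.assert_allclose(got, expect)

    def test_density_invariant_to_label_permutation(self, rng):
        labels = np.ones((8, 8), dtype=int)
        labels[0:4] = 2
        cmap1 = CompartmentMap(labels, {1: "fov", 2: "soma"})
        cmap2 = CompartmentMap(np.where(labels == 2, 5, 9), {9: "fov", 5: "soma"})
        mask = rng.random((4, 8, 8)) < 0.4
        np.testing.assert_array_equal(
            roa.roa_density(mask, cmap1, "soma").values,
            roa.roa_density(mask, cmap2, "soma").values,
        )

    def test_frequency_units_and_normalization(self, small_cmap):
        # 3 events with onsets inside a 1-minute window in a 100 um^2 region:
        # 16x16 fov at 0.625 um/px -> 256 px * 0.390625 um^2 = 100 um^2
        mask = np.zeros((1800, 16, 16), dtype=bool)
        for onset in (0, 300, 600):
            mask[onset : onset + 3, 4:7, 4:7] = True
        roas = roa.label_events(mask, 26)
        f = roa.roa_frequency(roas, small_cmap, "fov", (0, 60), fps=30.0, um_per_pixel=0.625)
        assert f == pytest.approx(3.0)
        f2 = roa.roa_frequency(roas, small_cmap, "fov", (0, 30), fps=30.0, um_per_pixel=0.625)
        assert f2 == pytest.approx(6.0)
        assert roa.roa_frequency(roas, small_cmap, "fov", (120, 180), fps=30.0, um_per_pixel=0.625) == 0.0
        with pytest.raises(ValueError, match="window"):
            roa.roa_frequency(roas, small_cmap, "fov", (10, 10))


class TestDetect:
    def test_constant_movie_yields_nothing(self, small_cmap):
        m = movie_of(np.full((40, 16, 16), 50.0))
        roas, densities = roa.detect(m, small_cmap, DetectionParams(t_smooth_frames=5))
        assert len(roas) == 0
        assert all(np.all(d.values == 0) for d in densities.values())

    def test_noiseless_events_recovered_exactly(self, quick_sim):
        movie, truth = synthetic.generate_movie(quick_sim)
        cmap = synthetic.generate_compartments(quick_sim.frame_shape)
        params = DetectionParams(t_smooth_frames=1, s_smooth_pixels=0)
        roas, _ = roa.detect(movie, cmap, params)
        assert len(roas) == quick_sim.n_events
        gt, det = truth.event_mask(movie.data.shape), roas.mask()
        assert (gt & det).sum() / (gt | det).sum() > 0.99

    def test_retained_events_respect_filters(self, quick_sim):
        movie, _ = synthetic.generate_movie(quick_sim)
        cmap = synthetic.generate_compartments(quick_sim.frame_shape)
        roas, densities = roa.detect(movie, cmap, DetectionParams(t_smooth_frames=5, s_smooth_pixels=1))
        for ev in roas:
            assert ev.duration >= 3 and ev.max_frame_area >= 3
        for d in densities.values():
            assert np.all((0 <= d.values) & (d.values <= 100))

    def test_noisy_movie_voxel_f1(self):
        # SNR 10 (amplitude 10, noise SD 1): temporal smoothing only, with
        # the threshold matched to the half-amplitude ground-truth contrast.
        cfg = SimulationConfig(seed=3, duration=40.0, n_events=5, noise_sigma=1.0)
        movie, truth = synthetic.generate_movie(cfg)
        cmap = synthetic.generate_compartments(cfg.frame_shape)
        probe = DetectionParams(t_smooth_frames=5, s_smooth_pixels=0, k_threshold=1.0)
        smoothed = roa.smooth(roa.variance_stabilize(movie), probe)
        sigma = np.median(np.std(smoothed.data, axis=0, ddof=1))
        target = np.sqrt(cfg.baseline_level + cfg.event_amplitude / 2) - np.sqrt(cfg.baseline_level)
        params = DetectionParams(
            t_smooth_frames=5, s_smooth_pixels=0, k_threshold=float(target / sigma)
        )
        roas, _ = roa.detect(movie, cmap, params)
        gt, det = truth.event_mask(movie.data.shape), roas.mask()
        tp = (gt & det).sum()
        f1 = 2 * tp / (gt.sum() + det.sum())
        assert len(roas) == cfg.n_events
        assert f1 >= 0.8
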