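import numpy as np
import pytest

from iterstereo.iterative import (
    build_mask,
    build_stage_masks,
    merge_masks,
    refine_single_pair,
    run_sequence_detailed,
    stage_radii,
    valid_entry_count,
)
from iterstereo.params import MatchParams
from iterstereo.synthetic import SceneSpec, generate
from iterstereo.types import STAGES, DisparityMap, DisparityRangeMask, INVALID


class TestStageRadii:
    def test_published_configuration(self):
        # edge radius 7, box radius 7: first x-stage window is widest
        assert stage_radii(7, 7, "x1") == (14, 21)
        assert stage_radii(7, 7, "y2") == (7, 7)

    def test_all_stage_formulas(self):
        er, br = 3, 5
        assert stage_radii(er, br, "x1") == (er + br, er + 2 * br)
        assert stage_radii(er, br, "y1") == (er + br, er + br)
        assert stage_radii(er, br, "x2") == (er, er + br)
        assert stage_radii(er, br, "y2") == (er, er)

    @pytest.mark.parametrize("er,br", [(1, 1), (3, 7), (7, 3), (9, 9)])
    def test_radii_shrink_monotonically_from_x1_to_y2(self, er, br):
        rx1, ry1 = stage_radii(er, br, "x1")
        rx4, ry4 = stage_radii(er, br, "y2")
        assert rx1 >= rx4 and ry1 >= ry4

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            stage_radii(7, 7, "z9")


class TestBuildMask:
    def params(self, **kw):
        defaults = dict(er=2, br=2, d_offset=2, d_min_global=0, d_max_global=30)
        defaults.update(kw)
        return MatchParams(**defaults)

    def test_constant_map_gives_constant_band(self):
        prev = DisparityMap(np.full((10, 12), 10.0), np.ones((10, 12), dtype=bool))
        mask = build_mask(prev, "y2", self.params())
        assert np.all(mask.lo == 8) and np.all(mask.hi == 12)

    def test_step_map_window_straddles_both_levels(self):
        d = np.where(np.tile(np.arange(20) < 10, (8, 1)), 5.0, 20.0)
        prev = DisparityMap(d, np.ones((8, 20), dtype=bool))
        mask = build_mask(prev, "y2", self.params())
        # pixels near the step see both levels
        assert mask.lo[4, 10] == 3 and mask.hi[4, 10] == 22
        # pixels far from the step see only their own level
        assert mask.lo[4, 0] == 3 and mask.hi[4, 0] == 7
        assert mask.lo[4, 19] == 18 and mask.hi[4, 19] == 22

    def test_matches_brute_force_window_scan(self, rng):
        h, w = 9, 11
        prev = DisparityMap(rng.random((h, w)) * 20, np.ones((h, w), dtype=bool))
        params = self.params()
        for stage in STAGES:
            rx, ry = stage_radii(params.er, params.br, stage)
            mask = build_mask(prev, stage, params)
            for y in range(h):
                for x in range(w):
                    win = prev.d[max(0, y - ry) : y + ry + 1, max(0, x - rx) : x + rx + 1]
                    lo = np.clip(np.floor(win.min()) - 2, 0, 30)
                    hi = np.clip(np.ceil(win.max()) + 2, 0, 30)
                    assert mask.lo[y, x] == lo and mask.hi[y, x] == hi

    def test_containment_of_previous_disparity(self, rng):
        prev = DisparityMap(rng.random((8, 10)) * 25, np.ones((8, 10), dtype=bool))
        for stage in STAGES:
            mask = build_mask(prev, stage, self.params())
            assert np.all(mask.lo <= prev.d) and np.all(prev.d <= mask.hi)

    def test_invalid_pixels_rejected(self):
        d = np.full((4, 4), 5.0)
        valid = np.ones((4, 4), dtype=bool)
        d[2, 2], valid[2, 2] = INVALID, False
        with pytest.raises(ValueError):
            build_mask(DisparityMap(d, valid), "y2", self.params())


class TestMergeMasks:
    def test_idempotent_on_identical_masks(self):
        m = DisparityRangeMask(np.full((4, 4), 3), np.full((4, 4), 9), "x1")
        merged = merge_masks([m, m, m, m])
        assert np.array_equal(merged.lo, m.lo) and np.array_equal(merged.hi, m.hi)

    def test_envelope_contains_every_input(self, rng):
        masks = []
        for stage in STAGES:
            lo = rng.integers(0, 10, size=(5, 6))
            masks.append(DisparityRangeMask(lo, lo + rng.integers(0, 8, size=(5, 6)), stage))
        merged = merge_masks(masks)
        for m in masks:
            assert np.all(merged.lo <= m.lo) and np.all(m.hi <= merged.hi)

    def test_per_pixel_exhaustive_containment(self, rng):
        masks = []
        for stage in STAGES:
            lo = rng.integers(0, 6, size=(4, 5))
            masks.append(DisparityRangeMask(lo, lo + rng.integers(0, 5, size=(4, 5)), stage))
        merged = merge_masks(masks)
        for y in range(4):
            for x in range(5):
                for d in range(0, 12):
                    in_any = any(m.lo[y, x] <= d <= m.hi[y, x] for m in masks)
                    in_env = merged.lo[y, x] <= d <= merged.hi[y, x]
                    if in_any:
                        assert in_env

    def test_shape_mismatch_rejected(self):
        a = DisparityRangeMask(np.zeros((3, 3), int), np.ones((3, 3), int))
        b = DisparityRangeMask(np.zeros((3, 4), int), np.ones((3, 4), int))
        with pytest.raises(ValueError):
            merge_masks([a, b])


def seq_params(**kw):
    defaults = dict(er=3, br=3, median_radius=3, sigma_g=3.0,
                    d_min_global=0, d_max_global=24, warmup_frames=1)
    defaults.update(kw)
    return MatchParams(**defaults)


class TestRunSequence:
    def test_static_scene_reaches_bitwise_fixed_point(self):
        spec = SceneSpec(height=32, width=40, surface="step_pyramid", d_base=8,
                         d_amplitude=4, n_frames=5, seed=2)
        frames = generate(spec)
        results = list(run_sequence_detailed((f.pair for f in frames), seq_params()))
        # after warm-up and one masked settling step the map is invariant
        for i in (3, 4):
            assert np.array_equal(results[i].disparity.d, results[i - 1].disparity.d)

    def test_drifting_scene_stays_inside_merged_mask(self):
        spec = SceneSpec(height=32, width=40, surface="plane", d_base=6, d_amplitude=2,
                         n_frames=5, drift_per_frame=1.0, seed=3)
        frames = generate(spec)
        params = seq_params(d_offset=2)
        prev = None
        for i, result in enumerate(run_sequence_detailed((f.pair for f in frames), params)):
            if prev is not None and i >= params.warmup_frames:
                masks = build_stage_masks(prev.disparity, params)
                env = merge_masks([masks[s] for s in STAGES])
                gt = frames[i].gt_disparity
                assert np.all((env.lo <= gt) & (gt <= env.hi))
            err = np.abs(result.disparity.d - frames[i].gt_disparity)[~frames[i].occluded]
            assert err.mean() < 0.5
            prev = result

    def test_masked_frames_do_less_work_than_full_range(self):
        spec = SceneSpec(height=32, width=40, surface="plane", d_base=8, d_amplitude=4, seed=5)
        frame = generate(spec)[0]
        params = seq_params()
        full_entries = (params.d_max_global - params.d_min_global + 1) * 32 * 40
        results = list(run_sequence_detailed([frame.pair, frame.pair], params))
        masks = build_stage_masks(results[0].disparity, params)
        assert valid_entry_count([masks[s] for s in STAGES]) < full_entries

    def test_single_pair_refinement_matches_manual_iteration(self):
        from iterstereo.pipeline import match_pair_detailed

        spec = SceneSpec(height=24, width=32, surface="plane", d_base=8, d_amplitude=4, seed=6)
        frame = generate(spec)[0]
        params = seq_params(warmup_frames=0)
        refined = refine_single_pair(frame.pair, params, iterations=1)
        first = match_pair_detailed(frame.pair, params)
        masks = build_stage_masks(first.disparity, params)
        right_masks = build_stage_masks(first.right_disparity, params)
        manual = match_pair_detailed(frame.pair, params, masks, right_masks)
        assert np.array_equal(refined.disparity.d, manual.disparity.d)

    def test_scene_cut_falls_back_to_full_range(self, rng):
        # frame 2 is unrelated to frame 1: the inconsistency spike on the
        # cut frame must disable masks for the frame after it
        spec_a = SceneSpec(height=24, width=32, surface="plane", d_base=4, d_amplitude=2,
                           seed=7, texture="noise")
        spec_b = SceneSpec(height=24, width=32, surface="plane", d_base=18, d_amplitude=2,
                           seed=99, texture="noise", d_max_global=24)
        fa = generate(spec_a)[0]
        fb = generate(spec_b)[0]
        params = seq_params(warmup_frames=1, cut_fallback_rate=0.2)
        results = list(
            run_sequence_detailed([fa.pair, fa.pair, fb.pair, fb.pair], params)
        )
        # last frame (post-cut, full range restored) recovers the new scene
        err = np.abs(results[3].disparity.d - fb.gt_disparity)[~fb.occluded]
        assert err.mean() < 0.5
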