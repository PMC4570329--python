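"""Keypoint matching, homography fitting, overlap and double-count logic."""

import numpy as np
import pytest

from rowcount.counting import LocalMaxima
from rowcount.geometry import PerspectiveParams
from rowcount.registration import (
    DetectorConfig,
    KeypointSet,
    MatchSet,
    RegistrationError,
    affine_validity,
    compute_buffer,
    count_sequence,
    detect_and_describe,
    estimate_homography,
    estimate_overlap,
    filter_matches,
    mark_double_counted,
    match_descriptors,
    register_pair,
)
from rowcount.synthetic import (
    SceneSpec,
    counting_roi,
    render_scene,
    render_sequence,
    sequence_spec_for_overlap,
)


def maxima_at(positions, width=640):
    pos = np.asarray(positions)
    return LocalMaxima(positions=pos, values=np.ones_like(pos, dtype=float))


@pytest.fixture(scope="module")
def translated_pair():
    """Two frames of the same row scene, content shifted left by 120 px."""
    spec = SceneSpec(n_plants=12, seed=21)
    frames, _ = render_sequence(spec, 2, 120)
    return frames[0], frames[1], 120


class TestDetectAndDescribe:
    def test_constant_image_near_empty(self):
        kp = detect_and_describe(np.full((200, 300, 3), 120, dtype=np.uint8))
        assert len(kp) <= 5

    def test_textured_scene_translated_copy_matches(self, translated_pair):
        a, b, shift = translated_pair
        kp_a = detect_and_describe(a)
        kp_b = detect_and_describe(b)
        assert len(kp_a) >= 50 and len(kp_b) >= 50
        matches = match_descriptors(kp_a, kp_b)
        displacement = matches.dst_xy[:, 0] - matches.src_xy[:, 0]
        within = np.abs(displacement + shift) <= 1.0
        assert within.mean() >= 0.6
        assert np.abs(np.median(displacement) + shift) <= 1.0

    def test_raising_response_threshold_never_increases_count(self, default_scene):
        _, image, _ = default_scene
        counts = [
            len(detect_and_describe(image, DetectorConfig(response_threshold=t)))
            for t in (0.0, 1e-4, 1e-3, 1e-2)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestMatchDescriptors:
    def test_self_match_distance_zero_exact_mode(self, default_scene):
        _, image, _ = default_scene
        kp = detect_and_describe(image)
        matches = match_descriptors(kp, kp, mode="exact")
        assert np.all(matches.distances == 0)
        assert np.all(matches.indices[:, 0] == matches.indices[:, 1])

    def test_empty_set_rejected(self, default_scene):
        _, image, _ = default_scene
        kp = detect_and_describe(image)
        empty = KeypointSet(
            np.empty((0, 2)), np.empty(0), np.empty((0, 256), dtype=bool)
        )
        with pytest.raises(RegistrationError, match="no descriptors"):
            match_descriptors(kp, empty)

    def test_tree_mode_agrees_with_exhaustive_search(self, rng):
        desc_a = rng.integers(0, 2, (500, 256)).astype(bool)
        desc_b = rng.integers(0, 2, (400, 256)).astype(bool)
        pos_a = rng.uniform(0, 100, (500, 2))
        pos_b = rng.uniform(0, 100, (400, 2))
        a = KeypointSet(pos_a, np.ones(500), desc_a)
        b = KeypointSet(pos_b, np.ones(400), desc_b)
        exact = match_descriptors(a, b, mode="exact")
        tree = match_descriptors(a, b, mode="tree")
        same_distance = exact.distances == tree.distances
        assert same_distance.mean() >= 0.95


class TestFilterMatches:
    def make_matches(self, distances):
        n = len(distances)
        return MatchSet(
            indices=np.column_stack([np.arange(n), np.arange(n)]),
            distances=np.asarray(distances, dtype=float),
            src_xy=np.zeros((n, 2)),
            dst_xy=np.zeros((n, 2)),
        )

    def test_equal_distances_all_retained(self):
        out = filter_matches(self.make_matches([4, 4, 4, 4]), k=3.0)
        assert len(out) == 4

    def test_three_times_minimum_threshold(self):
        out = filter_matches(self.make_matches([1, 2, 10]), k=3.0)
        assert out.distances.tolist() == [1, 2]

    def test_zero_minimum_keeps_perfect_matches(self):
        out = filter_matches(self.make_matches([0, 0, 5]), k=3.0)
        assert out.distances.tolist() == [0, 0]

    def test_empty_input_rejected(self):
        with pytest.raises(RegistrationError):
            filter_matches(self.make_matches([]))


class TestEstimateHomography:
    def test_identical_frames_give_identity(self, default_scene):
        _, image, _ = default_scene
        hom = register_pair(image, image)
        np.testing.assert_allclose(hom.matrix, np.eye(3), atol=1e-3)
        assert abs(hom.h13) < 0.5

    def test_pure_translation_recovers_h13(self, translated_pair):
        a, b, shift = translated_pair
        hom = register_pair(a, b)
        assert hom.h13 == pytest.approx(-shift, abs=1.0)
        assert affine_validity(hom.matrix)

    def test_h13_antisymmetry(self, translated_pair):
        a, b, _ = translated_pair
        forward = register_pair(a, b).h13
        backward = register_pair(b, a).h13
        assert forward + backward == pytest.approx(0.0, abs=1.0)

    def test_exact_correspondences_match_four_point_solver(self, rng):
        from rowcount.geometry import QuadCorrespondence, solve_perspective_matrix

        src = np.array([(0, 0), (100, 3), (97, 88), (5, 95)], dtype=float)
        true_m = solve_perspective_matrix(
            QuadCorrespondence(
                source=src, destination=src + [(3, 1), (-2, 2), (4, -1), (0, 3)]
            )
        )
        pts = rng.uniform(0, 100, (30, 2))
        mapped = (true_m @ np.hstack([pts, np.ones((30, 1))]).T).T
        mapped = mapped[:, :2] / mapped[:, 2:]
        matches = MatchSet(
            indices=np.column_stack([np.arange(30)] * 2),
            distances=np.zeros(30),
            src_xy=pts,
            dst_xy=mapped,
        )
        hom = estimate_homography(matches)
        np.testing.assert_allclose(hom.matrix, true_m, atol=1e-3)

    def test_insufficient_matches_rejected(self):
        matches = MatchSet(
            indices=np.zeros((3, 2), dtype=int),
            distances=np.zeros(3),
            src_xy=np.zeros((3, 2)),
            dst_xy=np.zeros((3, 2)),
        )
        with pytest.raises(RegistrationError, match=">= 4"):
            estimate_homography(matches)

    def test_fixed_seed_reproducible(self, translated_pair):
        a, b, _ = translated_pair
        m1 = register_pair(a, b).matrix
        m2 = register_pair(a, b).matrix
        np.testing.assert_array_equal(m1, m2)


class TestAffineValidity:
    def test_identity_valid(self):
        assert affine_validity(np.eye(3))

    def test_projective_bottom_row_invalid(self):
        m = np.eye(3)
        m[2, 0] = 0.01
        assert not affine_validity(m)

    def test_strong_scaling_invalid(self):
        m = np.eye(3)
        m[0, 0] = 1.2
        assert not affine_validity(m)


class TestEstimateOverlap:
    @pytest.mark.parametrize(
        "h13,width,expected",
        [(0.0, 640, 100.0), (640.0, 640, 0.0), (-640.0, 640, 0.0), (-256.0, 640, 60.0)],
    )
    def test_values(self, h13, width, expected):
        assert estimate_overlap(h13, width) == pytest.approx(expected)

    def test_beyond_frame_clamps_to_zero(self):
        assert estimate_overlap(-900.0, 640) == 0.0


class TestComputeBuffer:
    def test_stated_formula(self):
        assert compute_buffer(maxima_at([10, 30, 50]), 640) == 10.0

    def test_equal_spacing_gives_half_spacing(self):
        assert compute_buffer(maxima_at([100, 160, 220, 280]), 640) == 30.0

    def test_single_maximum_falls_back_to_w_over_20(self):
        assert compute_buffer(maxima_at([300]), 640) == 32.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_buffer(maxima_at([]), 640)


class TestMarkDoubleCounted:
    def test_zero_translation_example(self):
        decision = mark_double_counted(maxima_at([50, 320, 635]), 0.0, 10.0, 640)
        assert decision.duplicate.tolist() == [True, True, False]
        assert decision.n_new == 1

    def test_no_overlap_no_duplicates(self):
        decision = mark_double_counted(maxima_at([50, 320, 635]), -660.0, 10.0, 640)
        assert not decision.duplicate.any()

    def test_positive_translation_rule(self):
        decision = mark_double_counted(maxima_at([50, 320, 635]), 100.0, 10.0, 640)
        # duplicate iff i - b > h13
        assert decision.duplicate.tolist() == [False, True, True]

    def test_flags_partition_maxima(self, rng):
        for _ in range(20):
            pos = np.sort(rng.choice(640, size=8, replace=False))
            h13 = rng.uniform(-640, 640)
            decision = mark_double_counted(maxima_at(pos), h13, rng.uniform(0, 40), 640)
            assert decision.duplicate.shape == (8,)
            assert decision.duplicate.dtype == bool  # each maximum exactly one flag


class TestCountSequence:
    def test_single_image_equals_single_count(self, default_scene):
        _, image, _ = default_scene
        from rowcount.counting import count_single_image

        seq = count_sequence([image], PerspectiveParams(0, 0))
        assert seq.total == count_single_image(image, PerspectiveParams(0, 0)).n_plants
        assert seq.pair_records == []

    def test_repeated_image_counts_once(self, default_scene):
        _, image, _ = default_scene
        seq = count_sequence([image] * 3, PerspectiveParams(0, 0))
        assert seq.total == seq.image_counts[0].n_plants

    def test_sequence_total_matches_distinct_plants(self):
        spec, trans = sequence_spec_for_overlap(SceneSpec(seed=31), 6, 0.60)
        frames, truth = render_sequence(spec, 6, trans)
        seq = count_sequence(frames, PerspectiveParams(0, 0), roi=counting_roi(spec))
        assert abs(seq.total - truth.distinct_total) <= 1

    def test_appending_empty_nonoverlapping_frame_is_invariant(self, default_scene):
        spec, image, _ = default_scene
        soil, _ = render_scene(
            SceneSpec(n_plants=0, seed=99, width=spec.width, height=spec.height)
        )
        base = count_sequence([image, image], PerspectiveParams(0, 0))
        extended = count_sequence([image, image, soil], PerspectiveParams(0, 0))
        assert extended.total == base.total

    def test_unrelatable_pair_falls_back_and_continues(self, default_scene, caplog):
        _, image, _ = default_scene
        flat = np.full_like(image, 128)  # no keypoints: registration must fail
        import logging

        with caplog.at_level(logging.WARNING, logger="rowcount.registration"):
            seq = count_sequence([image, flat, image], PerspectiveParams(0, 0))
        assert any(rec.fallback for rec in seq.pair_records)
        assert len(seq.image_counts) == 3
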