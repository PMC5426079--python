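"""Objective terms: hand-computed values, scaling laws, normalization."""

import numpy as np
import pytest

from sonoseg.config import ObjectiveWeights
from sonoseg.graph import RegionStats, RgbParams, segment
from sonoseg.objective import (
    NormalizationFactors,
    ObjectiveEvaluator,
    ReferenceRegion,
    adjacent_regions,
    average_gradient,
    between_class_variance,
    boundary_pixels,
    combined_objective,
    evaluate_candidate,
    extract_reference_region,
    normalization_factors,
    sobel_magnitude,
    within_class_variance,
)


def _ref_from_mask(img, mask):
    return ReferenceRegion(
        label=0, mask=mask.astype(bool), stats=RegionStats.from_pixels(img[mask.astype(bool)])
    )


class TestReferenceRegion:
    def test_single_region(self):
        part = segment(np.full((6, 6), 9, np.uint8), RgbParams(k=100, alpha=1))
        ref = extract_reference_region(part)
        assert ref.stats.size == 36

    def test_centre_pixel_floor_convention(self, two_half_image, two_half_params):
        part = segment(two_half_image, two_half_params)
        ref = extract_reference_region(part)
        # (4, 4) lies in the right (bright) half
        assert ref.stats.mean == pytest.approx(200)

    def test_lesion_recovered_on_easy_phantom(self):
        from sonoseg.phantom import PhantomSpec, render_phantom
        from sonoseg.preprocess import RoiRect, preprocess_pipeline

        spec = PhantomSpec(seed=11, speckle_sigma=0.05)
        img, truth = render_phantom(spec)
        tci = preprocess_pipeline(img, RoiRect(0, 0, spec.width, spec.height))
        part = segment(tci, RgbParams(k=500, alpha=0.1))
        ref = extract_reference_region(part)
        overlap = (ref.mask & truth.astype(bool)).sum()
        assert overlap / truth.sum() > 0.5


class TestAdjacency:
    def test_single_region_has_no_neighbours(self):
        part = segment(np.full((6, 6), 9, np.uint8), RgbParams(k=100, alpha=1))
        ref = extract_reference_region(part)
        assert adjacent_regions(part, ref) == set()

    def test_three_stripes_middle_touches_both(self):
        img = np.zeros((9, 9), np.uint8)
        img[3:6] = 120
        img[6:] = 250
        part = segment(img, RgbParams(k=100, alpha=4))
        assert part.n_regions == 3
        centre = int(part.labels[4, 4])
        ref = ReferenceRegion(centre, part.labels == centre, part.regions[centre])
        assert adjacent_regions(part, ref) == set(part.regions) - {centre}

    def test_never_contains_reference(self, two_half_image, two_half_params):
        part = segment(two_half_image, two_half_params)
        ref = extract_reference_region(part)
        assert ref.label not in adjacent_regions(part, ref)


class TestBetweenClassVariance:
    def test_single_neighbour_hand_value(self, two_half_image):
        # adapt: halves of an 8x8 (sizes 32); scale to the worked numbers
        img = np.zeros((10, 10), np.uint8)
        img[:, :5] = 100
        img[:, 5:] = 150
        part = segment(img, RgbParams(k=100, alpha=4))
        assert part.n_regions == 2
        ref = extract_reference_region(part)
        # V_B = P(C)*(mu_C - mu_ref)^2 = 0.5 * 50^2 = 1250
        assert between_class_variance(part, ref, img.size) == pytest.approx(1250.0)

    def test_zero_when_neighbours_share_mean(self):
        img = np.zeros((8, 8), np.uint8)
        part = segment(img, RgbParams(k=100, alpha=1))
        ref = extract_reference_region(part)
        assert between_class_variance(part, ref, img.size) == 0.0

    def test_quadratic_in_contrast(self):
        imgs = []
        for gap in (25, 50):
            img = np.zeros((10, 10), np.uint8)
            img[:, :5] = 100
            img[:, 5:] = 100 + gap
            imgs.append(img)
        vals = []
        for img in imgs:
            part = segment(img, RgbParams(k=100, alpha=4))
            ref = extract_reference_region(part)
            vals.append(between_class_variance(part, ref, img.size))
        assert vals[1] == pytest.approx(4 * vals[0])


class TestWithinClassVariance:
    def test_uniform_reference_is_zero(self):
        img = np.full((10, 10), 55, np.uint8)
        mask = np.zeros((10, 10), bool)
        mask[4:6, 4:6] = True
        ref = _ref_from_mask(img, mask)
        assert within_class_variance(img, ref, img.size) == 0.0

    def test_hand_value(self):
        # two pixels {90, 110}: var=100; |TCI|=100 -> arctan(100)/0.02
        img = np.full((10, 10), 90, np.uint8)
        img[0, 1] = 110
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = mask[0, 1] = True
        ref = _ref_from_mask(img, mask)
        assert within_class_variance(img, ref, 100) == pytest.approx(
            np.arctan(100.0) / 0.02, rel=1e-12
        )

    def test_p_scaling(self):
        # same pixel variance, reference covering the whole TCI: shrink by 1/P
        img = np.full((10, 10), 90, np.uint8)
        img[::2, :] = 110
        full = _ref_from_mask(img, np.ones((10, 10), bool))
        v_full = within_class_variance(img, full, 100)
        assert v_full == pytest.approx(np.arctan(100.0), rel=1e-12)

    def test_multiply_form_differs_by_p_squared(self):
        img = np.full((10, 10), 90, np.uint8)
        img[0, 1] = 110
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = mask[0, 1] = True
        ref = _ref_from_mask(img, mask)
        div = within_class_variance(img, ref, 100, form="divide")
        mul = within_class_variance(img, ref, 100, form="multiply")
        assert mul == pytest.approx(div * (0.02**2))


class TestBoundary:
    def test_single_pixel_region(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        ref = _ref_from_mask(np.zeros((5, 5), np.uint8) + 1, mask)
        bp = boundary_pixels(ref)
        assert bp.tolist() == [[2, 2]]

    def test_filled_square_perimeter(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        ref = _ref_from_mask(np.ones((8, 8), np.uint8), mask)
        bp = boundary_pixels(ref)
        assert len(bp) == 12  # 4x4 square: 16 - 4 interior

    def test_image_border_counts_as_outside(self):
        mask = np.ones((6, 6), bool)
        ref = _ref_from_mask(np.ones((6, 6), np.uint8), mask)
        bp = boundary_pixels(ref)
        assert len(bp) == 20  # perimeter of the 6x6 frame


class TestAverageGradient:
    def test_constant_image_zero(self):
        img = np.full((10, 10), 128, np.uint8)
        mask = np.zeros((10, 10), bool)
        mask[3:7, 3:7] = True
        assert average_gradient(img, _ref_from_mask(img, mask)) == 0.0

    def test_ideal_step_gives_1020(self):
        # step 0 | 255 at column 5; a column-strip region hugging the step:
        # every boundary pixel sees the full Sobel response 4*255 = 1020
        img = np.zeros((10, 10), np.uint8)
        img[:, 5:] = 255
        mask = np.zeros((10, 10), bool)
        mask[:, 4] = True
        assert average_gradient(img, _ref_from_mask(img, mask)) == pytest.approx(1020.0)

    def test_linear_in_intensity_scale(self):
        img = np.zeros((10, 10), np.uint8)
        img[:, 5:] = 100
        mask = np.zeros((10, 10), bool)
        mask[:, 4] = True
        g1 = average_gradient(img, _ref_from_mask(img, mask))
        img2 = (img.astype(int) * 2).astype(np.uint8)
        g2 = average_gradient(img2, _ref_from_mask(img2, mask))
        assert g2 == pytest.approx(2 * g1)

    def test_sobel_magnitude_nonnegative(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert np.all(sobel_magnitude(img) >= 0)


class TestNormalization:
    def test_arithmetic_means(self):
        f = normalization_factors([(2, 4, 6), (4, 8, 10)])
        assert (f.f_b, f.f_w, f.f_a) == (3, 6, 8)

    def test_identical_samples(self):
        f = normalization_factors([(1.5, 2.5, 3.5)] * 7)
        assert (f.f_b, f.f_w, f.f_a) == (1.5, 2.5, 3.5)

    def test_zero_mean_guarded(self, caplog):
        f = normalization_factors([(0, 0, 0), (0, 0, 0)])
        assert (f.f_b, f.f_w, f.f_a) == (1, 1, 1)


class TestCombined:
    def test_hand_value(self):
        f = NormalizationFactors(1, 1, 1)
        w = ObjectiveWeights(0.3, 0.3, 0.4)
        assert combined_objective(2, 1, 1, f, w) == pytest.approx(0.7)

    def test_zero_terms(self):
        f = NormalizationFactors(1, 1, 1)
        assert combined_objective(0, 0, 0, f) == 0.0

    def test_single_objective_reduction(self, rng):
        # weights (1,0,0) with unit factors reproduce the pure contrast
        # objective candidate-for-candidate
        f = NormalizationFactors(1, 1, 1)
        w = ObjectiveWeights(1, 0, 0)
        for _ in range(20):
            vb, vw, ga = rng.uniform(0, 100, 3)
            assert combined_objective(vb, vw, ga, f, w) == pytest.approx(vb)


class TestEvaluateCandidate:
    def test_constant_image_all_terms_vanish(self):
        b = evaluate_candidate(np.full((8, 8), 50, np.uint8), RgbParams(k=100, alpha=1))
        assert (b.v_b, b.v_w, b.g_a) == (0, 0, 0)
        assert b.f_o is None

    def test_two_half_composition(self, two_half_image, two_half_params):
        b = evaluate_candidate(two_half_image, two_half_params)
        # single neighbour: P=0.5, contrast 150 -> V_B = 0.5*150^2
        assert b.v_b == pytest.approx(0.5 * 150**2)
        assert b.v_w == 0.0

    def test_deterministic(self, two_half_image, two_half_params):
        b1 = evaluate_candidate(two_half_image, two_half_params)
        b2 = evaluate_candidate(two_half_image, two_half_params)
        assert (b1.v_b, b1.v_w, b1.g_a) == (b2.v_b, b2.v_w, b2.g_a)


class TestEvaluator:
    def test_factors_set_once(self, two_half_image):
        ev = ObjectiveEvaluator(two_half_image)
        ev.set_normalization(np.array([[100.0, 1.0], [500.0, 2.0]]))
        with pytest.raises(RuntimeError):
            ev.set_normalization(np.array([[100.0, 1.0]]))

    def test_fitness_requires_factors(self, two_half_image):
        ev = ObjectiveEvaluator(two_half_image)
        with pytest.raises(RuntimeError):
            ev((100.0, 1.0))

    def test_caching_counts_unique_candidates(self, two_half_image):
        ev = ObjectiveEvaluator(two_half_image)
        ev.set_normalization(np.array([[100.0, 1.0], [100.0, 1.0], [500.0, 2.0]]))
        assert ev.n_evaluations == 2

    def test_matches_direct_evaluation(self, two_half_image, two_half_params):
        ev = ObjectiveEvaluator(two_half_image)
        b = ev.breakdown(two_half_params.k, two_half_params.alpha)
        direct = evaluate_candidate(two_half_image, two_half_params)
        assert b.v_b == pytest.approx(direct.v_b)
        assert b.v_w == pytest.approx(direct.v_w)
        assert b.g_a == pytest.approx(direct.g_a)
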