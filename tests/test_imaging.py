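"""Z-stack overlap correction and puncta detection/statistics."""

import numpy as np
import pytest

from arbormetry import (
    PunctaSimParams,
    ZStackField,
    ZStackSimParams,
    corrected_density,
    detect_puncta,
    estimate_overlap_fraction,
    generate_puncta_image,
    generate_zstack_field,
    match_detections,
    puncta_group_stats,
)


def field_from_sim(result, params: ZStackSimParams) -> ZStackField:
    return ZStackField(
        per_stack_raw_length=result.per_stack_raw_length,
        per_pair_duplicated_length=result.per_pair_duplicated_length,
        field_area_um2=params.field_area,
        stack_thickness_um=params.stack_thickness,
    )


class TestOverlapCorrection:
    def test_reference_fraction_arithmetic(self):
        f = ZStackField([100.0, 100.0], [25.4], 1.0, 8.0)
        assert estimate_overlap_fraction(f) == pytest.approx(0.254)
        assert estimate_overlap_fraction(f, mode="per_pair") == pytest.approx(0.254)

    def test_no_duplication(self):
        f = ZStackField([80.0, 120.0], [0.0], 1.0, 8.0)
        assert estimate_overlap_fraction(f) == 0.0

    def test_zero_raw_length_errors(self):
        f = ZStackField([0.0, 0.0], [0.0], 1.0, 8.0)
        with pytest.raises(ValueError):
            estimate_overlap_fraction(f)

    def test_corrected_length_arithmetic(self):
        # raw 100 µm at 25.4% overlap -> 74.6 µm corrected per stack
        f = ZStackField([100.0, 100.0], [25.4], field_area_um2=100.0)
        dens = corrected_density(f, 0.254)
        assert dens == pytest.approx(2 * 74.6 / (100.0 * 8.0 * 2))

    def test_fraction_zero_is_raw_density(self):
        f = ZStackField([100.0, 100.0], [0.0], field_area_um2=100.0)
        assert corrected_density(f, 0.0) == pytest.approx(200.0 / 1600.0)

    def test_fraction_at_least_one_errors(self):
        f = ZStackField([100.0, 100.0], [25.4], 1.0)
        with pytest.raises(ValueError):
            corrected_density(f, 1.0)

    def test_corrected_never_exceeds_raw(self):
        for seed in range(5):
            p = ZStackSimParams(seed=seed)
            r = generate_zstack_field(p)
            f = field_from_sim(r, p)
            frac = estimate_overlap_fraction(f)
            raw_density = np.sum(f.per_stack_raw_length) / (
                p.field_area * p.stack_thickness * p.n_stacks
            )
            assert corrected_density(f, frac) <= raw_density
            assert corrected_density(f, 0.0) == pytest.approx(raw_density)

    def test_synthetic_overlap_matches_truth(self):
        # generator truth: duplicated fraction is 2b/(T+2b)
        p = ZStackSimParams(bleed_depth=1.0, seed=0)
        expect = 2.0 / (8.0 + 2.0)
        fracs = []
        for seed in range(10):
            r = generate_zstack_field(ZStackSimParams(bleed_depth=1.0, seed=seed))
            fracs.append(estimate_overlap_fraction(field_from_sim(r, p)))
        assert np.mean(fracs) == pytest.approx(expect, rel=0.02)

    def test_uncorrected_density_overestimates_by_known_factor(self):
        # raw density exceeds truth by ~f/(1-f); the correction removes it
        p = ZStackSimParams(seed=1)
        r = generate_zstack_field(p)
        f = field_from_sim(r, p)
        frac = estimate_overlap_fraction(f)
        raw_density = np.sum(f.per_stack_raw_length) / (
            p.field_area * p.stack_thickness * p.n_stacks
        )
        assert raw_density / r.true_density == pytest.approx(1.0 / (1.0 - frac), rel=0.05)


class TestDetectPuncta:
    def test_blank_image(self):
        pf = detect_puncta(np.zeros((64, 64)))
        assert pf.count == 0

    def test_single_disc_detected_at_center(self):
        from skimage.draw import disk

        img = np.zeros((64, 64))
        rr, cc = disk((30.0, 40.0), 4.0, shape=img.shape)
        img[rr, cc] = 1.0
        pf = detect_puncta(img)
        assert pf.count == 1
        det = pf.detections.iloc[0]
        assert det.row == pytest.approx(30.0, abs=1.0)
        assert det.col == pytest.approx(40.0, abs=1.0)

    def test_non_2d_input_errors(self):
        with pytest.raises(ValueError):
            detect_puncta(np.zeros((4, 4, 3)))

    def test_count_monotone_in_min_diameter(self):
        img, _ = generate_puncta_image(PunctaSimParams(seed=2, noise_sd=0.0))
        counts = [
            detect_puncta(img, min_diameter_px=d).count for d in (0.0, 3.0, 5.0, 8.0, 12.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_truth_recovery_on_clean_two_size_field(self):
        # 10 discs of 8 px and 5 of 4 px: the >5 px criterion keeps exactly
        # the large ones, at perfect precision and recall
        from skimage.draw import disk

        big = PunctaSimParams(
            n_puncta=10, puncta_diameter_range=(8, 8), noise_sd=0.0, seed=21
        )
        img, t_b = generate_puncta_image(big)
        rng = np.random.default_rng(22)
        small_placed = []
        while len(small_placed) < 5:
            r, c = rng.uniform(10, 610, 2)
            clear_of_big = all(
                np.hypot(r - tr, c - tc) > 12 for tr, tc in zip(t_b.row, t_b.col)
            )
            clear_of_small = all(
                np.hypot(r - pr, c - pc) > 10 for pr, pc in small_placed
            )
            if clear_of_big and clear_of_small:
                rr, cc = disk((r, c), 2.0, shape=img.shape)
                img[rr, cc] = 1.0
                small_placed.append((r, c))
        pf = detect_puncta(img)
        assert pf.count == 10
        tp, fp, fn = match_detections(t_b, pf.detections)
        assert (tp, fp, fn) == (10, 0, 0)


class TestGroupStats:
    def test_quartiles_linear_interpolation(self):
        # hand-checked: {2,4,6,8} -> Q1 3.5, median 5, Q3 6.5
        summary, _ = puncta_group_stats(
            {"a": [2, 4, 6, 8], "b": [1, 1, 2, 3]}, field_area_um2=1e6
        )
        row = summary[summary.group == "a"].iloc[0]
        assert row["median"] == pytest.approx(5.0)
        assert row.q1 == pytest.approx(3.5)
        assert row.q3 == pytest.approx(6.5)
        assert (row["min"], row["max"]) == (2.0, 8.0)

    def test_identical_groups_t_zero(self):
        _, tests = puncta_group_stats({"a": [1, 2, 3], "b": [1, 2, 3]}, 1e6)
        assert tests.t.iloc[0] == pytest.approx(0.0)

    def test_student_t_reference_values(self):
        # closed form: t = (2-5)/sqrt(1*(1/3+1/3)) = -3.674, p = 0.0213 (df=4)
        _, tests = puncta_group_stats({"a": [1, 2, 3], "b": [4, 5, 6]}, 1e6)
        assert tests.t.iloc[0] == pytest.approx(-3.674, abs=1e-3)
        assert tests.p.iloc[0] == pytest.approx(0.0213, abs=2e-3)

    def test_degenerate_variance_flagged(self):
        _, tests = puncta_group_stats({"a": [2, 2, 2], "b": [2, 2, 2]}, 1e6)
        assert bool(tests.degenerate.iloc[0])
        assert np.isnan(tests.p.iloc[0])

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            puncta_group_stats({"a": [1, 2]}, 1e6)

    def test_density_conversion(self):
        # 10 puncta in a 400 µm x 400 µm field = 62.5 per mm²
        summary, _ = puncta_group_stats(
            {"a": [10, 10], "b": [0, 0]}, field_area_um2=400.0 * 400.0
        )
        assert summary[summary.group == "a"]["median"].iloc[0] == pytest.approx(62.5)
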