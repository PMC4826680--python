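import numpy as np
import pytest

from odlocate.detector import (
    DetectorConfig,
    analyze_region,
    expected_disc_area,
    generate_candidates,
    recursive_dilation_pass,
    refine_disc_region,
)
from odlocate.preprocess import RetinalImage
from odlocate.segmentation import Region, label_components


def fragmented_disc_mask(shape=(64, 64), center=(32, 32), radius=15):
    """A disc cut into fragments by vessel-like gaps, as thresholding does."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    m = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    m[center[0] - 2 : center[0] + 3, :] = False
    m[:, center[1] - 2 : center[1] + 2] = False
    return m


class TestGenerateCandidates:
    def test_blank_image_yields_no_candidates(self):
        img = RetinalImage(np.full((128, 128, 3), 60, np.uint8))
        regions, bright = generate_candidates(img)
        assert regions == [] and bright.max() == 0

    def test_intact_disc_yields_candidate_on_disc(self, intact_phantom):
        img, gt = intact_phantom
        regions, _ = generate_candidates(img)
        assert regions
        r0, c0, r1, c1 = regions[0].bbox
        assert r0 <= gt.disc_center[0] < r1 and c0 <= gt.disc_center[1] < c1

    def test_keypoint_filter_only_removes(self, phantom):
        from odlocate.detector import _candidate_mask, _threshold_bright
        from odlocate.preprocess import extract_bright_regions

        img, _ = phantom
        cfg = DetectorConfig()
        pre = _threshold_bright(extract_bright_regions(img, cfg.bright))
        post, _ = _candidate_mask(img, cfg)
        assert len(label_components(post)) <= len(label_components(pre))
        assert not (post & ~pre).any()


class TestAnalyzeRegion:
    def test_true_disc_region_scores_above_threshold(
        self, intact_phantom, trained_detector
    ):
        img, gt = intact_phantom
        cfg = DetectorConfig()
        r = int(gt.disc_radius)
        cr, cc = int(gt.disc_center[0]), int(gt.disc_center[1])
        region = Region(1, (2 * r) ** 2, (cr - r, cc - r, cr + r, cc + r),
                        (float(cr), float(cc)))
        cand = analyze_region(
            img, region, trained_detector.classifier_, None,
            trained_detector.templates_, cfg, dilation_round=3,
        )
        assert cand.model_prob > cfg.decision_threshold
        assert cand.dilation_round == 3

    def test_background_region_scores_below_disc(self, intact_phantom,
                                                 trained_detector):
        img, gt = intact_phantom
        cfg = DetectorConfig()
        r = int(gt.disc_radius)
        cr, cc = int(gt.disc_center[0]), int(gt.disc_center[1])
        disc = Region(1, 1, (cr - r, cc - r, cr + r, cc + r), (float(cr), float(cc)))
        h, w = img.shape
        flat = Region(2, 1, (h // 2 - r, 40 - r, h // 2 + r, 40 + r),
                      (h / 2.0, 40.0))
        args = (trained_detector.classifier_, None, trained_detector.templates_, cfg)
        assert (
            analyze_region(img, flat, *args).ssim_score
            < analyze_region(img, disc, *args).ssim_score
        )

    def test_degenerate_bbox_rejected(self, intact_phantom, trained_detector):
        img, _ = intact_phantom
        bad = Region(1, 1, (10, 10, 11, 30), (10.0, 15.0))
        with pytest.raises(ValueError):
            analyze_region(img, bad, trained_detector.classifier_, None,
                           trained_detector.templates_)


class TestRecursiveDilation:
    def test_merges_fragmented_disc(self):
        m = fragmented_disc_mask()
        assert len(label_components(m)) >= 3
        out, rounds = recursive_dilation_pass(
            m, DetectorConfig(), expected_area=np.pi * 15**2
        )
        assert len(label_components(out)) == 1
        assert 1 <= rounds <= 5

    def test_large_region_terminates_immediately(self):
        m = np.zeros((64, 64), bool)
        m[10:50, 10:50] = True  # 1600 px >> ceiling
        out, rounds = recursive_dilation_pass(
            m, DetectorConfig(), expected_area=100.0
        )
        assert rounds == 0 and (out == m).all()

    def test_rounds_never_exceed_cap(self):
        m = np.zeros((64, 64), bool)
        m[5, 5] = m[5, 60] = m[60, 5] = True  # far apart, never merge
        cfg = DetectorConfig(max_dilation_rounds=3)
        _, rounds = recursive_dilation_pass(m, cfg, expected_area=1e9)
        assert rounds <= 3


class TestRefineDiscRegion:
    def _img(self):
        return RetinalImage(np.zeros((100, 100, 3), np.uint8))

    def test_rectangular_bbox_becomes_square(self):
        region = Region(1, 800, (40, 30, 60, 70), (49.5, 49.5))
        out = refine_disc_region(self._img(), region)
        r0, c0, r1, c1 = out.bbox
        assert (r1 - r0, c1 - c0) == (40, 40)
        assert abs((r0 + r1) / 2 - 50) <= 1 and abs((c0 + c1) / 2 - 50) <= 1

    def test_square_centered_region_is_fixed_point(self):
        region = Region(1, 400, (40, 40, 60, 60), (49.5, 49.5))
        assert refine_disc_region(self._img(), region).bbox == (40, 40, 60, 60)

    def test_clamped_inside_image_near_border(self):
        region = Region(1, 400, (0, 80, 20, 100), (9.5, 89.5))
        out = refine_disc_region(self._img(), region)
        r0, c0, r1, c1 = out.bbox
        assert 0 <= r0 < r1 <= 100 and 0 <= c0 < c1 <= 100


class TestDetectOpticDisc:
    def test_blank_image_not_found(self, trained_detector):
        img = RetinalImage(np.full((128, 128, 3), 60, np.uint8))
        res = trained_detector.detect(img)
        assert not res.found and res.candidates == []

    def test_center_inside_bbox_when_found(self, phantom, trained_detector):
        img, _ = phantom
        res = trained_detector.detect(img)
        assert res.found
        r0, c0, r1, c1 = res.disc_region.bbox
        assert r0 <= res.disc_center[0] < r1 and c0 <= res.disc_center[1] < c1

    def test_fallback_skipped_when_first_pass_succeeds(
        self, intact_phantom, trained_detector
    ):
        img, _ = intact_phantom
        res = trained_detector.detect(img)
        assert res.found and res.rounds_used == 0
        assert all(c.dilation_round == 0 for c in res.candidates)

    def test_fragmented_disc_recovered_via_fallback(self, phantom,
                                                    trained_detector):
        img, gt = phantom
        res = trained_detector.detect(img)
        assert res.found and res.rounds_used >= 1
        err = np.hypot(res.disc_center[0] - gt.disc_center[0],
                       res.disc_center[1] - gt.disc_center[1])
        assert err < gt.disc_radius

    def test_result_json_is_deterministic(self, phantom, trained_detector):
        img, _ = phantom
        assert (
            trained_detector.detect(img).to_json()
            == trained_detector.detect(img).to_json()
        )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_area_fraction": 0.5, "max_area_fraction": 0.4},
            {"max_dilation_rounds": 0},
            {"ssim_weight": 1.5},
            {"fusion": "sum"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectorConfig(**kwargs)

    def test_expected_disc_area_from_fov(self, phantom):
        img, gt = phantom
        area = expected_disc_area(img, DetectorConfig())
        true_area = np.pi * gt.disc_radius**2
        assert 0.5 * true_area < area < 2.0 * true_area
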