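"""Quantification: optical-density fractions, spheroid densities, myelin
score averaging, and the endpoint-to-algorithm protocol map."""

import numpy as np
import pytest

from cuprank.errors import DegenerateHistogramError, EmptyFieldWarning
from cuprank.images import ODFieldSpec, SpheroidFieldSpec, make_od_image, make_spheroid_image
from cuprank.quantify import (
    DEFAULT_ALGORITHM_MAP,
    RoiGeometry,
    algorithm_for,
    count_spheroids,
    myelin_score_average,
    optical_density_fraction,
)


def full_roi(img: np.ndarray, pixel_size: float = 1.0) -> RoiGeometry:
    return RoiGeometry(np.ones(img.shape, dtype=bool), pixel_size)


class TestOpticalDensity:
    def test_half_bright_half_dark_is_fifty_percent(self):
        img = np.full((10, 10), 50, dtype=np.uint8)
        img[:5] = 200
        for alg in ("IsoData", "Default", "MaxEntropy"):
            assert optical_density_fraction(img, full_roi(img), alg) == pytest.approx(50.0)

    def test_two_intensity_zero_positive_class(self):
        """A nearly-empty foreground class: only the two bright pixels sit
        above the threshold."""
        img = np.full((10, 10), 50, dtype=np.uint8)
        img[0, :2] = 200
        assert optical_density_fraction(img, full_roi(img), "IsoData") == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "frac,alg", [(0.968, "MaxEntropy"), (0.10, "IsoData"), (0.5, "Default")]
    )
    def test_measured_matches_ground_truth_on_separated_laws(self, frac, alg):
        img = make_od_image(ODFieldSpec(width=128, height=128, true_fraction=frac, seed=5))
        measured = optical_density_fraction(img.pixels, full_roi(img.pixels), alg)
        assert measured == pytest.approx(100.0 * img.ground_truth.fraction, abs=1.5)

    def test_noiseless_two_level_image_measured_exactly(self):
        spec = ODFieldSpec(
            width=64,
            height=64,
            true_fraction=0.3,
            background_law=(50.0, 0.0),
            foreground_law=(200.0, 0.0),
            seed=9,
        )
        img = make_od_image(spec)
        measured = optical_density_fraction(img.pixels, full_roi(img.pixels), "IsoData")
        assert measured == pytest.approx(100.0 * img.ground_truth.fraction, abs=1e-12)

    def test_invert_flag_flips_positivity_side(self):
        img = np.full((10, 10), 50, dtype=np.uint8)
        img[:3] = 200  # 30% bright
        bright = optical_density_fraction(img, full_roi(img), "IsoData", invert=False)
        dark = optical_density_fraction(img, full_roi(img), "IsoData", invert=True)
        assert bright == pytest.approx(30.0)
        assert dark == pytest.approx(70.0)

    def test_uniform_roi_raises_degenerate_error(self):
        img = np.full((10, 10), 7, dtype=np.uint8)
        with pytest.raises(DegenerateHistogramError):
            optical_density_fraction(img, full_roi(img), "IsoData")

    def test_threshold_uses_roi_histogram_only(self):
        """Pixels outside the ROI must not influence the threshold."""
        img = np.full((20, 20), 50, dtype=np.uint8)
        img[:10] = 200
        roi = np.zeros(img.shape, dtype=bool)
        roi[5:15] = True  # half bright, half dark inside ROI
        outside = img.copy()
        outside[15:] = 255  # garbage outside ROI
        frac1 = optical_density_fraction(img, RoiGeometry(roi))
        frac2 = optical_density_fraction(outside, RoiGeometry(roi))
        assert frac1 == frac2 == pytest.approx(50.0)


class TestSpheroidCounting:
    def test_empty_field_warns_and_returns_zero(self):
        img = np.full((50, 50), 40, dtype=np.uint8)
        with pytest.warns(EmptyFieldWarning):
            assert count_spheroids(img, full_roi(img)) == 0.0

    def test_ten_disjoint_blobs_in_one_mm2_is_ten_per_mm2(self):
        edge = 1000
        centers = np.array([[100 + 80 * i, 500.0] for i in range(10)])
        spec = SpheroidFieldSpec(
            width=edge, height=edge, true_density=10.0, seed=0,
            background_law=(40.0, 3.0),
        )
        img = make_spheroid_image(spec, centers=centers)
        density = count_spheroids(img.pixels, full_roi(img.pixels))
        assert density == pytest.approx(10.0)

    def test_counting_invariant_to_class_preserving_intensity_rescale(self):
        edge = 400
        centers = np.array([[80.0 * (i + 1), 200.0] for i in range(4)])
        spec = SpheroidFieldSpec(
            width=edge, height=edge, true_density=1.0, seed=1,
            background_law=(40.0, 3.0),
        )
        img = make_spheroid_image(spec, centers=centers)
        rescaled = (img.pixels.astype(float) * 0.8).astype(np.uint8)
        d1 = count_spheroids(img.pixels, full_roi(img.pixels))
        d2 = count_spheroids(rescaled, full_roi(rescaled))
        assert d1 == d2

    def test_pure_noise_field_gated_as_empty(self):
        """A blank field whose histogram is background noise only must not
        yield phantom specks: the contrast gate reports density 0."""
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(40, 10, (300, 300)).round(), 0, 255).astype(np.uint8)
        with pytest.warns(EmptyFieldWarning):
            assert count_spheroids(img, full_roi(img)) == 0.0

    def test_sparse_real_objects_survive_contrast_gate(self):
        """A handful of genuine bright blobs over the same noise is counted,
        not gated away."""
        spec = SpheroidFieldSpec(width=500, height=500, true_density=24.0, seed=3)
        img = make_spheroid_image(spec)
        density = count_spheroids(img.pixels, full_roi(img.pixels))
        expected = img.ground_truth.count / 0.25  # 0.25 mm^2 ROI
        assert density == pytest.approx(expected, abs=4.1)

    def test_min_area_filter_drops_specks(self):
        img = np.full((100, 100), 40, dtype=np.uint8)
        img[10, 10] = 250  # single-pixel speck
        img[50:54, 50:54] = 250  # 16-pixel object
        roi = full_roi(img)
        assert count_spheroids(img, roi, min_area_px=4) == pytest.approx(1 / roi.area_mm2)
        assert count_spheroids(img, roi, min_area_px=1) == pytest.approx(2 / roi.area_mm2)

    def test_centroid_outside_roi_not_counted(self):
        img = np.full((100, 100), 40, dtype=np.uint8)
        img[48:53, 48:53] = 250  # centroid at (50, 50)
        roi_mask = np.zeros(img.shape, dtype=bool)
        roi_mask[:, :45] = True  # ROI excludes the blob centroid
        # threshold histogram comes from the ROI; add contrast inside it
        img[10:12, 10:12] = 250
        density = count_spheroids(img, RoiGeometry(roi_mask), min_area_px=4)
        assert density == pytest.approx(1 / RoiGeometry(roi_mask).area_mm2)

    def test_invalid_min_area_rejected(self):
        img = np.full((10, 10), 40, dtype=np.uint8)
        with pytest.raises(ValueError):
            count_spheroids(img, full_roi(img), min_area_px=0)


class TestMyelinScore:
    @pytest.mark.parametrize(
        "scores,expected", [((4, 4), 4.0), ((1, 1), 1.0), ((3, 4), 3.5), ((2,), 2.0)]
    )
    def test_rater_averaging(self, scores, expected):
        assert myelin_score_average(scores) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [(), (0, 3), (2, 5), (2.5, 3)])
    def test_invalid_scores_rejected(self, bad):
        with pytest.raises(ValueError):
            myelin_score_average(bad)


class TestAlgorithmMap:
    def test_protocol_assignments(self):
        assert algorithm_for("PLP_OD", 265) == "MaxEntropy"
        assert algorithm_for("GFAP_OD", 265) == "Default"
        for name in ("PLP_OD", "IBA1_OD", "GFAP_OD"):
            assert algorithm_for(name, 215) == "IsoData"
        assert algorithm_for("IBA1_OD", 265) == "IsoData"  # protocol silent; default
        assert len(DEFAULT_ALGORITHM_MAP) == 6

    def test_unknown_pair_raises(self):
        with pytest.raises(KeyError):
            algorithm_for("APP_DENSITY", 215)
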