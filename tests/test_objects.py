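"""Inclusion segmentation, shape filtering, density, and calibration."""

import numpy as np
import pytest

from npq import (
    CalibrationParams,
    DetectedObject,
    ObjectDetectionParams,
    ROIPolygon,
    calibrate_positive_threshold,
    count_density,
    filter_objects,
    intensity_histogram,
    segment_candidates,
)
from npq.simulate import Bridge, ImageSimParams, PlantedObject, render_ihc_image

from conftest import dab_intensity_of, full_frame_roi


def _detect(params_img, det_params=None):
    image, _ = render_ihc_image(params_img)
    dab = dab_intensity_of(image)
    roi = full_frame_roi(image.shape)
    return segment_candidates(dab, roi, det_params,
                              pixel_size_um=image.pixel_size_um)


def _dummy(area=50.0, roundness=0.9, elongation=0.8, intensity=150.0):
    return DetectedObject(np.zeros((1, 2), int), area, 10.0, roundness,
                          elongation, intensity)


class TestSegmentation:
    def test_three_planted_disks_recovered(self, rendered_three_disks):
        image, truth = rendered_three_disks
        dab = dab_intensity_of(image)
        objs = segment_candidates(dab, full_frame_roi(image.shape),
                                  pixel_size_um=0.5)
        assert len(objs) == 3
        for o in objs:
            assert o.area_um2 == pytest.approx(50.0, rel=0.10)
            assert o.mean_dab_intensity == pytest.approx(150.0, abs=3)

    def test_blank_image_empty(self):
        params = ImageSimParams(seed=5, shape=(64, 64))
        assert _detect(params) == []

    def test_shallow_bridge_merges_deep_bridge_splits(self):
        """Declustering: fused disks split only across a deep saddle."""
        disks = (PlantedObject((100, 100), "disk", 50, 0.2304),
                 PlantedObject((130, 100), "disk", 50, 0.2304))
        shallow = ImageSimParams(
            seed=6, shape=(200, 200), objects=disks, noise_sd=0,
            bridges=(Bridge(0, 1, 0.2304, width_um=8.0),))
        deep = ImageSimParams(
            seed=6, shape=(200, 200), objects=disks, noise_sd=0,
            bridges=(Bridge(0, 1, 0.07, width_um=8.0),))
        assert len(_detect(shallow)) == 1
        assert len(_detect(deep)) == 2

    def test_missing_pixel_size_errors(self):
        with pytest.raises(ValueError, match="pixel size"):
            segment_candidates(np.full((10, 10), 255.0),
                               ROIPolygon.rectangle(0, 0, 10, 10),
                               pixel_size_um=None)

    def test_roundness_of_large_disk_near_one(self):
        params = ImageSimParams(
            seed=7, shape=(200, 200), noise_sd=0,
            objects=(PlantedObject((100, 100), "disk", 200, 0.2304),))
        (obj,) = _detect(params)
        assert obj.roundness == pytest.approx(1.0, abs=0.1)

    def test_elongation_of_3to1_ellipse(self):
        params = ImageSimParams(
            seed=8, shape=(200, 200), noise_sd=0,
            objects=(PlantedObject((100, 100), "ellipse", 200, 0.2304,
                                   aspect=3.0),))
        (obj,) = _detect(params)
        assert obj.elongation == pytest.approx(1 / 3, rel=0.10)


class TestFiltering:
    @pytest.mark.parametrize("obj, kept", [
        (_dummy(area=10.0), False),           # below minimum size
        (_dummy(area=300.0), False),          # above maximum size
        (_dummy(roundness=0.1), False),       # fiber-like
        (_dummy(elongation=0.05), False),     # too elongated
        (_dummy(intensity=210.0), False),     # paler than positivity cutoff
        (_dummy(), True),
        (_dummy(area=20.0), True),            # boundary values kept
        (_dummy(area=225.0), True),
    ])
    def test_filter_rules(self, obj, kept):
        assert (filter_objects([obj]) == [obj]) is kept

    def test_raising_min_area_never_increases_count(self):
        rng = np.random.default_rng(9)
        objs = [_dummy(area=float(a)) for a in rng.uniform(5, 300, 50)]
        counts = [len(filter_objects(
            objs, ObjectDetectionParams(min_area_um2=m)))
            for m in (5, 20, 50, 100, 200)]
        assert counts == sorted(counts, reverse=True)


class TestDensity:
    @pytest.mark.parametrize("n, w, area, expect", [
        (5, 200, 2.0, 2.5),    # 100×200 px at 10 µm/px = 2 mm²
        (0, 200, 2.0, 0.0),
        (9, 50, 0.5, 18.0),
    ])
    def test_density_values(self, n, w, area, expect):
        roi = ROIPolygon.rectangle(0, 0, w, 100)
        res = count_density([_dummy()] * n, roi, (100, w), pixel_size_um=10.0)
        assert res.roi_area_mm2 == pytest.approx(area)
        assert res.objects_per_mm2 == pytest.approx(expect)

    def test_tiling_invariance(self, rendered_three_disks):
        """Counts/areas over two half-ROIs reproduce the whole-ROI density."""
        image, _ = rendered_three_disks
        dab = dab_intensity_of(image)
        h, w = image.shape
        whole = full_frame_roi(image.shape)
        split = 90  # between planted disks: none straddles the boundary
        left = ROIPolygon.rectangle(0, 0, split, h)
        right = ROIPolygon.rectangle(split, 0, w, h)
        dens_whole = count_density(
            filter_objects(segment_candidates(dab, whole, pixel_size_um=0.5)),
            whole, image.shape, 0.5)
        parts = [count_density(
            filter_objects(segment_candidates(dab, r, pixel_size_um=0.5)),
            r, image.shape, 0.5) for r in (left, right)]
        n = sum(p.n_objects for p in parts)
        a = sum(p.roi_area_mm2 for p in parts)
        assert a == pytest.approx(dens_whole.roi_area_mm2)
        assert n / a == pytest.approx(dens_whole.objects_per_mm2)


class TestHistogram:
    def test_point_mass_and_conservation(self):
        objs = [_dummy(intensity=100.0), _dummy(intensity=100.0)]
        h = intensity_histogram(objs)
        assert h[100] == 2 and h.sum() == 2
        assert intensity_histogram([]).sum() == 0


class TestCalibration:
    @staticmethod
    def _hist_at(intensities):
        h = np.zeros(256, dtype=int)
        for i in intensities:
            h[i] += 1
        return h

    def test_separable_training_set(self):
        rng = np.random.default_rng(10)
        pos = [self._hist_at(rng.integers(120, 151, 40)) for _ in range(5)]
        neg = [self._hist_at(rng.integers(240, 256, 40)) for _ in range(5)]
        res = calibrate_positive_threshold(pos, neg)
        assert res.constrained
        assert 150 <= res.threshold <= 239
        assert res.positive_capture >= 0.99
        assert res.negative_capture <= 0.60

    def test_identical_distributions_unconstrained(self):
        h = self._hist_at([100] * 20)
        res = calibrate_positive_threshold([h], [h.copy()])
        assert not res.constrained

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            calibrate_positive_threshold([], [self._hist_at([100])])
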