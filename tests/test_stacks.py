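"""Stack preprocessing, ROI extraction and morphometry."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from skimage import draw

from vesipool.errors import InvalidInputError
from vesipool.frap import normalize_trace
from vesipool.sim import FieldGeometry, SimConfig, render_frap_stack
from vesipool.stacks import (
    CircleRoi,
    ImageStack,
    PolygonRoi,
    RoiSet,
    extract_roi_traces,
    measure_boutons,
    puncta_density,
    register_stack,
    roi_trace,
    sum_project,
)


def _textured_image(rng, shape=(96, 96)):
    img = np.zeros(shape)
    for _ in range(12):
        r, c = rng.uniform(15, shape[0] - 15, 2)
        rr, cc = draw.disk((r, c), rng.uniform(2, 5), shape=shape)
        img[rr, cc] += rng.uniform(50, 200)
    return ndi.gaussian_filter(img, 1.0)


class TestSumProject:
    def test_sum_of_identical_planes(self):
        planes = np.full((4, 8, 8), 3.0)
        out = sum_project([planes])
        assert np.all(out.data[0] == 12.0)

    def test_single_plane_identity(self, rng):
        img = rng.random((8, 8))
        out = sum_project([img])
        assert np.allclose(out.data[0], img, atol=1e-6)

    def test_matches_bruteforce_sum(self, rng):
        subs = [rng.random((3, 10, 10)) for _ in range(4)]
        out = sum_project(subs)
        for k, sub in enumerate(subs):
            brute = np.zeros((10, 10))
            for plane in sub:  # explicit-loop oracle
                brute += plane
            assert np.allclose(out.data[k], brute, atol=1e-4)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            sum_project([rng.random((2, 8, 8)), rng.random((2, 9, 9))])


class TestRegistration:
    def _drifting_stack(self, rng, drift, n_frames=6):
        base = _textured_image(rng)
        frames = [
            ndi.shift(base, (drift[0] * k, drift[1] * k), order=3, mode="nearest")
            for k in range(n_frames)
        ]
        return ImageStack(np.stack(frames), np.arange(n_frames, dtype=float), 0.2)

    def test_zero_drift_estimates_near_zero(self, rng):
        stack = self._drifting_stack(rng, (0.0, 0.0))
        _, drift = register_stack(stack)
        assert np.abs(drift).max() < 0.05

    def test_injected_drift_recovered(self, rng):
        stack = self._drifting_stack(rng, (2.3, -1.7))
        _, drift = register_stack(stack)
        truth = np.array([2.3, -1.7]) * np.arange(stack.n_frames)[:, None]
        assert np.abs(drift - truth).max() < 0.25

    def test_registration_increases_reference_correlation(self, rng):
        stack = self._drifting_stack(rng, (1.4, -0.9))
        aligned, _ = register_stack(stack)

        def mean_corr(s):
            ref = s.data[0].ravel()
            return np.mean(
                [np.corrcoef(ref, f.ravel())[0, 1] for f in s.data[1:]]
            )

        assert mean_corr(aligned) > mean_corr(stack)

    def test_all_zero_frame_warns_and_passes_through(self):
        data = np.zeros((3, 16, 16), dtype=np.float32)
        stack = ImageStack(data, [0.0, 1.0, 2.0], 0.2)
        with pytest.warns(UserWarning, match="degenerate"):
            aligned, drift = register_stack(stack)
        assert np.all(drift == 0)


class TestExtractRoiTraces:
    def _uniform_stack(self, value=7.0, n=4):
        data = np.full((n, 32, 32), value, dtype=np.float32)
        return ImageStack(data, np.arange(n, dtype=float), 0.2)

    def test_uniform_frame_gives_value_times_area(self):
        stack = self._uniform_stack(7.0)
        roi = CircleRoi(16, 16, 5)
        area = roi.mask((32, 32)).sum()
        trace = roi_trace(stack, roi)
        assert np.allclose(trace, 7.0 * area)

    def test_background_over_zero_region_is_zero(self):
        data = np.zeros((3, 32, 32), dtype=np.float32)
        data[:, :16] = 9.0
        stack = ImageStack(data, [0.0, 1.0, 2.0], 0.2)
        assert np.all(roi_trace(stack, CircleRoi(24, 24, 4)) == 0.0)

    def test_long_format_output(self):
        stack = self._uniform_stack()
        rois = RoiSet(
            bouton_rois=[CircleRoi(10, 10, 3)],
            cell_rois=[PolygonRoi(((20, 20), (20, 28), (28, 28), (28, 20)))],
            background_roi=CircleRoi(26, 8, 3),
        )
        df = extract_roi_traces(stack, rois)
        assert set(df["roi_kind"]) == {"bouton", "cell", "background"}
        assert len(df) == 3 * stack.n_frames

    def test_linearity(self, rng):
        # integer-valued data keeps float32 addition exact
        a = np.float32(rng.integers(0, 1000, (3, 24, 24)))
        b = np.float32(rng.integers(0, 1000, (3, 24, 24)))
        t = [0.0, 1.0, 2.0]
        roi = CircleRoi(12, 12, 6)
        ta = roi_trace(ImageStack(a, t, 1.0), roi)
        tb = roi_trace(ImageStack(b, t, 1.0), roi)
        tab = roi_trace(ImageStack(a + b, t, 1.0), roi)
        assert np.array_equal(tab, ta + tb)

    def test_empty_roi_rejected(self):
        stack = self._uniform_stack()
        # degenerate polygon between pixel centers covers no pixel
        empty = PolygonRoi(((5.2, 5.2), (5.3, 5.2), (5.2, 5.3)))
        with pytest.raises(InvalidInputError):
            roi_trace(stack, empty)


class TestEndToEndDriftRecovery:
    def test_registered_extraction_matches_drift_free_trace(self, standard_model):
        cfg = SimConfig(recovery_model=standard_model)
        still, rois, gt = render_frap_stack(cfg)
        drifting, _, _ = render_frap_stack(
            cfg, FieldGeometry(drift_per_frame=(0.15, -0.1))
        )
        aligned, _ = register_stack(drifting)
        norm_still = normalize_trace(gt["traces"][0])
        tr = roi_trace(aligned, rois.bouton_rois[0])
        truth = gt["traces"][0].bouton_raw
        assert np.max(np.abs(tr - truth) / truth.max()) < 0.02
        assert norm_still.post_values[0] == 0.0


class TestMeasureBoutons:
    def test_disk_area_recovered(self):
        img = np.zeros((100, 100))
        rr, cc = draw.disk((50, 50), 10)
        img[rr, cc] = 5.0
        ms = measure_boutons(img, pixel_size=0.5)
        assert len(ms) == 1
        assert ms[0].area == pytest.approx(np.pi * 10**2 * 0.25, rel=0.10)

    def test_blank_image_gives_empty_list(self):
        assert measure_boutons(np.zeros((50, 50))) == []

    def test_intensity_ratio_two_to_one(self):
        img = np.zeros((120, 120))
        for center, value in (((30, 30), 8.0), ((80, 80), 4.0)):
            rr, cc = draw.disk(center, 9)
            img[rr, cc] = value
        ms = measure_boutons(img)
        ints = sorted(m.integrated_intensity for m in ms)
        assert len(ints) == 2
        assert ints[1] / ints[0] == pytest.approx(2.0, rel=0.05)

    def test_additive_offset_invariance(self):
        img = np.zeros((100, 100))
        rr, cc = draw.disk((50, 50), 10)
        img[rr, cc] = 5.0
        base = measure_boutons(img)[0].integrated_intensity
        shifted = measure_boutons(img + 123.0)[0].integrated_intensity
        assert shifted == pytest.approx(base, rel=1e-6)

    def test_normalized_against_reference_mean(self):
        img = np.zeros((100, 100))
        rr, cc = draw.disk((50, 50), 10)
        img[rr, cc] = 5.0
        m = measure_boutons(img, reference_mean=100.0)[0]
        assert m.normalized_intensity == pytest.approx(m.integrated_intensity / 100.0)


class TestPunctaDensity:
    def _puncta_image(self, value=8.0):
        img = np.zeros((80, 80))
        for c in ((20, 20), (40, 60), (60, 30)):
            rr, cc = draw.disk(c, 6)
            img[rr, cc] = value
        return img

    def test_uniform_image_flagged_empty(self):
        res = puncta_density(np.full((50, 50), 3.0))
        assert res.mask_empty and res.mean_density == 0.0

    def test_density_approximates_punctum_value(self):
        res = puncta_density(self._puncta_image(8.0))
        assert res.mean_density == pytest.approx(8.0, rel=0.15)

    def test_density_linear_in_intensity(self):
        d1 = puncta_density(self._puncta_image(8.0)).mean_density
        d2 = puncta_density(self._puncta_image(16.0)).mean_density
        assert d2 / d1 == pytest.approx(2.0, rel=0.02)
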