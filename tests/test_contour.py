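"""CT ingestion, intensity transform, segmentation, contour extraction,
structure-file round trips."""

import numpy as np
import pytest

import rtclear as rc
from rtclear.contour import (
    CTVolume,
    SliceContour,
    export_contours,
    extract_slice_contours,
    hu_to_gray,
    import_contours,
    intensity_transform,
    load_ct_series,
    segment_mask,
)
from rtclear.errors import ContourError, CTSeriesError
from rtclear._polygon import is_simple, signed_area


def _tiny_volume(nz=4, n=32, spacing=2.0):
    vox = np.full((nz, n, n), -1000, dtype=np.int16)
    zs = np.arange(nz) * 5.0
    half = (n - 1) / 2 * spacing
    return CTVolume(
        voxels=vox,
        pixel_spacing=(spacing, spacing),
        slice_positions=zs,
        origin=(-half, -half, 0.0),
    )


class TestCTVolume:
    def test_nonuniform_slice_gap_rejected(self):
        with pytest.raises(CTSeriesError, match="spacing"):
            CTVolume(
                voxels=np.zeros((3, 4, 4)),
                pixel_spacing=(1.0, 1.0),
                slice_positions=[0.0, 5.0, 12.0],
            )

    def test_isocenter_outside_rejected(self):
        vol = _tiny_volume()
        with pytest.raises(ContourError, match="outside"):
            vol.set_isocenter((1000.0, 0.0, 0.0))


class TestDicomSeriesRoundTrip:
    def test_series_reloads_voxel_identical(self, tmp_path, phantom_vol):
        rc.write_dicom_series(phantom_vol, tmp_path)
        back = load_ct_series(tmp_path)
        assert back.voxels.shape == phantom_vol.voxels.shape
        assert np.array_equal(back.voxels, phantom_vol.voxels)
        assert np.allclose(back.slice_positions, phantom_vol.slice_positions)
        assert back.pixel_spacing == phantom_vol.pixel_spacing
        assert np.allclose(back.origin, phantom_vol.origin)

    def test_order_from_positions_not_filenames(self, tmp_path, phantom_vol):
        paths = rc.write_dicom_series(phantom_vol, tmp_path)
        # shuffle names
        rng = np.random.default_rng(0)
        tmp_names = [p.with_suffix(".tmp") for p in paths]
        for p, t in zip(paths, tmp_names):
            p.rename(t)
        order = rng.permutation(len(paths))
        for t, k in zip(tmp_names, order):
            t.rename(t.parent / f"scrambled_{k:04d}.dcm")
        back = load_ct_series(tmp_path)
        assert np.array_equal(back.voxels, phantom_vol.voxels)

    def test_gap_error_when_slice_removed(self, tmp_path, phantom_vol):
        paths = rc.write_dicom_series(phantom_vol, tmp_path)
        paths[len(paths) // 2].unlink()
        with pytest.raises(CTSeriesError, match="gap"):
            load_ct_series(tmp_path)


class TestIntensityTransform:
    def test_window_endpoints_and_midpoint(self):
        vol = np.array([[[-500.0, 300.0, -100.0, -101.0]]])
        g = intensity_transform(vol, -500, 300)
        assert g[0, 0, 0] == 0
        assert g[0, 0, 1] == 255
        assert g[0, 0, 2] == 128  # midpoint rounds half-up
        assert hu_to_gray(-500, -500, 300) == 0

    def test_clamping(self):
        g = intensity_transform(np.array([[[-2000.0, 2000.0]]]), -500, 300)
        assert g[0, 0, 0] == 0 and g[0, 0, 1] == 255

    def test_invalid_window(self):
        with pytest.raises(ContourError):
            intensity_transform(np.zeros((1, 1, 1)), 10, 10)


class TestSegmentMask:
    def test_closing_fills_notch(self):
        img = np.zeros((1, 40, 40), dtype=np.uint8)
        rr, cc = np.mgrid[0:40, 0:40]
        disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 15**2
        img[0][disk] = 255
        img[0, 19:21, 5:21] = 0  # 2-px notch cut into the disk
        mask = segment_mask(img, 128, closing_radius_px=3)
        assert mask[0][19:21, 8:20].all()  # notch interior closed

    def test_all_air_slice_is_empty(self):
        g = intensity_transform(np.full((1, 16, 16), -1000.0), -500, 300)
        assert not segment_mask(g, 128, 2).any()

    def test_closing_idempotent(self):
        rng = np.random.default_rng(3)
        img = (rng.random((1, 48, 48)) > 0.6).astype(np.uint8) * 255
        m1 = segment_mask(img, 128, 2)
        m2 = segment_mask(m1.astype(np.uint8) * 255, 128, 2)
        assert np.array_equal(m1, m2)


class TestExtractSliceContours:
    def _vol_with_mask(self, mask):
        nz, n, _ = mask.shape
        vol = _tiny_volume(nz=nz, n=n)
        vol.plate_height_mm = vol.v_coords()[2]  # third row from the bottom
        vol.set_isocenter((0.0, 0.0, vol.slice_positions[nz // 2]))
        return vol

    def test_circle_area_matches_pixel_count(self):
        n = 128
        mask = np.zeros((2, n, n), dtype=bool)
        rr, cc = np.mgrid[0:n, 0:n]
        disk = (rr - 70) ** 2 + (cc - 64) ** 2 <= 25**2
        mask[:] = disk
        vol = _tiny_volume(nz=2, n=n, spacing=1.0)
        vol.plate_height_mm = vol.v_coords()[1]
        vol.set_isocenter((0.0, 10.0, vol.slice_positions[0]))
        stack = extract_slice_contours(mask, vol, min_area_mm2=10.0)
        area = stack.for_label("body")[0].area_mm2
        rasterized = disk.sum() * 1.0  # the independent pixel-count oracle
        assert abs(area - rasterized) / rasterized < 0.02

    def test_two_components_become_two_colliders(self):
        n = 64
        mask = np.zeros((3, n, n), dtype=bool)
        mask[:, 30:50, 8:28] = True  # large: body
        mask[:, 35:45, 40:55] = True  # small: accessory
        vol = self._vol_with_mask(mask)
        stack = extract_slice_contours(mask, vol, min_area_mm2=10.0)
        assert stack.labels() == ["accessory_1", "body"]
        assert len(stack.for_label("body")) == 3

    def test_component_below_plate_excluded(self):
        n = 64
        mask = np.zeros((2, n, n), dtype=bool)
        mask[:, 0:2, 10:50] = True  # below plate (plate at row 2)
        mask[:, 30:50, 10:50] = True
        vol = self._vol_with_mask(mask)
        stack = extract_slice_contours(mask, vol, min_area_mm2=10.0)
        assert stack.labels() == ["body"]
        v_min = min(c.points[:, 1].min() for c in stack.for_label("body"))
        assert v_min > vol.plate_height_mm

    def test_empty_stack_is_error(self):
        n = 32
        mask = np.zeros((2, n, n), dtype=bool)
        vol = self._vol_with_mask(mask)
        with pytest.raises(ContourError, match="no collider"):
            extract_slice_contours(mask, vol, min_area_mm2=10.0)

    def test_output_polygons_simple_and_ccw(self, phantom_stack):
        for label in phantom_stack.labels():
            for c in phantom_stack.for_label(label):
                assert signed_area(c.points) > 0
                assert is_simple(c.points)


class TestWindowInvariance:
    def test_same_hu_cut_same_contours(self, phantom_vol):
        # two windows, one effective HU threshold -> identical masks
        s1 = rc.contour_pipeline(phantom_vol, window_hu=(-500, 300), threshold_hu=-300)
        s2 = rc.contour_pipeline(phantom_vol, window_hu=(-400, 500), threshold_hu=-300)
        a1 = [c.area_mm2 for c in s1.for_label("body")]
        a2 = [c.area_mm2 for c in s2.for_label("body")]
        assert np.allclose(a1, a2)


class TestStructureFileRoundTrip:
    def test_points_survive_within_micron_scale(self, tmp_path, phantom_stack):
        path = tmp_path / "case.dcm"
        export_contours(phantom_stack, path)
        back = import_contours(path)
        assert back.labels() == phantom_stack.labels()
        assert np.allclose(back.isocenter_mm, phantom_stack.isocenter_mm, atol=1e-3)
        assert back.plate_height_mm == pytest.approx(
            phantom_stack.plate_height_mm, abs=1e-3
        )
        for label in phantom_stack.labels():
            for a, b in zip(phantom_stack.for_label(label), back.for_label(label)):
                assert a.z_mm == pytest.approx(b.z_mm, abs=1e-3)
                assert np.abs(a.points - b.points).max() < 1e-3

    def test_structure_count(self, tmp_path, shell_stack):
        import pydicom

        path = tmp_path / "case.dcm"
        export_contours(shell_stack, path)
        ds = pydicom.dcmread(str(path))
        names = {str(r.ROIName) for r in ds.StructureSetROISequence}
        assert "ISOCENTER" in names and "CT_PLATE" in names
        assert len(names) == len(shell_stack.labels()) + 2

    def test_missing_plate_roi_is_error(self, tmp_path, phantom_stack):
        import pydicom

        path = tmp_path / "case.dcm"
        export_contours(phantom_stack, path)
        ds = pydicom.dcmread(str(path))
        keep = [
            i
            for i, r in enumerate(ds.StructureSetROISequence)
            if str(r.ROIName) != "CT_PLATE"
        ]
        ds.StructureSetROISequence = [ds.StructureSetROISequence[i] for i in keep]
        ds.ROIContourSequence = [ds.ROIContourSequence[i] for i in keep]
        broken = tmp_path / "broken.dcm"
        ds.save_as(str(broken), enforce_file_format=True)
        with pytest.raises(ContourError, match="plate"):
            import_contours(broken)
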