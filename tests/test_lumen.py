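"""Lumen quantification: areas, patency, narrowing, thrombosis."""

import numpy as np
import pytest

from mvoct import (
    ScanGeometry,
    VesselSpec,
    analyze_volume,
    area_from_mask,
    build_scene,
    narrowing_pct,
    patency_pct,
    thrombosis_pct,
)
from mvoct.lumen import round_half_up


class TestAreaFromMask:
    def test_pixel_count_times_pixel_area(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10, :10] = True
        assert area_from_mask(mask, (0.015, 0.00977)) == pytest.approx(100 * 1.4655e-4)

    def test_empty_mask_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert area_from_mask(np.zeros((4, 4), dtype=bool), (0.1, 0.1)) == 0.0

    @pytest.mark.parametrize("n", [128, 256, 512])
    def test_disk_area_converges_to_pi_r_squared(self, n):
        r = 0.2585
        px = 1.2 / n
        xs = (np.arange(n) + 0.5) * px
        X, Z = np.meshgrid(xs, xs, indexing="ij")
        disk = np.hypot(X - 0.6, Z - 0.6) <= r
        area = area_from_mask(disk, (px, px))
        boundary_tol = 2 * np.pi * r * px  # one pixel-area per boundary pixel
        assert abs(area - np.pi * r**2) < boundary_tol


class TestPercentages:
    def test_patency_full_flow(self):
        assert patency_pct(0.21, 0.21) == 100.0

    def test_patency_partial(self):
        assert patency_pct(0.0896, 0.16) == pytest.approx(56.0)

    def test_patency_requires_positive_lumen(self):
        with pytest.raises(ValueError):
            patency_pct(0.1, 0.0)

    @pytest.mark.parametrize(
        "area,ref,expected_int",
        [(0.09, 0.46, 80), (0.11, 0.46, 76), (0.11, 0.18, 39), (0.13, 0.18, 28),
         (0.21, 0.21, 0)],
    )
    def test_narrowing_from_printed_lumen_areas(self, area, ref, expected_int):
        assert int(round_half_up(narrowing_pct(area, ref))) == expected_int

    def test_narrowing_negative_when_dilated(self):
        assert narrowing_pct(0.25, 0.20) == pytest.approx(-25.0)

    def test_narrowing_invariant_under_pixel_rescale(self):
        assert narrowing_pct(0.11, 0.18) == pytest.approx(narrowing_pct(1.1, 1.8))

    @pytest.mark.parametrize("patency,expected", [(100.0, 0.0), (56.0, 44.0), (80.0, 20.0)])
    def test_thrombosis_complement(self, patency, expected):
        assert thrombosis_pct(patency) == pytest.approx(expected)

    def test_thrombosis_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            thrombosis_pct(120.0)

    def test_patency_plus_thrombosis_is_identity(self):
        for p in np.linspace(0, 100, 23):
            assert patency_pct(p, 100.0) + thrombosis_pct(p) == pytest.approx(100.0)


@pytest.fixture(scope="module")
def thrombus_scene():
    g = ScanGeometry(fov_x_mm=1.2, fov_y_mm=0.2, depth_range_mm=1.2,
                     n_x=400, n_z=400, n_frames=3)
    v = VesselSpec(center_x_mm=0.6, center_z_mm=0.6, radius_mm=0.25,
                   peak_velocity_mm_s=5.0, thrombus_fraction=0.44,
                   thrombus_anchor_rad=0.7)
    return build_scene(g, [v], 0.05, seed=2)


class TestAnalyzeVolume:
    def test_thrombus_fraction_reported_as_thrombosis_pct(self, thrombus_scene):
        g = thrombus_scene.geometry
        report = analyze_volume(
            thrombus_scene.lumen_mask,
            thrombus_scene.flow_mask,
            reference_frame_id=0,
            pixel_size_mm=(g.dx_mm, g.dz_mm),
        )
        assert np.allclose(report.table["thrombosis_pct"], 44.0, atol=2.0)
        assert np.allclose(
            report.table["patency_pct"] + report.table["thrombosis_pct"], 100.0
        )

    def test_all_flow_scene_is_fully_patent(self, flow_scene):
        g = flow_scene.geometry
        report = analyze_volume(
            flow_scene.lumen_mask,
            flow_scene.flow_mask,
            reference_frame_id=0,
            pixel_size_mm=(g.dx_mm, g.dz_mm),
        )
        assert (report.table["patency_pct"] == 100.0).all()
        assert (report.table["narrowing_pct"] == 0.0).all()

    def test_flow_autoderived_from_doppler_magnitude(self, thrombus_scene):
        g = thrombus_scene.geometry
        report = analyze_volume(
            thrombus_scene.lumen_mask,
            None,
            reference_frame_id=0,
            pixel_size_mm=(g.dx_mm, g.dz_mm),
            doppler_stack=thrombus_scene.axial_velocity,
            v_min_mm_s=0.363,
        )
        # parabolic profile dips below v_min near the wall, so patency is a
        # little below the geometric 56% but far above zero
        assert 40 < report.table["patency_pct"].iloc[0] < 56.5

    def test_mask_shape_mismatch_names_frame(self, thrombus_scene):
        g = thrombus_scene.geometry
        bad_flow = thrombus_scene.flow_mask[:, :, :-3]
        with pytest.raises(ValueError, match="frame"):
            analyze_volume(
                thrombus_scene.lumen_mask,
                bad_flow,
                reference_frame_id=0,
                pixel_size_mm=(g.dx_mm, g.dz_mm),
            )

    def test_missing_reference_frame_rejected(self, thrombus_scene):
        g = thrombus_scene.geometry
        with pytest.raises(ValueError, match="reference"):
            analyze_volume(
                thrombus_scene.lumen_mask,
                thrombus_scene.flow_mask,
                reference_frame_id=99,
                pixel_size_mm=(g.dx_mm, g.dz_mm),
            )
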