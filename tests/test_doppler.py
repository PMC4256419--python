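"""Phase-resolved Doppler: calibration, antisymmetry, range, wrapping."""

import numpy as np
import pytest

from mvoct import (
    AcqParams,
    SourceSpec,
    doppler_range,
    phase_difference,
    reconstruct,
    synth_mirror_series,
    velocity_map,
)
from mvoct.recon import ComplexBScan

from conftest import NOISELESS


class TestPhaseDifference:
    def test_static_field_gives_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((8, 16)) + 1j * rng.standard_normal((8, 16))
        vals = np.tile(vals[:1], (8, 1))
        b = ComplexBScan(vals, dz_mm=0.01)
        assert np.allclose(phase_difference(b), 0.0)

    def test_conjugation_flips_sign(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((12, 10)) + 1j * rng.standard_normal((12, 10))
        b = ComplexBScan(vals, dz_mm=0.01)
        b_conj = ComplexBScan(np.conj(vals), dz_mm=0.01)
        assert np.allclose(phase_difference(b_conj), -phase_difference(b), atol=1e-12)

    def test_uniform_velocity_phase_step(self, flat_source, acq):
        # 5 mm/s -> dphi = 4 pi v dt / lambda0 = 0.9593 rad
        frame = synth_mirror_series(1.25, 16, flat_source, acq, NOISELESS,
                                    velocity_mm_s=5.0)
        b = reconstruct(frame, window="rect")
        surface = int(round(1.25 / flat_source.dz_mm))
        dphi = phase_difference(b)[:-1, surface]
        assert np.allclose(dphi, 0.95927, atol=1e-4)

    def test_oversized_window_rejected(self):
        b = ComplexBScan(np.ones((4, 4), dtype=complex), dz_mm=0.01)
        with pytest.raises(ValueError, match="avg_window"):
            phase_difference(b, avg_window=(10, 1))

    def test_kasai_window_averages_noise(self):
        rng = np.random.default_rng(2)
        base = np.exp(1j * rng.normal(0, 0.3, (64, 64)))
        b = ComplexBScan(base, dz_mm=0.01)
        raw = phase_difference(b)
        smooth = phase_difference(b, avg_window=(4, 4))
        assert smooth.std() < raw.std()


class TestVelocityMap:
    def test_pi_maps_to_wrap_limit(self, acq):
        src = SourceSpec()
        dmap = velocity_map(np.array([[np.pi]]), src, acq)
        assert dmap.velocity_mm_s[0, 0] == pytest.approx(16.375)
        assert dmap.velocity_mm_s[0, 0] == pytest.approx(16.3, rel=0.01)
        assert dmap.wrap_flag[0, 0]

    def test_zero_phase_zero_velocity(self, acq):
        dmap = velocity_map(np.zeros((2, 2)), SourceSpec(), acq)
        assert np.all(dmap.velocity_mm_s == 0)
        assert not np.any(dmap.wrap_flag)

    def test_phase_noise_floor_velocity(self, acq):
        dmap = velocity_map(np.array([[0.070]]), SourceSpec(), acq)
        assert dmap.velocity_mm_s[0, 0] == pytest.approx(0.3649, abs=2e-4)
        # the instrument's quoted figure is 0.363; accept within 1%
        assert dmap.velocity_mm_s[0, 0] == pytest.approx(0.363, rel=0.01)

    def test_out_of_range_phase_rejected(self, acq):
        with pytest.raises(ValueError):
            velocity_map(np.array([[4.0]]), SourceSpec(), acq)

    def test_intensity_gate_masks_low_snr(self, acq):
        phase = np.zeros((2, 2))
        intensity = np.array([[0.0, -50.0], [-50.0, 0.0]])
        dmap = velocity_map(phase, SourceSpec(), acq, intensity_db=intensity,
                            noise_floor_db=-40.0)
        assert dmap.validity_mask.tolist() == [[True, False], [False, True]]


class TestDopplerRange:
    def test_defaults_match_quoted_range(self, acq):
        v_min, v_max = doppler_range(0.070, SourceSpec(), acq)
        assert v_min == pytest.approx(0.3649, abs=2e-4)
        assert v_max == pytest.approx(16.375, abs=1e-3)

    def test_half_pi_sigma_gives_half_vmax(self, acq):
        v_min, v_max = doppler_range(np.pi / 2, SourceSpec(), acq)
        assert v_min == pytest.approx(v_max / 2)

    def test_halving_dt_doubles_both_bounds(self):
        lo1 = doppler_range(0.1, SourceSpec(), AcqParams(aline_rate_hz=50_000))
        lo2 = doppler_range(0.1, SourceSpec(), AcqParams(aline_rate_hz=100_000))
        assert lo2[0] == pytest.approx(2 * lo1[0])
        assert lo2[1] == pytest.approx(2 * lo1[1])

    def test_sigma_at_or_above_pi_rejected(self, acq):
        with pytest.raises(ValueError):
            doppler_range(np.pi, SourceSpec(), acq)


class TestEndToEndRecovery:
    def test_parabolic_profile_recovered_exactly_noise_free(self, flow_scene, flat_source, acq):
        from mvoct import synth_bscan

        frame = synth_bscan(flow_scene, 0, flat_source, acq, NOISELESS, seed=5)
        b = reconstruct(frame, window="rect")
        dmap = velocity_map(phase_difference(b), flat_source, acq)
        gt = flow_scene.axial_velocity[0]
        m = flow_scene.flow_mask[0]
        rmse = np.sqrt(np.mean((dmap.velocity_mm_s[m] - gt[m]) ** 2))
        assert rmse < 0.02 * 10.0

    def test_aliasing_wraps_modulo_twice_vmax(self, small_geometry, flat_source, acq):
        from mvoct import VesselSpec, build_scene, synth_bscan

        v_true = 20.0
        vessel = VesselSpec(center_x_mm=0.75, center_z_mm=1.25, radius_mm=0.25,
                            peak_velocity_mm_s=v_true)
        scene = build_scene(small_geometry, [vessel], 0.05, seed=0)
        frame = synth_bscan(scene, 0, flat_source, acq, NOISELESS, seed=7)
        b = reconstruct(frame, window="rect")
        dmap = velocity_map(phase_difference(b), flat_source, acq)
        center = dmap.velocity_mm_s[150, int(round(1.25 / flat_source.dz_mm))]
        assert center == pytest.approx(v_true - 2 * 16.375, abs=0.05)
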