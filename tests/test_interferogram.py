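"""Fringe synthesis: linearity, Parseval, Doppler phase encoding, roll-off."""

import numpy as np
import pytest

from mvoct import (
    AcqParams,
    NoiseModel,
    SourceSpec,
    reconstruct,
    synth_aline,
    synth_bscan,
    synth_mirror_series,
)
from mvoct.doppler import phase_difference
from mvoct.interferogram import SpectralFrame

from conftest import NOISELESS


def _frame(fringe, source):
    return SpectralFrame(fringe[:, None], source, AcqParams(), NOISELESS)


class TestSynthAline:
    def test_single_reflector_fft_peak_at_depth_bin(self, small_source):
        depth = 1.5
        fringe = synth_aline([(depth, 1.0, 0.0)], small_source, NOISELESS)
        b = reconstruct(_frame(fringe, small_source), window="rect")
        peak_bin = int(np.argmax(np.abs(b.values[0])))
        assert peak_bin == round(depth / small_source.dz_mm)

    def test_linearity_of_superposition(self, small_source):
        f1 = synth_aline([(0.8, 1.0, 0.3)], small_source, NOISELESS)
        f2 = synth_aline([(1.7, 0.5, -1.0)], small_source, NOISELESS)
        f12 = synth_aline([(0.8, 1.0, 0.3), (1.7, 0.5, -1.0)], small_source, NOISELESS)
        assert np.allclose(f12, f1 + f2, atol=1e-12)

    def test_parseval_energy_conserved(self, small_source):
        fringe = synth_aline([(1.1, 1.0, 0.0)], small_source, NOISELESS)
        spectrum = np.fft.fft(fringe)
        assert np.sum(fringe**2) == pytest.approx(
            np.sum(np.abs(spectrum) ** 2) / small_source.n_k, rel=1e-10
        )

    def test_rolloff_attenuates_reconstructed_peak(self, small_source):
        noise = NoiseModel(phase_jitter_sd_rad=0.0, noise_floor_db=-300.0,
                           rolloff_db_per_mm=5.7)
        near = synth_aline([(0.5, 1.0, 0.0)], small_source, noise)
        far = synth_aline([(1.5, 1.0, 0.0)], small_source, noise)
        p = lambda f: np.abs(reconstruct(_frame(f, small_source), window="rect",
                                         pad_factor=8).values[0]).max()
        drop_db = 20 * np.log10(p(near) / p(far))
        assert drop_db == pytest.approx(5.7, abs=0.1)

    def test_negative_depth_rejected(self, small_source):
        with pytest.raises(ValueError):
            synth_aline([(-0.1, 1.0, 0.0)], small_source, NOISELESS)


class TestSynthBscan:
    def test_static_scene_has_zero_phase_differences(self, flow_scene, flat_source, acq):
        static = flow_scene
        # zero out velocities by using a zero-velocity copy
        import dataclasses

        scene = dataclasses.replace(
            static, axial_velocity=np.zeros_like(static.axial_velocity)
        )
        frame = synth_bscan(scene, 0, flat_source, acq, NOISELESS, seed=3)
        b = reconstruct(frame, window="rect")
        dphi = phase_difference(b)
        refl = scene.reflectivity[0] > 0
        refl[:, 0] = False  # bin 0 is the (mean-subtracted) zero-delay line
        assert np.max(np.abs(dphi[refl])) < 1e-8

    def test_phase_step_is_pi_at_wrap_velocity(self, flat_source, acq):
        v_max = flat_source.lambda0_um * 1e-3 / (4 * acq.delta_t_s)  # 16.375 mm/s
        frame = synth_mirror_series(1.25, 8, flat_source, acq, NOISELESS,
                                    velocity_mm_s=v_max)
        b = reconstruct(frame, window="rect")
        surface = int(round(1.25 / flat_source.dz_mm))
        dphi = phase_difference(b)[:-1, surface]
        assert np.allclose(np.abs(dphi), np.pi, atol=1e-6)

    def test_velocity_above_wrap_limit_wraps_negative(self, flat_source, acq):
        frame = synth_mirror_series(1.25, 8, flat_source, acq, NOISELESS,
                                    velocity_mm_s=20.0)
        b = reconstruct(frame, window="rect")
        surface = int(round(1.25 / flat_source.dz_mm))
        dphi = phase_difference(b)[0, surface]
        expected = np.angle(np.exp(1j * 4 * np.pi * 20.0 * acq.delta_t_s / 1.31e-3))
        assert dphi == pytest.approx(expected, abs=1e-6)
        assert dphi < 0

    def test_geometry_mismatch_rejected(self, flow_scene, acq):
        wrong = SourceSpec(n_k=256, depth_range_mm=2.5)
        with pytest.raises(ValueError, match="n_z"):
            synth_bscan(flow_scene, 0, wrong, acq, NOISELESS, seed=0)

    def test_frame_index_out_of_range(self, flow_scene, flat_source, acq):
        with pytest.raises(ValueError, match="frame_index"):
            synth_bscan(flow_scene, 99, flat_source, acq, NOISELESS, seed=0)

    def test_same_seed_bit_identical_fringes(self, flow_scene, small_source, acq):
        noise = NoiseModel(phase_jitter_sd_rad=0.07, noise_floor_db=-60.0)
        a = synth_bscan(flow_scene, 0, small_source, acq, noise, seed=11)
        b = synth_bscan(flow_scene, 0, small_source, acq, noise, seed=11)
        assert np.array_equal(a.fringes, b.fringes)

    def test_dc_component_removed(self, flow_scene, small_source, acq):
        frame = synth_bscan(flow_scene, 0, small_source, acq, NOISELESS, seed=0)
        assert np.allclose(frame.fringes.mean(axis=0), 0.0, atol=1e-12)
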