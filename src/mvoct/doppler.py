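"""Phase-resolved Doppler processing.

The axial velocity at a pixel follows from the phase difference between the
complex A-lines of adjacent lateral positions,

    v_axial = lambda0 * dphi / (4 pi dt),

with ``dt`` the inter-A-line interval.  The unambiguous range is
``|v| <= lambda0 / (4 dt)`` (phase wrap at +/- pi); the noise floor is set by
the phase stability ``sigma`` as ``v_min = lambda0 sigma / (4 pi dt)``.  With
the default 1.31 um source at 50 kHz and 70 mrad phase noise this is
0.365 ... 16.4 mm/s in both directions.  No unwrapping is attempted; wrapped
pixels are only flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .interferogram import AcqParams, SourceSpec
from .recon import ComplexBScan

__all__ = ["DopplerMap", "phase_difference", "velocity_map", "doppler_range"]


@dataclass
class DopplerMap:
    """Calibrated axial-velocity map with validity and wrap flags."""

    phase_diff_rad: np.ndarray  # (n_x, n_z), in (-pi, pi]
    velocity_mm_s: np.ndarray
    validity_mask: np.ndarray  # intensity-gated
    wrap_flag: np.ndarray  # |dphi| within tolerance of pi
    v_max_mm_s: float


def phase_difference(
    b: ComplexBScan, avg_window: tuple[int, int] = (1, 1)
) -> np.ndarray:
    """Inter-A-line phase difference map, optionally Kasai-averaged.

    ``dphi(x, z) = arg( sum_window A(x+1, .) conj(A(x, .)) )`` over a
    ``(pixels_x, pixels_z)`` neighborhood.  The result has the same width as
    the input; the last column (which has no successor) is an edge copy.
    """
    if b.n_x < 2:
        raise ValueError("need at least 2 A-lines for a phase difference")
    wx, wz = avg_window
    if wx < 1 or wz < 1:
        raise ValueError("avg_window entries must be >= 1")
    if wx > b.n_x - 1 or wz > b.n_z:
        raise ValueError(
            f"avg_window {avg_window} exceeds the correlation map size "
            f"({b.n_x - 1}, {b.n_z})"
        )
    corr = b.values[1:, :] * np.conj(b.values[:-1, :])
    if (wx, wz) != (1, 1):
        corr = uniform_filter(corr.real, (wx, wz), mode="nearest") + 1j * uniform_filter(
            corr.imag, (wx, wz), mode="nearest"
        )
    dphi = np.angle(corr)
    return np.concatenate([dphi, dphi[-1:, :]], axis=0)


def velocity_map(
    phase: np.ndarray,
    source: SourceSpec,
    acq: AcqParams,
    *,
    intensity_db: np.ndarray | None = None,
    noise_floor_db: float | None = None,
    gate_margin_db: float = 10.0,
    wrap_tol_rad: float = 0.05,
    refractive_index: float = 1.0,
) -> DopplerMap:
    """Calibrate a phase-difference map into axial velocities (mm/s).

    Doppler values are marked valid only where the structural intensity
    exceeds ``noise_floor_db + gate_margin_db`` (phase is meaningless in
    noise); with no intensity image every pixel is valid.  The calibration
    divides by ``refractive_index`` (default 1: in-air convention).
    """
    phase = np.asarray(phase, dtype=float)
    if np.any(np.abs(phase) > np.pi + 1e-9):
        raise ValueError("phases must lie in (-pi, pi]")
    lam_mm = source.lambda0_um * 1e-3
    scale = lam_mm / (4.0 * np.pi * acq.delta_t_s * refractive_index)
    v = scale * phase
    wrap = np.abs(phase) >= np.pi - wrap_tol_rad
    if intensity_db is not None and noise_floor_db is not None:
        valid = np.asarray(intensity_db) > noise_floor_db + gate_margin_db
    else:
        valid = np.ones(phase.shape, dtype=bool)
    return DopplerMap(
        phase_diff_rad=phase,
        velocity_mm_s=v,
        validity_mask=valid,
        wrap_flag=wrap,
        v_max_mm_s=scale * np.pi,
    )


def doppler_range(
    sigma_phase_rad: float, source: SourceSpec, acq: AcqParams
) -> tuple[float, float]:
    """Measurable axial-velocity range ``(v_min, v_max)`` in mm/s.

    ``v_min = lambda0 sigma / (4 pi dt)`` (phase-noise floor) and
    ``v_max = lambda0 / (4 dt)`` (wrap limit).
    """
    if not 0 < sigma_phase_rad < np.pi:
        raise ValueError("sigma_phase_rad must lie in (0, pi): no dynamic range otherwise")
    lam_mm = source.lambda0_um * 1e-3
    v_max = lam_mm / (4.0 * acq.delta_t_s)
    v_min = lam_mm * sigma_phase_rad / (4.0 * np.pi * acq.delta_t_s)
    return v_min, v_max
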