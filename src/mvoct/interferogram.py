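"""Forward simulation of swept-source spectral fringes.

The sampled spectrum of one A-line is modelled directly on a grid that is
uniform in wavenumber k (emulating hardware k-clocking), with the fringe of a
reflector at depth ``z`` (in air, single-sided from the zero-delay line)

    f(k) = a * rolloff(z) * env(k) * cos(2 k z + phi + a2 (k - k0)^2)

where ``env`` is a Gaussian spectral envelope, ``rolloff`` the depth-dependent
sensitivity decay (linear in dB per mm), ``phi`` a per-reflector phase offset,
and ``a2`` a residual second-order dispersion coefficient.  Additive detector
noise is white Gaussian, calibrated so that the reconstructed noise floor sits
at ``noise_floor_db`` relative to the reconstructed peak of a unit reflector.

Between consecutive A-lines of a B-scan each moving voxel advances its phase
by ``4 pi v dt / lambda0`` and every A-line additionally accumulates an
independent N(0, sigma^2) global phase increment (trigger/scanner jitter), so
that the inter-A-line phase difference on a static reflector has standard
deviation exactly ``sigma``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "SourceSpec",
    "AcqParams",
    "NoiseModel",
    "SpectralFrame",
    "synth_aline",
    "synth_bscan",
    "synth_mirror_series",
]


@dataclass(frozen=True)
class SourceSpec:
    """Swept laser source and spectral sampling.

    ``depth_range_mm`` is the single-sided imaging range mapped onto
    ``n_k/2`` reconstructed pixels; it fixes the digitized k-span via
    ``span_k = pi / dz`` (the digitizer window of a k-clocked system, which
    is narrower than the full tuning range quoted for the source).
    """

    lambda0_um: float = 1.31
    sweep_range_nm: float = 100.0  # nominal tuning range (metadata)
    n_k: int = 1024
    spectral_envelope_fwhm_nm: float = 60.1
    depth_range_mm: float = 5.0
    envelope_shape: str = "gaussian"  # "gaussian" or "flat" (idealized source)

    def __post_init__(self) -> None:
        if self.n_k < 2 or self.n_k % 2:
            raise ValueError("n_k must be an even integer >= 2")
        if self.lambda0_um <= 0 or self.depth_range_mm <= 0:
            raise ValueError("lambda0_um and depth_range_mm must be > 0")
        if self.envelope_shape not in ("gaussian", "flat"):
            raise ValueError("envelope_shape must be 'gaussian' or 'flat'")
        if self.spectral_envelope_fwhm_nm > self.sweep_range_nm:
            raise ValueError("spectral envelope FWHM cannot exceed the sweep range")

    @property
    def n_z(self) -> int:
        return self.n_k // 2

    @property
    def dz_mm(self) -> float:
        """Axial pixel pitch of the reconstruction (mm, in air)."""
        return self.depth_range_mm / self.n_z

    @property
    def k0_per_mm(self) -> float:
        return 2.0 * np.pi / (self.lambda0_um * 1e-3)

    @property
    def dk_per_mm(self) -> float:
        """k-grid step; span n_k*dk = pi/dz maps bin m to depth m*dz."""
        return np.pi / (self.n_k * self.dz_mm)

    def k_grid_per_mm(self) -> np.ndarray:
        """Uniform wavenumber samples centered on k0 (1/mm)."""
        n = np.arange(self.n_k) - self.n_k / 2
        return self.k0_per_mm + n * self.dk_per_mm

    def envelope(self) -> np.ndarray:
        """Spectral amplitude envelope evaluated on the k grid."""
        if self.envelope_shape == "flat":
            return np.ones(self.n_k)
        lam_mm = self.lambda0_um * 1e-3
        fwhm_k = 2.0 * np.pi * (self.spectral_envelope_fwhm_nm * 1e-6) / lam_mm**2
        sigma_k = fwhm_k / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        k = self.k_grid_per_mm()
        return np.exp(-0.5 * ((k - self.k0_per_mm) / sigma_k) ** 2)


@dataclass(frozen=True)
class AcqParams:
    """A-line timing."""

    aline_rate_hz: float = 50_000.0

    def __post_init__(self) -> None:
        if self.aline_rate_hz <= 0:
            raise ValueError("aline_rate_hz must be > 0")

    @property
    def delta_t_s(self) -> float:
        return 1.0 / self.aline_rate_hz


@dataclass(frozen=True)
class NoiseModel:
    """Noise and signal-degradation parameters.

    ``noise_floor_db`` is the reconstructed noise floor (rms bin magnitude)
    in dB relative to the reconstructed peak of a unit-amplitude reflector at
    zero depth; ``-inf``-like large negative values make noise negligible.
    """

    phase_jitter_sd_rad: float = 0.070
    noise_floor_db: float = -100.0
    rolloff_db_per_mm: float = 5.7
    dispersion_a2: float = 0.0  # rad per (rad/um)^2, second-order spectral phase

    def __post_init__(self) -> None:
        if self.phase_jitter_sd_rad < 0:
            raise ValueError("phase_jitter_sd_rad must be >= 0")
        if self.rolloff_db_per_mm < 0:
            raise ValueError("rolloff_db_per_mm must be >= 0")

    def rolloff_amplitude(self, depth_mm: np.ndarray | float) -> np.ndarray | float:
        return 10.0 ** (-self.rolloff_db_per_mm * np.asarray(depth_mm) / 20.0)


@dataclass
class SpectralFrame:
    """Raw fringe data of one B-scan: (n_k, n_x) real array plus metadata."""

    fringes: np.ndarray
    source: SourceSpec
    acq: AcqParams
    noise: NoiseModel
    frame_index: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fringes.ndim != 2 or self.fringes.shape[0] != self.source.n_k:
            raise ValueError(
                f"fringes must be (n_k, n_x) = ({self.source.n_k}, *), got {self.fringes.shape}"
            )
        if not np.all(np.isfinite(self.fringes)):
            raise ValueError("fringes contain non-finite values")

    @property
    def n_x(self) -> int:
        return self.fringes.shape[1]

    def metadata_json(self) -> str:
        return json.dumps(
            {
                "source": asdict(self.source),
                "acq": asdict(self.acq),
                "noise": asdict(self.noise),
                "frame_index": self.frame_index,
                "seed": self.seed,
            }
        )


def _dispersion_phase(source: SourceSpec, a2: float) -> np.ndarray:
    """Second-order spectral phase a2*(k-k0)^2 with k in rad/um."""
    k_um = source.k_grid_per_mm() * 1e-3
    k0_um = source.k0_per_mm * 1e-3
    return a2 * (k_um - k0_um) ** 2


def unit_peak_amplitude(source: SourceSpec) -> float:
    """Reconstructed (rect-window) peak magnitude of a unit reflector at depth 0."""
    return 0.5 * float(np.sum(source.envelope()))


def _noise_sigma(source: SourceSpec, noise: NoiseModel) -> float:
    # white real noise of sd s gives FFT bins with rms magnitude s*sqrt(n_k)
    target_rms = unit_peak_amplitude(source) * 10.0 ** (noise.noise_floor_db / 20.0)
    return target_rms / np.sqrt(source.n_k)


def _fringes_from_reflectors(
    depths_mm: np.ndarray,
    complex_amps: np.ndarray,
    source: SourceSpec,
    noise: NoiseModel,
) -> np.ndarray:
    """Core forward model.

    ``depths_mm``: (n_r,) reflector depths; ``complex_amps``: (n_r, n_alines)
    amplitude * exp(i * phase) per reflector and A-line.  Returns real fringes
    of shape (n_k, n_alines), noise-free and before DC removal.
    """
    k = source.k_grid_per_mm()[:, None]  # (n_k, 1)
    z = np.asarray(depths_mm, dtype=float)[None, :]  # (1, n_r)
    if np.any(z < 0):
        raise ValueError("reflector depths must be >= 0")
    if np.any(z >= source.depth_range_mm):
        raise ValueError(
            f"reflector depths must lie in [0, {source.depth_range_mm}) mm"
        )
    carrier = np.exp(2j * k * z)  # (n_k, n_r)
    amps = complex_amps * noise.rolloff_amplitude(z.T)  # (n_r, n_alines)
    analytic = carrier @ amps  # (n_k, n_alines)
    env_disp = source.envelope() * np.exp(1j * _dispersion_phase(source, noise.dispersion_a2))
    return np.real(env_disp[:, None] * analytic)


def synth_aline(
    reflectors: list[tuple[float, float, float]],
    source: SourceSpec,
    noise: NoiseModel,
    seed: int | None = None,
) -> np.ndarray:
    """Synthesize one spectral fringe from ``(depth_mm, amplitude, phase_rad)`` triples.

    The returned fringe has its mean removed (balanced-detection emulation).
    """
    if reflectors:
        depths = np.array([r[0] for r in reflectors], dtype=float)
        amps = np.array([r[1] * np.exp(1j * r[2]) for r in reflectors])[:, None]
        fringe = _fringes_from_reflectors(depths, amps, source, noise)[:, 0]
    else:
        fringe = np.zeros(source.n_k)
    if seed is not None and noise.noise_floor_db > -200:
        rng = np.random.default_rng(seed)
        fringe = fringe + rng.normal(0.0, _noise_sigma(source, noise), source.n_k)
    return fringe - fringe.mean()


def synth_bscan(
    scene,
    frame_index: int,
    source: SourceSpec,
    acq: AcqParams,
    noise: NoiseModel,
    seed: int = 0,
) -> SpectralFrame:
    """Forward-simulate the raw fringes of one B-scan frame of a TissueScene.

    Voxel (x, z) contributes a reflector at the voxel-center depth with
    amplitude ``reflectivity[frame, x, z]``.  Its phase at A-line x is the
    cumulative Doppler advance ``(4 pi dt / lambda0) * sum_{x' <= x} v(x', z)``
    plus the common jitter random walk, so the step from A-line x to x+1
    carries the local axial velocity.
    """
    from .phantom import TissueScene  # local import to avoid cycle at import time

    if not isinstance(scene, TissueScene):
        raise TypeError("scene must be a TissueScene")
    g = scene.geometry
    if not (0 <= frame_index < g.n_frames):
        raise ValueError(f"frame_index {frame_index} out of range [0, {g.n_frames})")
    if g.n_z != source.n_z:
        raise ValueError(
            f"scene n_z = {g.n_z} does not match source n_k/2 = {source.n_z}"
        )
    if not np.isclose(g.depth_range_mm, source.depth_range_mm):
        raise ValueError(
            f"scene depth range {g.depth_range_mm} mm does not match source "
            f"{source.depth_range_mm} mm"
        )

    refl = scene.reflectivity[frame_index]  # (n_x, n_z)
    vel = scene.axial_velocity[frame_index]
    lam_mm = source.lambda0_um * 1e-3
    dphi_per_aline = 4.0 * np.pi * vel * acq.delta_t_s / lam_mm  # (n_x, n_z)

    rng = np.random.default_rng(seed)
    jitter = np.zeros(g.n_x)
    if noise.phase_jitter_sd_rad > 0:
        jitter = np.cumsum(rng.normal(0.0, noise.phase_jitter_sd_rad, g.n_x))

    # phase of column x = sum of Doppler steps of columns before x (exclusive
    # cumsum), so the measured difference between x and x+1 carries v(x, z)
    phase = np.cumsum(dphi_per_aline, axis=0) - dphi_per_aline + jitter[:, None]
    if scene.scatter_phase is not None:
        phase = phase + scene.scatter_phase[frame_index]

    # only voxels that reflect anywhere need simulating
    active = np.flatnonzero(refl.max(axis=0) > 0)
    depths = scene.geometry.z_centers_mm()[active]
    camps = (refl[:, active] * np.exp(1j * phase[:, active])).T  # (n_r, n_x)
    fringes = _fringes_from_reflectors(depths, camps, source, noise)
    if noise.noise_floor_db > -200:
        fringes = fringes + rng.normal(0.0, _noise_sigma(source, noise), fringes.shape)
    fringes = fringes - fringes.mean(axis=0, keepdims=True)
    return SpectralFrame(fringes, source, acq, noise, frame_index=frame_index, seed=seed)


def synth_mirror_series(
    depth_mm: float,
    n_alines: int,
    source: SourceSpec,
    acq: AcqParams,
    noise: NoiseModel,
    seed: int = 0,
    amplitude: float = 1.0,
    velocity_mm_s: float = 0.0,
) -> SpectralFrame:
    """Repeated A-lines of a single (optionally moving) mirror surface.

    The workhorse of the metrology suite: phase-stability, roll-off and PSF
    measurements all image a mirror.
    """
    lam_mm = source.lambda0_um * 1e-3
    step = 4.0 * np.pi * velocity_mm_s * acq.delta_t_s / lam_mm
    rng = np.random.default_rng(seed)
    phase = step * np.arange(n_alines, dtype=float)
    if noise.phase_jitter_sd_rad > 0:
        phase = phase + np.cumsum(rng.normal(0.0, noise.phase_jitter_sd_rad, n_alines))
    camps = (amplitude * np.exp(1j * phase))[None, :]
    fringes = _fringes_from_reflectors(np.array([depth_mm]), camps, source, noise)
    if noise.noise_floor_db > -200:
        fringes = fringes + rng.normal(0.0, _noise_sigma(source, noise), fringes.shape)
    fringes = fringes - fringes.mean(axis=0, keepdims=True)
    return SpectralFrame(fringes, source, acq, noise, frame_index=0, seed=seed)
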