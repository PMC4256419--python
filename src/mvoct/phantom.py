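"""Synthetic vascular scenes for the imaging pipeline.

A :class:`TissueScene` is a voxelized stand-in for the exposed surgical site:
a 3-D reflectivity field, an axial (beam-parallel) velocity field with
parabolic flow inside vessel lumens, and ground-truth boolean masks for the
inner lumen, the flowing blood, and any static thrombus.  Vessels run along
the slow (Y) scan axis so every transverse B-scan cuts a circular lumen
cross-section, the situation in which cross-sectional patency analysis is
performed.

Axis order of all volume arrays is ``(frame, x, z)``: slow axis first, then
fast lateral axis, then depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScanGeometry",
    "VesselSpec",
    "TissueScene",
    "build_scene",
    "parabolic_velocity",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Voxel grid of the scanned volume.

    Defaults match a 1.5 x 1.5 mm lateral field of view over a 5 mm (in air)
    imaging depth sampled as 252 frames x 1000 A-lines x 512 axial pixels.
    """

    fov_x_mm: float = 1.5
    fov_y_mm: float = 1.5
    depth_range_mm: float = 5.0
    n_x: int = 1000
    n_z: int = 512
    n_frames: int = 252

    def __post_init__(self) -> None:
        for name in ("fov_x_mm", "fov_y_mm", "depth_range_mm"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be finite and > 0")
        for name in ("n_x", "n_z", "n_frames"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def dx_mm(self) -> float:
        """Lateral pixel pitch (mm)."""
        return self.fov_x_mm / self.n_x

    @property
    def dy_mm(self) -> float:
        return self.fov_y_mm / self.n_frames

    @property
    def dz_mm(self) -> float:
        """Axial pixel pitch (mm, in air)."""
        return self.depth_range_mm / self.n_z

    def x_centers_mm(self) -> np.ndarray:
        return (np.arange(self.n_x) + 0.5) * self.dx_mm

    def z_centers_mm(self) -> np.ndarray:
        # aligned to the reconstruction depth bins (zero-delay = pixel 0), so
        # a voxel maps to exactly one FFT bin when no spectral envelope is set
        return np.arange(self.n_z) * self.dz_mm


@dataclass(frozen=True)
class VesselSpec:
    """One straight vessel running along the slow (Y) axis.

    ``radius_mm`` is the *inner lumen* radius; the wall is an annulus of
    ``wall_thickness_mm`` outside it.  ``peak_velocity_mm_s`` is the signed
    centerline axial velocity (positive = toward the probe); magnitudes above
    the phase-wrap limit are allowed so aliasing can be exercised.
    ``thrombus_fraction`` is the fraction of the lumen cross-section occupied
    by a static clot, modelled as an angular sector anchored at
    ``thrombus_anchor_rad``.
    """

    center_x_mm: float
    center_z_mm: float
    radius_mm: float
    peak_velocity_mm_s: float = 0.0
    wall_thickness_mm: float = 0.0
    thrombus_fraction: float = 0.0
    thrombus_anchor_rad: float = 0.0
    wall_reflectivity: float = 0.5
    blood_reflectivity: float = 0.2
    thrombus_reflectivity: float = 0.6

    def __post_init__(self) -> None:
        if self.wall_thickness_mm < 0:
            raise ValueError("wall_thickness_mm must be >= 0")
        if self.radius_mm <= self.wall_thickness_mm:
            raise ValueError("radius_mm must exceed wall_thickness_mm")
        if not 0.0 <= self.thrombus_fraction < 1.0:
            raise ValueError("thrombus_fraction must lie in [0, 1)")

    @property
    def outer_radius_mm(self) -> float:
        return self.radius_mm + self.wall_thickness_mm


@dataclass
class TissueScene:
    """Reflectivity + axial velocity + ground-truth masks on a ScanGeometry grid."""

    geometry: ScanGeometry
    reflectivity: np.ndarray  # (n_frames, n_x, n_z) float
    axial_velocity: np.ndarray  # mm/s, zero outside flow_mask
    lumen_mask: np.ndarray  # bool
    flow_mask: np.ndarray
    thrombus_mask: np.ndarray
    scatter_phase: np.ndarray | None = None  # rad, only when speckle enabled
    seed: int | None = None
    vessels: tuple[VesselSpec, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        g = self.geometry
        shape = (g.n_frames, g.n_x, g.n_z)
        for name in ("reflectivity", "axial_velocity", "lumen_mask", "flow_mask", "thrombus_mask"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.flow_mask & ~self.lumen_mask):
            raise ValueError("flow_mask must be a subset of lumen_mask")
        if np.any(self.thrombus_mask & ~self.lumen_mask):
            raise ValueError("thrombus_mask must be a subset of lumen_mask")
        if np.any(self.flow_mask & self.thrombus_mask):
            raise ValueError("flow_mask and thrombus_mask must be disjoint")
        if np.any(self.axial_velocity[~self.flow_mask] != 0.0):
            raise ValueError("axial_velocity must vanish outside flow_mask")

    def label_volume(self) -> np.ndarray:
        """uint8 labels: 0 background, 1 lumen (static, non-thrombus), 2 flow, 3 thrombus."""
        labels = np.zeros(self.lumen_mask.shape, dtype=np.uint8)
        labels[self.lumen_mask] = 1
        labels[self.flow_mask] = 2
        labels[self.thrombus_mask] = 3
        return labels


def parabolic_velocity(
    r_mm: float | np.ndarray, radius_mm: float, peak_velocity_mm_s: float
) -> float | np.ndarray:
    """Poiseuille profile: ``v(r) = v_peak * (1 - (r/R)^2)`` for ``r <= R``, else 0.

    The cross-sectional mean over the full disk is ``v_peak / 2``.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    r = np.asarray(r_mm, dtype=float)
    if np.any(r < 0):
        raise ValueError("r_mm must be >= 0")
    v = peak_velocity_mm_s * (1.0 - (r / radius_mm) ** 2)
    v = np.where(r <= radius_mm, v, 0.0)
    return float(v) if np.isscalar(r_mm) else v


def _sector_mask(dx: np.ndarray, dz: np.ndarray, fraction: float, anchor: float) -> np.ndarray:
    """Angular sector of width ``2*pi*fraction`` centered on ``anchor``."""
    if fraction <= 0.0:
        return np.zeros(dx.shape, dtype=bool)
    ang = np.arctan2(dz, dx)
    delta = np.angle(np.exp(1j * (ang - anchor)))  # wrapped to (-pi, pi]
    return np.abs(delta) <= np.pi * fraction


def build_scene(
    geometry: ScanGeometry,
    vessels: list[VesselSpec] | tuple[VesselSpec, ...] = (),
    background_reflectivity: float = 0.05,
    seed: int = 0,
    *,
    cos_doppler_angle: float = 1.0,
    speckle: bool = False,
) -> TissueScene:
    """Rasterize vessels into a :class:`TissueScene`.

    Every vessel cross-section (lumen plus wall) must fit inside the lateral
    and axial extents.  The result is deterministic for a given ``seed``;
    randomness is used only for the optional speckle texture.

    ``cos_doppler_angle`` scales flow velocities into the beam-parallel
    component; the default 1 corresponds to flow parallel to the beam.
    """
    g = geometry
    for i, v in enumerate(vessels):
        lo_x = v.center_x_mm - v.outer_radius_mm
        hi_x = v.center_x_mm + v.outer_radius_mm
        lo_z = v.center_z_mm - v.outer_radius_mm
        hi_z = v.center_z_mm + v.outer_radius_mm
        if lo_x < 0 or hi_x > g.fov_x_mm or lo_z < 0 or hi_z > g.depth_range_mm:
            raise ValueError(
                f"vessel {i} (center ({v.center_x_mm}, {v.center_z_mm}) mm, outer radius "
                f"{v.outer_radius_mm} mm) extends outside the grid "
                f"[0, {g.fov_x_mm}] x [0, {g.depth_range_mm}] mm"
            )

    x = g.x_centers_mm()[:, None]  # (n_x, 1)
    z = g.z_centers_mm()[None, :]  # (1, n_z)

    refl2d = np.full((g.n_x, g.n_z), float(background_reflectivity))
    vel2d = np.zeros((g.n_x, g.n_z))
    lumen2d = np.zeros((g.n_x, g.n_z), dtype=bool)
    flow2d = np.zeros_like(lumen2d)
    thromb2d = np.zeros_like(lumen2d)

    for v in vessels:
        dx = x - v.center_x_mm
        dz = z - v.center_z_mm
        dist = np.hypot(dx, dz)
        lumen = dist <= v.radius_mm
        wall = (dist > v.radius_mm) & (dist <= v.outer_radius_mm)
        thromb = lumen & _sector_mask(dx, dz, v.thrombus_fraction, v.thrombus_anchor_rad)
        flow = lumen & ~thromb

        refl2d[wall] = v.wall_reflectivity
        refl2d[thromb] = v.thrombus_reflectivity
        refl2d[flow] = v.blood_reflectivity
        prof = parabolic_velocity(dist, v.radius_mm, v.peak_velocity_mm_s)
        vel2d[flow] = cos_doppler_angle * prof[flow]
        vel2d[thromb] = 0.0
        lumen2d |= lumen
        flow2d |= flow
        thromb2d |= thromb

    # vessels are y-invariant: broadcast the cross-section to all frames
    tile = lambda a: np.broadcast_to(a, (g.n_frames,) + a.shape).copy()
    reflectivity = tile(refl2d)
    scatter_phase = None
    if speckle:
        rng = np.random.default_rng(seed)
        amp = np.abs(
            rng.standard_normal(reflectivity.shape) + 1j * rng.standard_normal(reflectivity.shape)
        ) / np.sqrt(np.pi / 2)  # unit-mean Rayleigh texture
        reflectivity = reflectivity * amp
        scatter_phase = rng.uniform(-np.pi, np.pi, reflectivity.shape)

    scene = TissueScene(
        geometry=g,
        reflectivity=reflectivity,
        axial_velocity=tile(vel2d),
        lumen_mask=tile(lumen2d),
        flow_mask=tile(flow2d),
        thrombus_mask=tile(thromb2d),
        scatter_phase=scatter_phase,
        seed=seed,
        vessels=tuple(vessels),
    )
    scene.validate()
    return scene
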