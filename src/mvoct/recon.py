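"""A-line reconstruction: spectral fringes -> complex depth profiles.

Per A-line the residual mean is subtracted, an apodization window and a
numerical second-order dispersion-compensation phase ``exp(-i a2 (k-k0)^2)``
are applied, and the FFT is taken; the first half of the bins (positive
depths) is kept.  Bin ``m`` of the result sits at depth ``m * dz`` with
``dz = depth_range / (n_k/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .interferogram import SpectralFrame, _dispersion_phase

__all__ = ["ComplexBScan", "StructuralImage", "reconstruct", "to_db", "DB_EPS_REL"]

#: epsilon used in to_db, as a fraction of the full-scale magnitude
DB_EPS_REL = 1e-12


@dataclass
class ComplexBScan:
    """Complex reconstructed B-scan, shape (n_x, n_z)."""

    values: np.ndarray
    dz_mm: float
    source: "object" = None
    acq: "object" = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_x, n_z)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")

    @property
    def n_x(self) -> int:
        return self.values.shape[0]

    @property
    def n_z(self) -> int:
        return self.values.shape[1]


@dataclass
class StructuralImage:
    """Log-intensity image (dB), shape (n_x, n_z)."""

    values_db: np.ndarray
    dz_mm: float
    display_min_db: float = -60.0
    display_max_db: float = 0.0


def reconstruct(
    frame: SpectralFrame,
    a2_comp: float = 0.0,
    window: str = "hann",
    pad_factor: int = 1,
) -> ComplexBScan:
    """Reconstruct a complex B-scan from a :class:`SpectralFrame`.

    Parameters
    ----------
    a2_comp:
        Second-order dispersion compensation coefficient (rad per (rad/um)^2);
        setting it equal to the injected ``dispersion_a2`` cancels the
        dispersion phase exactly.
    window:
        Apodization: ``"hann"`` (default, sidelobe suppression), ``"rect"``
        (resolution probing) or any scipy window name.
    pad_factor:
        Zero-padding factor for sub-pixel sampling of the PSF; the output has
        ``pad_factor * n_k/2`` axial pixels of pitch ``dz / pad_factor``.
    """
    fr = frame.fringes
    if np.any(~np.isfinite(fr)):
        bad = np.argwhere(~np.isfinite(fr))
        k, x = bad[0]
        raise ValueError(
            f"fringes contain {len(bad)} non-finite sample(s); first at k={k}, A-line={x}"
        )
    n_k = frame.source.n_k
    if n_k % 2:
        raise ValueError("fringe length must be even")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")

    data = fr - fr.mean(axis=0, keepdims=True)
    win = np.ones(n_k) if window in ("rect", "boxcar", None) else get_window(window, n_k, fftbins=False)
    comp = np.exp(-1j * _dispersion_phase(frame.source, a2_comp))
    spectrum = data * (win * comp)[:, None]
    alines = np.fft.fft(spectrum, n=n_k * pad_factor, axis=0)
    half = (n_k * pad_factor) // 2
    values = alines[:half, :].T  # (n_x, n_z_padded)
    return ComplexBScan(
        values=values,
        dz_mm=frame.source.dz_mm / pad_factor,
        source=frame.source,
        acq=frame.acq,
    )


def to_db(b: ComplexBScan) -> StructuralImage:
    """Log-intensity image ``20 log10(|A| + eps)`` with eps = 1e-12 of full scale."""
    mag = np.abs(b.values)
    eps = DB_EPS_REL * (mag.max() if mag.max() > 0 else 1.0)
    return StructuralImage(values_db=20.0 * np.log10(mag + eps), dz_mm=b.dz_mm)
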