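"""Anastomosis quantification from cross-sectional segmentation masks.

For every frame the inner-lumen and flowing-blood areas are measured by pixel
counting, and three clinically reported percentages are derived:

* patency   = 100 * flow_area / lumen_area   (fraction of lumen with flow)
* narrowing = 100 * (reference_area - lumen_area) / reference_area, against a
  naive (unoperated) reference frame; negative if the lumen dilated
* thrombosis = 100 - patency                 (cross-sectional clot fraction)

Patency and thrombosis sum to 100 exactly before rounding.  Displayed values
are rounded half-up to integers; one decimal is kept internally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "LumenMeasurement",
    "LumenReport",
    "area_from_mask",
    "patency_pct",
    "narrowing_pct",
    "thrombosis_pct",
    "analyze_volume",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of the printed percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LumenMeasurement:
    """Per-frame areas (mm^2)."""

    frame_id: int
    lumen_area_mm2: float
    flow_area_mm2: float
    reference_area_mm2: float
    pixel_size_mm: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.flow_area_mm2 <= self.lumen_area_mm2 + 1e-12:
            raise ValueError("flow area must satisfy 0 <= flow <= lumen")
        if self.reference_area_mm2 <= 0:
            raise ValueError("reference_area_mm2 must be > 0")


@dataclass
class LumenReport:
    """Per-frame patency/narrowing/thrombosis percentages."""

    measurements: list[LumenMeasurement]
    table: pd.DataFrame
    reference_frame_id: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "reference_frame_id": self.reference_frame_id,
                    "frames": self.table.to_dict(orient="records"),
                },
                fh,
                indent=2,
            )


def area_from_mask(mask: np.ndarray, pixel_size_mm: tuple[float, float]) -> float:
    """Area (mm^2) of a boolean mask: true-pixel count times pixel area."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    count = int(np.count_nonzero(m))
    if count == 0:
        warnings.warn("empty mask: area is 0")
    return count * pixel_size_mm[0] * pixel_size_mm[1]


def patency_pct(flow_area: float, lumen_area: float) -> float:
    """Lumen patency percentage ``100 * flow / lumen``."""
    if lumen_area <= 0:
        raise ValueError("lumen_area must be > 0")
    return 100.0 * flow_area / lumen_area


def narrowing_pct(area: float, reference_area: float) -> float:
    """Lumen narrowing percentage relative to the reference cross-section.

    May be negative when the lumen dilated beyond the reference.
    """
    if reference_area <= 0:
        raise ValueError("reference_area must be > 0")
    return 100.0 * (reference_area - area) / reference_area


def thrombosis_pct(patency: float) -> float:
    """Thrombosis percentage: complement of patency."""
    if not 0.0 <= patency <= 100.0:
        raise ValueError("patency must lie in [0, 100]")
    return 100.0 - patency


def analyze_volume(
    lumen_masks: np.ndarray,
    flow_masks: np.ndarray | None,
    reference_frame_id: int,
    pixel_size_mm: tuple[float, float],
    *,
    structural_stack: np.ndarray | None = None,
    doppler_stack: np.ndarray | None = None,
    v_min_mm_s: float | None = None,
    frame_ids: list[int] | None = None,
) -> LumenReport:
    """Quantify patency, narrowing and thrombosis across a stack of frames.

    ``lumen_masks`` is a (n_frames, nx, nz) boolean stack of manually (or
    synthetically) segmented inner lumens.  ``flow_masks`` may be given
    directly (the default workflow: flow segmented on the Doppler images); if
    ``None`` it is auto-derived as ``|v| >= v_min`` within the lumen from
    ``doppler_stack``.
    """
    lumen_masks = np.asarray(lumen_masks, dtype=bool)
    if lumen_masks.ndim != 3:
        raise ValueError("lumen_masks must be 3-D (frame, x, z)")
    n_frames = lumen_masks.shape[0]
    ids = list(frame_ids) if frame_ids is not None else list(range(n_frames))
    if len(ids) != n_frames:
        raise ValueError("frame_ids length must match the stack")
    if reference_frame_id not in ids:
        raise ValueError(f"reference frame {reference_frame_id} not present in {ids}")

    if flow_masks is None:
        if doppler_stack is None or v_min_mm_s is None:
            raise ValueError(
                "flow_masks not given: need doppler_stack and v_min_mm_s to derive them"
            )
        doppler_stack = np.asarray(doppler_stack)
        if doppler_stack.shape != lumen_masks.shape:
            raise ValueError(
                f"doppler_stack shape {doppler_stack.shape} does not match "
                f"lumen_masks {lumen_masks.shape}"
            )
        flow_masks = (np.abs(doppler_stack) >= v_min_mm_s) & lumen_masks
    flow_masks = np.asarray(flow_masks, dtype=bool)
    for name, stack in (("flow_masks", flow_masks), ("structural_stack", structural_stack)):
        if stack is not None and stack.shape[0] != n_frames:
            raise ValueError(f"{name} has {stack.shape[0]} frames, expected {n_frames}")
    for f, (lm, fm) in enumerate(zip(lumen_masks, flow_masks)):
        if fm.shape != lm.shape:
            raise ValueError(f"mask shape mismatch at frame {ids[f]}")

    ref_idx = ids.index(reference_frame_id)
    ref_area = area_from_mask(lumen_masks[ref_idx], pixel_size_mm)
    if ref_area <= 0:
        raise ValueError(f"reference frame {reference_frame_id} has empty lumen")

    measurements: list[LumenMeasurement] = []
    rows = []
    for f in range(n_frames):
        lumen_area = area_from_mask(lumen_masks[f], pixel_size_mm)
        flow_area = area_from_mask(flow_masks[f] & lumen_masks[f], pixel_size_mm)
        m = LumenMeasurement(ids[f], lumen_area, flow_area, ref_area, tuple(pixel_size_mm))
        measurements.append(m)
        patency = patency_pct(flow_area, lumen_area) if lumen_area > 0 else 0.0
        rows.append(
            {
                "frame_id": ids[f],
                "lumen_area_mm2": lumen_area,
                "flow_area_mm2": flow_area,
                "patency_pct": round_half_up(patency, 1),
                "narrowing_pct": round_half_up(narrowing_pct(lumen_area, ref_area), 1),
                "thrombosis_pct": round_half_up(thrombosis_pct(patency), 1),
                "patency_display": int(round_half_up(patency)),
                "narrowing_display": int(round_half_up(narrowing_pct(lumen_area, ref_area))),
                "thrombosis_display": int(round_half_up(thrombosis_pct(patency))),
            }
        )
    return LumenReport(
        measurements=measurements,
        table=pd.DataFrame(rows),
        reference_frame_id=reference_frame_id,
    )
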