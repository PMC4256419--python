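"""MEMS raster-scan drive waveforms and frame-trigger timing.

One slow-axis section of the fast-axis waveform is a quasi-sinusoidal cycle:
a half-cosine lead-in riding on a linear term takes the mirror from the rest
position to the ramp start with slope continuity, a linear ramp covers the
acquisition region, and the mirrored half-cosine lead-out returns the mirror
to rest.  The slow axis steps once per section and is held constant within
it.  A digital frame trigger rises at the first acquisition sample of each
imaging section; the digitizer then acquires one A-line per sample over the
linear region.

At the defaults (50 kHz clock, 1400 points/section, 200-point leads, 1000
acquisition points, 252 sections) the frame rate is 50 000/1400 = 35.7 Hz
(quoted as 36 fps) and a C-scan volume takes 252 * 1400 / 50 000 = 7.06 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScanPlan", "ScanWaveforms", "build_waveforms", "validate_linearity"]


@dataclass(frozen=True)
class ScanPlan:
    """Raster-scan timing plan.

    In C-scan mode the first and last sections park/return the mirror on the
    slow axis and carry no trigger, so a plan with ``n_sections`` sections
    yields ``n_sections - 2`` imaging frames; in B-scan mode the slow axis is
    held at zero and every section images.
    """

    clock_hz: float = 50_000.0
    n_sections: int = 252
    points_per_section: int = 1400
    lead_points: int = 200
    acq_points: int = 1000
    x_amplitude: float = 1.0
    y_amplitude: float = 1.0
    mode: str = "C-scan"

    def __post_init__(self) -> None:
        if self.clock_hz <= 0:
            raise ValueError("clock_hz must be > 0")
        if self.mode not in ("B-scan", "C-scan"):
            raise ValueError("mode must be 'B-scan' or 'C-scan'")
        if 2 * self.lead_points + self.acq_points != self.points_per_section:
            raise ValueError(
                f"2*lead_points + acq_points = {2 * self.lead_points + self.acq_points} "
                f"must equal points_per_section = {self.points_per_section}"
            )
        if self.mode == "C-scan" and self.n_sections < 3:
            raise ValueError("C-scan mode needs n_sections >= 3 (park/return sections)")
        if self.n_sections < 1 or self.acq_points < 2:
            raise ValueError("n_sections >= 1 and acq_points >= 2 required")

    @property
    def frame_rate_hz(self) -> float:
        return self.clock_hz / self.points_per_section

    @property
    def n_imaging_sections(self) -> int:
        return self.n_sections - 2 if self.mode == "C-scan" else self.n_sections


@dataclass
class ScanWaveforms:
    """Drive samples (normalized units) plus frame-trigger sample indices."""

    x_samples: np.ndarray
    y_samples: np.ndarray
    trigger_indices: np.ndarray
    frame_rate_hz: float
    volume_time_s: float
    plan: ScanPlan


def _fast_axis_section(plan: ScanPlan) -> np.ndarray:
    """One section of the fast-axis waveform (starts and ends at rest = 0)."""
    amp = plan.x_amplitude
    lead, acq = plan.lead_points, plan.acq_points
    slope = 2.0 * amp / acq  # per sample, kept across the blends for continuity
    t_ramp = np.arange(acq)
    ramp = -amp + slope * t_ramp
    if lead == 0:
        return ramp
    # lead-in f(t) = s*t - (A + s*L)*(1 - cos(pi t / L))/2 : f(0)=0, f(L)=-A,
    # f'(0)=f'(L)=s, so every junction is slope-continuous with the ramp and
    # with the preceding section's lead-out.
    t = np.arange(lead, dtype=float)
    lead_in = slope * t - (amp + slope * lead) * (1.0 - np.cos(np.pi * t / lead)) / 2.0
    t_out = np.arange(1, lead + 1, dtype=float)
    tl = lead - t_out
    lead_out = -(slope * tl - (amp + slope * lead) * (1.0 - np.cos(np.pi * tl / lead)) / 2.0)
    return np.concatenate([lead_in, ramp, lead_out])


def build_waveforms(plan: ScanPlan) -> ScanWaveforms:
    """Generate fast/slow drive waveforms and frame triggers for a plan."""
    section = _fast_axis_section(plan)
    x = np.tile(section, plan.n_sections)

    y = np.zeros(plan.n_sections * plan.points_per_section)
    if plan.mode == "C-scan":
        n_img = plan.n_imaging_sections
        levels = (
            np.linspace(-plan.y_amplitude, plan.y_amplitude, n_img)
            if n_img > 1
            else np.array([0.0])
        )
        pps = plan.points_per_section
        # park section ramps 0 -> first level; return section ramps last -> 0
        tt = np.arange(pps) / pps
        y[:pps] = levels[0] * (1.0 - np.cos(np.pi * tt)) / 2.0
        for j, lev in enumerate(levels):
            y[(j + 1) * pps : (j + 2) * pps] = lev
        y[-pps:] = levels[-1] * (1.0 + np.cos(np.pi * tt)) / 2.0
        first_img = 1
    else:
        first_img = 0

    triggers = np.array(
        [
            s * plan.points_per_section + plan.lead_points
            for s in range(first_img, first_img + plan.n_imaging_sections)
        ],
        dtype=int,
    )
    return ScanWaveforms(
        x_samples=x,
        y_samples=y,
        trigger_indices=triggers,
        frame_rate_hz=plan.frame_rate_hz,
        volume_time_s=plan.n_sections * plan.points_per_section / plan.clock_hz,
        plan=plan,
    )


def validate_linearity(x_samples: np.ndarray, plan: ScanPlan) -> float:
    """Max |x - ideal ramp| over all acquisition regions, normalized to amplitude.

    Zero for the default generator; positive for e.g. low-pass-filtered
    waveforms whose ramp ends get bent.
    """
    amp = plan.x_amplitude
    if amp == 0:
        return 0.0
    slope = 2.0 * amp / plan.acq_points
    ideal = -amp + slope * np.arange(plan.acq_points)
    worst = 0.0
    for s in range(plan.n_sections):
        start = s * plan.points_per_section + plan.lead_points
        seg = x_samples[start : start + plan.acq_points]
        if seg.size < plan.acq_points:
            break
        worst = max(worst, float(np.max(np.abs(seg - ideal))))
    return worst / amp
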