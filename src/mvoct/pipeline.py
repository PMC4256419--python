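"""Stage orchestration: scene -> fringes -> recon -> doppler -> quantify.

Each stage reads its predecessors' on-disk artifacts from the run directory,
so stages can be re-run individually; a manifest JSON records the package
version, configuration, seed and artifact paths, from which the whole run is
reproducible.  Runs are idempotent and bit-reproducible for a given config.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .doppler import doppler_range, phase_difference, velocity_map
from .fileio import load_fringes, load_scene, save_fringes, save_image_tiff, save_scene
from .interferogram import synth_bscan, unit_peak_amplitude
from .lumen import analyze_volume
from .metrology import characterize
from .phantom import build_scene
from .recon import reconstruct, to_db
from .scanpattern import build_waveforms

__all__ = ["PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("mvoct.pipeline")

STAGES = ("scene", "fringes", "recon", "doppler", "characterize", "quantify")

_REQUIRES = {
    "scene": (),
    "fringes": ("scene",),
    "recon": ("fringes",),
    "doppler": ("recon",),
    "characterize": (),
    "quantify": ("scene", "doppler"),
}

_ARTIFACTS = {
    "scene": "scene/scene.json",
    "fringes": "fringes.h5",
    "recon": "structural.tiff",
    "doppler": "velocity.tiff",
    "characterize": "characterization.json",
    "quantify": "lumen_report.csv",
}


class PipelineError(RuntimeError):
    pass


def _stage_marker(stage: str, status: str) -> None:
    log.info("[stage:%s] %s", stage, status)


def run_pipeline(config: RunConfig, stages: list[str] | tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order; returns the manifest dict.

    A stage whose upstream artifact is neither scheduled earlier in ``stages``
    nor already present in the run directory raises :class:`PipelineError`
    naming the missing stage.
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage '{s}'; valid stages: {STAGES}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    done: set[str] = set()
    for s in stages:
        for req in _REQUIRES[s]:
            if req in done or req in stages[: stages.index(s)]:
                continue
            if (out / _ARTIFACTS[req]).exists():
                continue
            raise PipelineError(
                f"stage '{s}' requires output of stage '{req}', which is neither "
                f"scheduled nor present in {out}"
            )

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    scene = None
    frames = None
    bscans = None
    dop_maps = None

    for stage in stages:
        _stage_marker(stage, "start")
        if stage == "scene":
            scene = build_scene(
                config.geometry,
                list(config.vessels),
                config.background_reflectivity,
                seed=config.seed,
            )
            paths = save_scene(scene, out / "scene")
            manifest["stages"]["scene"] = paths
        elif stage == "fringes":
            if scene is None:
                scene = load_scene(out / "scene")
            frames = [
                synth_bscan(scene, i, config.source, config.acq, config.noise,
                            seed=config.seed + 1 + i)
                for i in range(scene.geometry.n_frames)
            ]
            save_fringes(frames, out / "fringes.h5")
            manifest["stages"]["fringes"] = {"fringes": str(out / "fringes.h5")}
        elif stage == "recon":
            if frames is None:
                frames = load_fringes(out / "fringes.h5")
            bscans = [reconstruct(f) for f in frames]
            struct = np.stack([to_db(b).values_db for b in bscans])
            save_image_tiff(struct, out / "structural.tiff")
            np.save(out / "complex_bscans.npy", np.stack([b.values for b in bscans]))
            manifest["stages"]["recon"] = {
                "structural": str(out / "structural.tiff"),
                "complex": str(out / "complex_bscans.npy"),
            }
        elif stage == "doppler":
            if bscans is None:
                frames = frames or load_fringes(out / "fringes.h5")
                bscans = [reconstruct(f) for f in frames]
            floor_abs_db = (
                20 * np.log10(unit_peak_amplitude(config.source))
                + config.noise.noise_floor_db
            )
            dop_maps = []
            for b in bscans:
                dphi = phase_difference(b)
                dop_maps.append(
                    velocity_map(
                        dphi, config.source, config.acq,
                        intensity_db=to_db(b).values_db,
                        noise_floor_db=floor_abs_db,
                    )
                )
            vel = np.stack([d.velocity_mm_s for d in dop_maps])
            save_image_tiff(vel, out / "velocity.tiff")
            save_image_tiff(
                np.stack([d.validity_mask for d in dop_maps]).astype(np.float32),
                out / "validity.tiff",
            )
            manifest["stages"]["doppler"] = {
                "velocity": str(out / "velocity.tiff"),
                "validity": str(out / "validity.tiff"),
            }
        elif stage == "characterize":
            report = characterize(
                config.source, config.acq, config.noise, config.optics, seed=config.seed
            )
            with open(out / "characterization.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            manifest["stages"]["characterize"] = {
                "report": str(out / "characterization.json")
            }
        elif stage == "quantify":
            if scene is None:
                scene = load_scene(out / "scene")
            if dop_maps is None:
                import tifffile

                vel = tifffile.imread(out / "velocity.tiff")
            else:
                vel = np.stack([d.velocity_mm_s for d in dop_maps])
            v_min, _ = doppler_range(
                max(config.noise.phase_jitter_sd_rad, 1e-3), config.source, config.acq
            )
            g = scene.geometry
            report = analyze_volume(
                scene.lumen_mask,
                None,
                reference_frame_id=0,
                pixel_size_mm=(g.dx_mm, g.dz_mm),
                doppler_stack=vel,
                v_min_mm_s=v_min,
            )
            report.to_csv(out / "lumen_report.csv")
            report.to_json(out / "lumen_report.json")
            manifest["stages"]["quantify"] = {
                "csv": str(out / "lumen_report.csv"),
                "json": str(out / "lumen_report.json"),
            }
        _stage_marker(stage, "done")

    # scan plan timing always recorded alongside
    wf = build_waveforms(config.plan)
    manifest["scan_timing"] = {
        "frame_rate_hz": wf.frame_rate_hz,
        "volume_time_s": wf.volume_time_s,
        "n_triggers": int(wf.trigger_indices.size),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
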