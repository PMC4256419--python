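"""File-format plumbing: scenes, raw fringes, images, masks, reports.

Scenes are stored as multi-page float32 TIFFs (reflectivity, velocity) plus a
uint8 label TIFF (0 background, 1 lumen, 2 flow, 3 thrombus) and a JSON
geometry sidecar.  Raw fringe frames go into one HDF5 container with the
acquisition metadata attached as a JSON attribute.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .interferogram import AcqParams, NoiseModel, SourceSpec, SpectralFrame
from .phantom import ScanGeometry, TissueScene, VesselSpec

__all__ = [
    "save_scene",
    "load_scene",
    "save_fringes",
    "load_fringes",
    "save_image_tiff",
    "save_mask_png",
    "load_mask",
]


def save_scene(scene: TissueScene, outdir: str | Path) -> dict[str, str]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reflectivity": str(out / "reflectivity.tiff"),
        "velocity": str(out / "velocity.tiff"),
        "labels": str(out / "labels.tiff"),
        "geometry": str(out / "scene.json"),
    }
    tifffile.imwrite(paths["reflectivity"], scene.reflectivity.astype(np.float32))
    tifffile.imwrite(paths["velocity"], scene.axial_velocity.astype(np.float32))
    tifffile.imwrite(paths["labels"], scene.label_volume())
    meta = {
        "geometry": asdict(scene.geometry),
        "vessels": [asdict(v) for v in scene.vessels],
        "seed": scene.seed,
        "has_speckle": scene.scatter_phase is not None,
    }
    with open(paths["geometry"], "w") as fh:
        json.dump(meta, fh, indent=2)
    if scene.scatter_phase is not None:
        paths["scatter_phase"] = str(out / "scatter_phase.tiff")
        tifffile.imwrite(paths["scatter_phase"], scene.scatter_phase.astype(np.float32))
    return paths


def load_scene(indir: str | Path) -> TissueScene:
    ind = Path(indir)
    with open(ind / "scene.json") as fh:
        meta = json.load(fh)
    geometry = ScanGeometry(**meta["geometry"])
    labels = tifffile.imread(ind / "labels.tiff")
    scatter = None
    if meta.get("has_speckle") and (ind / "scatter_phase.tiff").exists():
        scatter = tifffile.imread(ind / "scatter_phase.tiff").astype(float)
    scene = TissueScene(
        geometry=geometry,
        reflectivity=tifffile.imread(ind / "reflectivity.tiff").astype(float),
        axial_velocity=tifffile.imread(ind / "velocity.tiff").astype(float),
        lumen_mask=labels >= 1,
        flow_mask=labels == 2,
        thrombus_mask=labels == 3,
        scatter_phase=scatter,
        seed=meta.get("seed"),
        vessels=tuple(VesselSpec(**v) for v in meta.get("vessels", [])),
    )
    scene.validate()
    return scene


def save_fringes(frames: list[SpectralFrame], path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        data = np.stack([f.fringes for f in frames])
        ds = h5.create_dataset("fringes", data=data)
        ds.attrs["metadata"] = frames[0].metadata_json()
        ds.attrs["frame_indices"] = [f.frame_index for f in frames]


def load_fringes(path: str | Path) -> list[SpectralFrame]:
    with h5py.File(path, "r") as h5:
        ds = h5["fringes"]
        meta = json.loads(ds.attrs["metadata"])
        indices = list(ds.attrs["frame_indices"])
        data = ds[...]
    source = SourceSpec(**meta["source"])
    acq = AcqParams(**meta["acq"])
    noise = NoiseModel(**meta["noise"])
    return [
        SpectralFrame(data[i], source, acq, noise, frame_index=int(indices[i]),
                      seed=meta.get("seed"))
        for i in range(data.shape[0])
    ]


def save_image_tiff(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(str(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a label/mask image (PNG or TIFF); nonzero pixels are foreground."""
    arr = np.asarray(iio.imread(str(path)) if str(path).endswith(".png") else tifffile.imread(str(path)))
    return arr
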