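"""Run configuration: one structured object holding every tunable parameter.

A :class:`RunConfig` aggregates the source/acquisition/noise models, the scan
geometry and plan, the probe optics, the phantom vessel list and the run
seed.  It round-trips losslessly through JSON or YAML; unknown keys anywhere
in the document are rejected so that typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any

import yaml

from .interferogram import AcqParams, NoiseModel, SourceSpec
from .metrology import OpticsSpec
from .phantom import ScanGeometry, VesselSpec
from .scanpattern import ScanPlan

__all__ = ["RunConfig", "strict_from_dict"]


def strict_from_dict(cls, data: dict[str, Any]):
    """Instantiate a dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown key(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        sub = _NESTED.get((cls.__name__, name))
        if sub is not None and value is not None:
            if sub is VesselSpec:  # list of vessels
                kwargs[name] = tuple(strict_from_dict(VesselSpec, v) for v in value)
            else:
                kwargs[name] = strict_from_dict(sub, value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    source: SourceSpec = field(default_factory=SourceSpec)
    acq: AcqParams = field(default_factory=AcqParams)
    noise: NoiseModel = field(default_factory=NoiseModel)
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    plan: ScanPlan = field(default_factory=ScanPlan)
    optics: OpticsSpec = field(default_factory=OpticsSpec)
    vessels: tuple[VesselSpec, ...] = ()
    background_reflectivity: float = 0.05
    seed: int = 0
    outdir: str = "mvoct_out"
    verbosity: int = 1

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["vessels"] = [asdict(v) for v in self.vessels]
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        return strict_from_dict(cls, data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        data = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        return cls.from_dict(data)


_NESTED = {
    ("RunConfig", "source"): SourceSpec,
    ("RunConfig", "acq"): AcqParams,
    ("RunConfig", "noise"): NoiseModel,
    ("RunConfig", "geometry"): ScanGeometry,
    ("RunConfig", "plan"): ScanPlan,
    ("RunConfig", "optics"): OpticsSpec,
    ("RunConfig", "vessels"): VesselSpec,
}
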