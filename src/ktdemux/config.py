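"""Run configuration: geometry, relay, slots, simulation and extraction
parameters bundled into one serializable object."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .extract import ExtractionParams, default_params
from .optics import RelayOptics, SlotSpec, TaperGeometry, default_slots
from .simulate import SimConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable through YAML/JSON."""

    geometry: TaperGeometry = field(default_factory=TaperGeometry)
    relay: RelayOptics = field(default_factory=RelayOptics)
    slots: list[SlotSpec] = field(default_factory=default_slots)
    sim: SimConfig = field(default_factory=SimConfig)
    extraction: ExtractionParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extraction is None:
            self.extraction = default_params(
                self.relay, self.sim.dark_mean, self.sim.dark_sd
            )

    def to_dict(self) -> dict:
        d = {
            "geometry": asdict(self.geometry),
            "relay": asdict(self.relay),
            "slots": [asdict(s) for s in self.slots],
            "sim": {
                k: v for k, v in asdict(self.sim).items() if k != "background"
            },
            "extraction": asdict(self.extraction),
            "seed": self.seed,
        }
        d["relay"]["image_shape"] = list(self.relay.image_shape)
        d["relay"]["center"] = list(self.relay.center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        relay = dict(d.get("relay", {}))
        if "image_shape" in relay:
            relay["image_shape"] = tuple(relay["image_shape"])
        if "center" in relay:
            relay["center"] = tuple(relay["center"])
        extraction = d.get("extraction")
        return cls(
            geometry=TaperGeometry(**d.get("geometry", {})),
            relay=RelayOptics(**relay),
            slots=[SlotSpec(**s) for s in d.get("slots", [])] or default_slots(),
            sim=SimConfig(**d.get("sim", {})),
            extraction=ExtractionParams(**extraction) if extraction else None,
            seed=int(d.get("seed", 0)),
        )

    def hash(self) -> str:
        """Stable content hash of the configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_seed(self, seed: int) -> "RunConfig":
        from dataclasses import replace

        return RunConfig(
            geometry=self.geometry,
            relay=self.relay,
            slots=list(self.slots),
            sim=replace(self.sim, seed=seed),
            extraction=self.extraction,
            seed=seed,
        )


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"malformed config file: {path}")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
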