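"""Run configuration: analysis thresholds, model orders, stages, paths.

Every constant that shapes the analysis lives here and is serialized into
the output provenance, so a report is reproducible from config + seed alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class Thresholds:
    z_display: float = 2.0
    z_extract: float = 3.2
    cluster_k: int = 200
    ratio_min: float = 1.5
    wm_overlap_min: float = 0.5
    wm_prob_gate: float = 0.8
    smoothing_fwhm_mm: float = 5.0
    t2_cap_ms: float = 150.0
    assumed_t1_s: float = 1.25
    clamp_sd: float = 4.0


@dataclass
class RunConfig:
    stages: tuple[str, ...] = ("simulate", "decompose", "fingerprint")
    thresholds: Thresholds = field(default_factory=Thresholds)
    model_orders: tuple[int, ...] = (6, 8, 10, 12)
    seed: int = 0
    ica_seed: int = 17
    out_dir: str = "wmfp-out"
    in_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            tk = {f.name for f in fields(Thresholds)}
            bad = set(d["thresholds"]) - tk
            if bad:
                raise ValueError(f"unknown threshold keys: {sorted(bad)}")
            d["thresholds"] = Thresholds(**d["thresholds"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "model_orders" in d:
            d["model_orders"] = tuple(int(n) for n in d["model_orders"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["model_orders"] = list(self.model_orders)
        return d
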