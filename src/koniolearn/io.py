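"""Model / config serialization and the package CSV dialect.

Models serialize to JSON with ``repr``-exact floats (Python's ``json``
writes shortest round-trip representations), sorted keys and a fixed
layout, so save -> load -> save is byte-identical.  Datasets and traces
use comma-separated UTF-8 CSV with a header row and '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import SchemaError
from .layer import CompetitiveLayerState
from .perceptron import CpModel, InputCoding, TrainConfig

SCHEMA_VERSION = "1"

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "model_to_json",
    "model_from_json",
    "save_model",
    "load_model",
]


class RunConfig(BaseModel):
    """Validated CLI run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    schema_version: str = SCHEMA_VERSION
    neurons: int = 2
    mode: str = "supervised"
    eta: float = 0.025
    nu: float = 0.08
    k: float = 500.0
    gain: float = 1.0
    epochs: int = 16000
    seed: int = 0
    settle_max_steps: int = 25
    eval_max_steps: int = 50
    amp: bool = False
    complement: bool = True
    divisive: bool = True
    autapses: bool = True
    early_stop: bool = True
    restart_stall: int = 2500

    @field_validator("schema_version")
    @classmethod
    def _version(cls, v):
        if v != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {v!r}")
        return v

    def to_train_config(self) -> TrainConfig:
        return TrainConfig(**self.model_dump(exclude={"schema_version"}))


def model_to_json(model: CpModel) -> str:
    obj = {
        "schema_version": SCHEMA_VERSION,
        "kind": "competitive_perceptron",
        "coding": {
            "complement": model.coding.complement,
            "divisive": model.coding.divisive,
            "eps": model.coding.eps,
            "scale": model.coding.scale,
        },
        "layer": {
            "weights": model.layer.weights.tolist(),
            "autapses": model.layer.autapses.tolist(),
            "shifts": model.layer.shifts.tolist(),
            "gain": model.layer.gain,
            "k": model.layer.k,
            "nu": model.layer.nu,
            "theta_fire": model.layer.theta_fire,
        },
        "class_map": {str(k): int(v) for k, v in model.class_map.items()},
        "mode": model.mode,
        "raw_dim": model.raw_dim,
        "eval_max_steps": model.eval_max_steps,
    }
    return json.dumps(obj, sort_keys=True, indent=1) + "\n"


def model_from_json(text: str) -> CpModel:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid model JSON: {exc}") from exc
    if obj.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"schema_version mismatch: {obj.get('schema_version')!r}")
    lay = obj["layer"]
    layer = CompetitiveLayerState(
        weights=np.array(lay["weights"], dtype=float),
        autapses=np.array(lay["autapses"], dtype=float),
        shifts=np.array(lay["shifts"], dtype=float),
        gain=lay["gain"], k=lay["k"], nu=lay["nu"],
        theta_fire=lay["theta_fire"])
    coding = InputCoding(**obj["coding"])
    return CpModel(coding=coding, layer=layer,
                   class_map={int(k): v for k, v in obj["class_map"].items()},
                   mode=obj["mode"], raw_dim=obj["raw_dim"],
                   eval_max_steps=obj["eval_max_steps"])


def save_model(model: CpModel, path) -> None:
    Path(path).write_text(model_to_json(model), encoding="utf-8")


def load_model(path) -> CpModel:
    return model_from_json(Path(path).read_text(encoding="utf-8"))
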