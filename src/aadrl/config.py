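"""Run configuration: YAML-backed, with defaults mirroring the decoder's
reference parameterization (learner hyperparameters, 2-30 Hz band, 64 Hz
rate, 1 s windows)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dqlearn import DQLConfig
from .preprocess import FilterSpec
from .qlearn import QLConfig
from .rnn import RNNTrainConfig
from .states import StateConfig
from .synthetic import GeneratorConfig

__all__ = ["RunConfig", "load_config", "config_hash", "learner_config"]

_LEARNER_CFG = {
    "rnn": RNNTrainConfig,
    "ql": QLConfig,
    "dql-dnn": DQLConfig,
    "dql-rnn": DQLConfig,
}


def _build(cls, data: dict):
    """Instantiate a config dataclass from a dict, rejecting unknown keys."""
    if not data:
        return cls()
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    data = dict(data)
    for key in ("lags_ms", "kernel_lags_ms"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return cls(**data)


@dataclass
class RunConfig:
    seed: int = 0
    out: str = "results"
    n_trials: int = 1
    schedule: dict = field(default_factory=lambda: {
        "segment_s": 60.0, "total_s": 60.0, "start_side": "left"})
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    fs_out: float = 64.0
    state: StateConfig = field(default_factory=StateConfig)
    learner_kind: str = "dql-rnn"
    learner: object = None
    eval_epsilon: float = 0.02
    n_perm: int = 100

    def __post_init__(self):
        if self.learner_kind not in _LEARNER_CFG:
            raise ValueError(f"unknown learner kind: {self.learner_kind}")
        if self.learner is None:
            self.learner = _LEARNER_CFG[self.learner_kind]()

    def to_dict(self) -> dict:
        out = {
            "seed": self.seed, "out": self.out, "n_trials": self.n_trials,
            "schedule": self.schedule, "fs_out": self.fs_out,
            "learner_kind": self.learner_kind,
            "eval_epsilon": self.eval_epsilon, "n_perm": self.n_perm,
            "generator": dataclasses.asdict(self.generator),
            "filter": dataclasses.asdict(self.filter),
            "state": dataclasses.asdict(self.state),
            "learner": dataclasses.asdict(self.learner),
        }
        return out


def learner_config(kind: str, params: dict | None = None):
    return _build(_LEARNER_CFG[kind], params or {})


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    kind = raw.get("learner_kind", "dql-rnn")
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        out=str(raw.get("out", "results")),
        n_trials=int(raw.get("n_trials", 1)),
        schedule=raw.get("schedule",
                         {"segment_s": 60.0, "total_s": 60.0, "start_side": "left"}),
        generator=_build(GeneratorConfig, raw.get("generator", {})),
        filter=_build(FilterSpec, raw.get("filter", {})),
        fs_out=float(raw.get("fs_out", 64.0)),
        state=_build(StateConfig, raw.get("state", {})),
        learner_kind=kind,
        learner=learner_config(kind, raw.get("learner", {})),
        eval_epsilon=float(raw.get("eval_epsilon", 0.02)),
        n_perm=int(raw.get("n_perm", 100)),
    )
    return cfg


def config_hash(cfg: RunConfig) -> str:
    canonical = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
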