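"""Pipeline configuration: nested blocks, YAML round-trip, strict keys."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "painq_run",
    "synth": {
        "n_subjects": 6,
        "duration": 60.0,
        "class_mix": [1 / 3, 1 / 3, 1 / 3],
        "powerline_hz": 60.0,
    },
    "preprocess": {
        "low_cut": 0.5,
        "high_cut": 40.0,
        "order": 4,
        "threshold_factor": 3.0,
        "refractory": 0.2,
        "normalization": "zscore",
        "per_segment": True,
        "window": 10.0,
    },
    "cwt": {
        "n_scales": 640,
        "f_min": 0.5,
        "f_max": 40.0,
        "beta": 3.0,
        "gamma": 60.0,
    },
    "circuit": {
        "n_qubits": 9,
        "layers": 4,
        "entangler": "cz_chain",
        "rot_axes": ["x", "y", "z"],  # ["x", "x", "z"] = prose variant
    },
    "model": {
        "backbone": "eq3_stack",
        "alpha": 0.01,
        "beta_reg": 1e-4,
        "gamma_q": 1.0,
    },
    "train": {
        "learning_rate": 0.001,
        "epochs": 5,
        "batch_size": 4,
    },
    "federated": {
        "clients": 3,
        "rounds": 3,
        "local_epochs": 1,
    },
}


class MissingConfigKey(KeyError):
    pass


@dataclass
class PipelineConfig:
    """Nested configuration; unknown keys rejected, known keys defaulted."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def get(self, *path):
        node = self.data
        for key in path:
            if not isinstance(node, dict) or key not in node:
                raise MissingConfigKey(
                    f"missing config key {'.'.join(map(str, path))!r}")
            node = node[key]
        return node

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        data = copy.deepcopy(DEFAULTS)
        _merge(data, user, [])
        return cls(data=data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.data, f, sort_keys=False)


def _merge(base: dict, user: dict, path: list) -> None:
    for key, value in user.items():
        if key not in base:
            raise MissingConfigKey(
                f"unknown config key {'.'.join(path + [str(key)])!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            _merge(base[key], value, path + [str(key)])
        else:
            base[key] = value
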