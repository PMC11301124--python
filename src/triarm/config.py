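"""YAML (de)serialization of generator and run configurations.

Files carry a ``schema_version`` key so older configs can be detected
explicitly rather than misread.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .model import ModelParams
from .simulate import GeneratorConfig, PreScoreDist, reference_config

__all__ = [
    "SCHEMA_VERSION",
    "generator_config_to_dict",
    "generator_config_from_dict",
    "save_generator_config",
    "load_generator_config",
    "RunConfig",
]

SCHEMA_VERSION = 1


def _params_to_dict(p: ModelParams) -> dict:
    return {k: v for k, v in asdict(p).items() if v is not None}


def generator_config_to_dict(cfg: GeneratorConfig) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "generator",
        "n_per_arm": dict(cfg.n_per_arm),
        "truths": {o: _params_to_dict(t) for o, t in cfg.truths.items()},
        "pre_dists": {k: {"mean": d.mean, "sd": d.sd} for k, d in cfg.pre_dists.items()},
        "familiarity_probs": list(cfg.familiarity_probs),
    }


def generator_config_from_dict(d: dict) -> GeneratorConfig:
    version = d.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema_version {version!r}")
    return GeneratorConfig(
        n_per_arm=dict(d["n_per_arm"]),
        truths={o: ModelParams(**t) for o, t in d["truths"].items()},
        pre_dists={k: PreScoreDist(**v) for k, v in d["pre_dists"].items()},
        familiarity_probs=tuple(d["familiarity_probs"]),
    )


def save_generator_config(cfg: GeneratorConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(generator_config_to_dict(cfg), sort_keys=False))


def load_generator_config(path: str | Path) -> GeneratorConfig:
    return generator_config_from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunConfig:
    """End-to-end pipeline settings.

    Exactly one of ``dataset_path`` (fit an existing CSV) or ``generator``
    (simulate first) must be set.
    """

    mode: str = "full"  # simulate | fit | full
    dataset_path: str | None = None
    generator: GeneratorConfig | None = None
    chains: int = 4
    iterations: int = 3000
    warmup: int | None = None
    seed: int = 0
    out_dir: str = "triarm_out"
    report_format: str = "csv"  # csv | table

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "fit", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.dataset_path is None) == (self.generator is None):
            raise ValueError("exactly one of dataset_path or generator must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        version = d.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema_version {version!r}")
        gen = d.pop("generator", None)
        if gen is not None:
            gen = generator_config_from_dict({**gen, "schema_version": SCHEMA_VERSION})
        return cls(generator=gen, **d)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "schema_version": SCHEMA_VERSION,
            "mode": self.mode,
            "dataset_path": self.dataset_path,
            "chains": self.chains,
            "iterations": self.iterations,
            "warmup": self.warmup,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "report_format": self.report_format,
        }
        d = {k: v for k, v in d.items() if v is not None}
        if self.generator is not None:
            g = generator_config_to_dict(self.generator)
            g.pop("schema_version")
            g.pop("kind")
            d["generator"] = g
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def default_run_config(**overrides) -> RunConfig:
    base = dict(mode="full", generator=reference_config(), seed=0)
    base.update(overrides)
    return RunConfig(**base)
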