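"""Run configuration, YAML parsing, JSON report helpers."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import yaml

from .exceptions import CohortSpecError
from .synthetic import GeneratorSpec

#: The predefined random states of the repeated-run analysis.
DEFAULT_SEEDS: tuple[int, ...] = (8463, 7053, 2194, 4727, 3929)


@dataclass
class RunConfig:
    """Everything a full analysis run needs, loadable from YAML."""

    generator: dict | None = None  # GeneratorSpec overrides; None -> table_path
    table_path: str | None = None
    seeds: tuple[int, ...] = DEFAULT_SEEDS
    alpha: float = 0.05
    exclusion_percentiles: tuple[float, ...] = (70.0, 77.5, 85.0, 92.5, 100.0)
    tta_draws: int = 5
    tta_scale: float = 0.1
    stratify: bool = True
    filter_scope: str = "fold"
    importance: bool = True
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.seeds:
            raise CohortSpecError("seeds list must be non-empty")
        ps = list(self.exclusion_percentiles)
        if ps != sorted(ps) or not all(0.0 < p <= 100.0 for p in ps):
            raise CohortSpecError("exclusion percentiles must be ascending within (0,100]")
        if self.generator is None and self.table_path is None:
            raise CohortSpecError("either a generator spec or a table path is required")

    def generator_spec(self, seed: int | None = None) -> GeneratorSpec:
        overrides = dict(self.generator or {})
        if seed is not None:
            overrides["seed"] = seed
        return GeneratorSpec(**overrides)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("seeds", "exclusion_percentiles"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        """Short stable hash identifying the analysis (where it is written
        does not change what it computes, so output_dir is excluded)."""
        d = asdict(self)
        d.pop("output_dir")
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def jsonify(obj):
    """Make an object JSON-clean: tuples -> lists, NaN/inf -> None."""
    if isinstance(obj, dict):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, float):
        return None if (math.isnan(obj) or math.isinf(obj)) else obj
    if hasattr(obj, "item"):  # numpy scalars
        return jsonify(obj.item())
    return obj


def write_report(path, payload: dict, config: RunConfig | None = None, seed=None) -> None:
    """Write a JSON report stamped with config hash and seed provenance."""
    body = {"provenance": {"config_digest": config.digest() if config else None, "seed": seed}}
    body.update(payload)
    with open(path, "w") as fh:
        json.dump(jsonify(body), fh, indent=2)
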