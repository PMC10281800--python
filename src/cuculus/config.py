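"""Run configuration: YAML schema, validation, defaults."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mcmc import MCMCSettings

SCHEMA_VERSION = 1

DEFAULT_THRESHOLDS = dict(
    stopover_km=50.0,
    min_duration_days=1.0,
    cycle_gap_h=10.0,
    uncertainty_max_days=5.0,
    wa_sahara_uncertainty_days=2.0,
    breeding_disc_km=50.0,
)


class ConfigError(ValueError):
    """Configuration failed schema validation; message names the field."""


@dataclass
class RunConfig:
    seed: int
    output_dir: Path = Path("results/run")
    fixes: Path | None = None
    metadata: Path | None = None
    deaths: Path | None = None
    regions: Path | None = None           # None -> packaged region set
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    simulate: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed: a seed is mandatory for stochastic stages")
        for k, v in self.thresholds.items():
            if k not in DEFAULT_THRESHOLDS:
                raise ConfigError(f"thresholds.{k}: unknown threshold")
            if not (isinstance(v, (int, float)) and v > 0):
                raise ConfigError(f"thresholds.{k}: must be a positive number")
        for k in DEFAULT_THRESHOLDS:
            self.thresholds.setdefault(k, DEFAULT_THRESHOLDS[k])
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        doc = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {"seed", "output_dir", "paths", "thresholds", "mcmc",
                 "simulate", "schema_version"}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"{sorted(unknown)[0]}: unknown top-level field")
        if "seed" not in doc:
            raise ConfigError("seed: required field missing")
        paths = doc.get("paths") or {}
        mcmc_doc = doc.get("mcmc") or {}
        try:
            mcmc = MCMCSettings(seed=int(doc["seed"]), **mcmc_doc)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"mcmc: {e}") from None
        return cls(
            seed=int(doc["seed"]),
            output_dir=Path(doc.get("output_dir", "results/run")),
            fixes=_opt_path(paths.get("fixes")),
            metadata=_opt_path(paths.get("metadata")),
            deaths=_opt_path(paths.get("deaths")),
            regions=_opt_path(paths.get("regions")),
            thresholds=dict(doc.get("thresholds") or {}),
            mcmc=mcmc,
            simulate=dict(doc.get("simulate") or {}),
            schema_version=int(doc.get("schema_version", SCHEMA_VERSION)),
        )

    def to_yaml(self, path) -> None:
        doc = dict(
            schema_version=self.schema_version, seed=self.seed,
            output_dir=str(self.output_dir),
            paths={k: (str(getattr(self, k)) if getattr(self, k) else None)
                   for k in ("fixes", "metadata", "deaths", "regions")},
            thresholds=dict(self.thresholds),
            mcmc=dict(chains=self.mcmc.chains, burn_in=self.mcmc.burn_in,
                      draws=self.mcmc.draws),
            simulate=dict(self.simulate),
        )
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _opt_path(v):
    return Path(v) if v else None
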