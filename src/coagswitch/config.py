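"""Run configuration: YAML/JSON parsing, validation and round-tripping.

The default configuration reproduces the base case: a Caucasian patient
with median warfarin half-lives discontinuing at INR 2.5, an hourly
corridor grid over the first week, and the bridging schedule of 10 mg on
day 1 followed by 20 mg once daily.  Unknown keys are rejected so typos
fail loudly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .pk import DoseSchedule, PkParams
from .populations import make_profile

__all__ = ["RunConfig", "load_config"]


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class RunConfig:
    population: str = "caucasian"
    speed: str = "median"
    start_inr: float = 2.5
    grid_start_h: float = 0.0
    grid_stop_h: float = 168.0
    grid_step_h: float = 1.0
    trigger: str = "pt_test"
    clot_threshold_fraction: float | None = None
    rivaroxaban_ugL: float = 0.0
    doses: tuple[tuple[int, float], ...] = ((1, 10.0),) + tuple((d, 20.0) for d in range(2, 8))
    risk: str = "high"
    pk: PkParams = field(default_factory=PkParams)
    output_dir: str = "."
    seed: int = 0  # reserved; the pipeline is deterministic

    @property
    def profile(self):
        return make_profile(self.population, self.speed)

    @property
    def time_grid_h(self) -> tuple[float, ...]:
        n = int(round((self.grid_stop_h - self.grid_start_h) / self.grid_step_h))
        return tuple(float(self.grid_start_h + i * self.grid_step_h) for i in range(n + 1))

    @property
    def schedule(self) -> DoseSchedule:
        return DoseSchedule(tuple((int(d), float(mg)) for d, mg in self.doses), self.pk)

    # -- parsing -----------------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        _check_keys(data, {"scenario", "assay", "schedule", "output", "seed"}, "config")
        kw: dict = {}
        scenario = data.get("scenario", {})
        _check_keys(
            scenario,
            {"population", "speed", "start_inr", "grid_start_h", "grid_stop_h", "grid_step_h"},
            "scenario block",
        )
        kw.update(scenario)
        assay = data.get("assay", {})
        _check_keys(
            assay, {"trigger", "clot_threshold_fraction", "rivaroxaban_ugL"}, "assay block"
        )
        kw.update(assay)
        schedule = data.get("schedule", {})
        _check_keys(schedule, {"doses", "risk", "pk"}, "schedule block")
        if "doses" in schedule:
            kw["doses"] = tuple((int(d), float(mg)) for d, mg in schedule["doses"])
        if "risk" in schedule:
            kw["risk"] = schedule["risk"]
        if "pk" in schedule:
            pk_block = schedule["pk"]
            _check_keys(
                pk_block,
                {"clearance_L_h", "volume_L", "ka_per_h", "bioavailability"},
                "pk block",
            )
            kw["pk"] = PkParams(**pk_block)
        output = data.get("output", {})
        _check_keys(output, {"output_dir"}, "output block")
        kw.update(output)
        if "seed" in data:
            kw["seed"] = int(data["seed"])
        try:
            return cls(**kw)
        except TypeError as exc:  # pragma: no cover - guarded by _check_keys
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        return {
            "scenario": {
                "population": self.population,
                "speed": self.speed,
                "start_inr": self.start_inr,
                "grid_start_h": self.grid_start_h,
                "grid_stop_h": self.grid_stop_h,
                "grid_step_h": self.grid_step_h,
            },
            "assay": {
                "trigger": self.trigger,
                "clot_threshold_fraction": self.clot_threshold_fraction,
                "rivaroxaban_ugL": self.rivaroxaban_ugL,
            },
            "schedule": {
                "doses": [[int(d), float(mg)] for d, mg in self.doses],
                "risk": self.risk,
                "pk": asdict(self.pk),
            },
            "output": {"output_dir": self.output_dir},
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return RunConfig.from_dict(data)
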