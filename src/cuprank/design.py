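"""Study design: groups, endpoints, dosing schedule and the packaged
group-parameter fixture.

The vocabulary mirrors a cuprizone formulation-comparison study: seven
groups of mice (untreated control plus cuprizone formulations A-F) are
profiled in two coronal regions of the corpus callosum (215 = anterior
commissure level, 265 = rostral hippocampus level) on five quantitative
endpoints per region -- myelin (PLP) optical density, microglial (IBA1)
and astrocytic (GFAP) optical density, APP-positive spheroid density, and
relative body-weight loss -- plus an ordinal LFB-PAS myelin score.

Per-endpoint *direction* encodes which way a strong cuprizone reaction
points: demyelination lowers PLP optical density and the myelin score
(``lower_is_stronger``); gliosis, axonal damage and weight loss raise their
endpoints (``higher_is_stronger``).
"""

from __future__ import annotations

import math
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigurationError

__all__ = [
    "Direction",
    "EndpointSpec",
    "StudyDesign",
    "GroupParams",
    "DoseSchedule",
    "WeightModel",
    "StudyParams",
    "load_study_params",
    "RANKING_ENDPOINTS",
    "ENDPOINT_DIRECTIONS",
    "ENDPOINT_BOUNDS",
]

#: endpoints entering the cumulative-rank composite (the ordinal LFB myelin
#: score is reported but not ranked)
RANKING_ENDPOINTS = ("PLP_OD", "IBA1_OD", "GFAP_OD", "APP_DENSITY", "WEIGHT_LOSS")


class Direction(str, Enum):
    """Which way an endpoint moves under a strong cuprizone reaction."""

    higher_is_stronger = "higher_is_stronger"
    lower_is_stronger = "lower_is_stronger"


ENDPOINT_DIRECTIONS: dict[str, Direction] = {
    "PLP_OD": Direction.lower_is_stronger,
    "LFB_SCORE": Direction.lower_is_stronger,
    "IBA1_OD": Direction.higher_is_stronger,
    "GFAP_OD": Direction.higher_is_stronger,
    "APP_DENSITY": Direction.higher_is_stronger,
    "WEIGHT_LOSS": Direction.higher_is_stronger,
}

# Admissible value ranges, in endpoint units.  WEIGHT_LOSS is percent of
# starting weight lost (positive = loss); a gain is a negative loss with no
# lower bound, while losing more than all body weight is impossible.
ENDPOINT_BOUNDS: dict[str, tuple[float, float]] = {
    "PLP_OD": (0.0, 100.0),
    "IBA1_OD": (0.0, 100.0),
    "GFAP_OD": (0.0, 100.0),
    "APP_DENSITY": (0.0, math.inf),
    "LFB_SCORE": (1.0, 4.0),
    "WEIGHT_LOSS": (-math.inf, 100.0),
}


class EndpointSpec(BaseModel):
    """One measured endpoint in one region."""

    name: str
    region: int
    direction: Direction
    bounds: tuple[float, float]

    @field_validator("name")
    @classmethod
    def _known_name(cls, v: str) -> str:
        if v not in ENDPOINT_DIRECTIONS:
            raise ValueError(f"unknown endpoint name {v!r}")
        return v

    @field_validator("region")
    @classmethod
    def _known_region(cls, v: int) -> int:
        if v not in (215, 265):
            raise ValueError("region must be 215 or 265")
        return v

    @model_validator(mode="after")
    def _direction_convention(self) -> "EndpointSpec":
        if self.direction is not ENDPOINT_DIRECTIONS[self.name]:
            raise ValueError(
                f"{self.name} must carry direction {ENDPOINT_DIRECTIONS[self.name].value}"
            )
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must be a non-degenerate interval")
        return self

    @classmethod
    def standard(cls, name: str, region: int) -> "EndpointSpec":
        """The conventional spec (direction, bounds) for a named endpoint."""
        return cls(
            name=name,
            region=region,
            direction=ENDPOINT_DIRECTIONS[name],
            bounds=ENDPOINT_BOUNDS[name],
        )

    @property
    def key(self) -> tuple[str, int]:
        return (self.name, self.region)

    def __hash__(self) -> int:  # usable as dict key
        return hash(self.key)


class StudyDesign(BaseModel):
    """Cohort layout: groups, replication, regions and endpoints."""

    groups: list[str]
    n_per_group: int = Field(ge=2)
    regions: list[int]
    endpoints: list[EndpointSpec]
    seed: int = Field(ge=0, default=0)

    @model_validator(mode="after")
    def _consistent(self) -> "StudyDesign":
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if not set(self.regions) <= {215, 265} or not self.regions:
            raise ValueError("regions must be a non-empty subset of {215, 265}")
        keys = [e.key for e in self.endpoints]
        if len(set(keys)) != len(keys):
            raise ValueError("endpoint names must be unique within a region")
        return self


class GroupParams(BaseModel):
    """Published summary (mean, SEM) of one endpoint in one group.

    ``source_n`` is the real study's group size, used to convert the printed
    SEM back to a per-animal SD (sd = sem * sqrt(source_n)); it is decoupled
    from the simulated ``n_per_group`` so cohorts can be scaled up without
    changing the per-animal dispersion.
    """

    group: str
    endpoint: str
    region: int
    mean: float
    sem: float = Field(ge=0)
    source_n: int = Field(gt=0)

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.source_n)

    @model_validator(mode="after")
    def _finite(self) -> "GroupParams":
        if not math.isfinite(self.sd) or not math.isfinite(self.mean):
            raise ValueError("mean and sd must be finite")
        lo, hi = ENDPOINT_BOUNDS[self.endpoint]
        if not (lo <= self.mean <= hi):
            raise ValueError(
                f"mean {self.mean} outside {self.endpoint} bounds [{lo}, {hi}]"
            )
        return self


class DoseSchedule(BaseModel):
    """Cuprizone dosing: 0.3% w/w in chow, reduced to 0.275% on day 16 of 35."""

    start_concentration: float = 0.3
    reduced_concentration: float = 0.275
    reduction_day: int = 16
    duration_days: int = 35

    @model_validator(mode="after")
    def _ordered(self) -> "DoseSchedule":
        if not self.reduced_concentration < self.start_concentration:
            raise ValueError("reduced concentration must be below start concentration")
        if not 0 < self.reduction_day < self.duration_days:
            raise ValueError("reduction day must fall inside the study window")
        return self


class WeightModel(BaseModel):
    """Parameters of the body-weight trajectory simulator."""

    start_mean_g: float = Field(gt=0)
    start_sd_g: float = Field(ge=0)
    noise_sd_g: float = Field(ge=0)
    final_g: dict[str, dict[str, float]]  # group -> {mean, sem}


class StudyParams(BaseModel):
    """Everything needed to synthesize a cohort: design + group parameters."""

    design: StudyDesign
    schedule: DoseSchedule
    weights: WeightModel
    group_params: list[GroupParams]
    reference_cumulative_ranks: Optional[dict[str, dict[str, dict[str, float]]]] = None

    def params_for(self, group: str, endpoint: str, region: int) -> GroupParams:
        for p in self.group_params:
            if (p.group, p.endpoint, p.region) == (group, endpoint, region):
                return p
        raise ConfigurationError(
            f"no GroupParams for group={group!r} endpoint={endpoint!r} region={region}"
        )

    @model_validator(mode="after")
    def _complete(self) -> "StudyParams":
        have = {(p.group, p.endpoint, p.region) for p in self.group_params}
        for g in self.design.groups:
            for e in self.design.endpoints:
                if (g, e.name, e.region) not in have:
                    raise ConfigurationError(
                        f"missing GroupParams for ({g}, {e.name}, {e.region})"
                    )
        return self


def _weight_loss_params(
    weights: WeightModel, group: str, region: int, source_n: int
) -> GroupParams:
    """Derive relative weight-loss summaries from final-weight summaries.

    loss% = 100 * (start - final) / start, evaluated at the mean start
    weight; the SEM scales accordingly.  Negative loss = weight gain.
    """
    final = weights.final_g[group]
    s = weights.start_mean_g
    return GroupParams(
        group=group,
        endpoint="WEIGHT_LOSS",
        region=region,
        mean=100.0 * (s - final["mean"]) / s,
        sem=100.0 * final["sem"] / s,
        source_n=source_n,
    )


def load_study_params(path: str | Path | None = None, seed: int = 0) -> StudyParams:
    """Load group parameters from a YAML file (packaged fixture by default).

    The fixture transcribes the published per-group means and SEMs of every
    endpoint in both regions; relative weight-loss parameters are derived
    from the published end-of-study weights and the configured start weight.
    """
    if path is None:
        text = (resources.files("cuprank") / "data" / "study_params.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)

    d = raw["design"]
    source_n = int(d.get("source_n", d["n_per_group"]))
    schedule = DoseSchedule(**raw["dose_schedule"])
    weights = WeightModel(**raw["weights"])

    endpoint_specs: list[EndpointSpec] = []
    group_params: list[GroupParams] = []
    for entry in raw["endpoints"]:
        spec = EndpointSpec.standard(entry["name"], int(entry["region"]))
        endpoint_specs.append(spec)
        for group, ms in entry["groups"].items():
            group_params.append(
                GroupParams(
                    group=group,
                    endpoint=spec.name,
                    region=spec.region,
                    mean=float(ms["mean"]),
                    sem=float(ms["sem"]),
                    source_n=source_n,
                )
            )
    # one weight-loss endpoint per region, same animal-level quantity in both
    for region in d["regions"]:
        endpoint_specs.append(EndpointSpec.standard("WEIGHT_LOSS", int(region)))
        for group in d["groups"]:
            group_params.append(
                _weight_loss_params(weights, group, int(region), source_n)
            )

    design = StudyDesign(
        groups=list(d["groups"]),
        n_per_group=int(d["n_per_group"]),
        regions=[int(r) for r in d["regions"]],
        endpoints=endpoint_specs,
        seed=seed,
    )
    return StudyParams(
        design=design,
        schedule=schedule,
        weights=weights,
        group_params=group_params,
        reference_cumulative_ranks=raw.get("reference_cumulative_ranks"),
    )
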