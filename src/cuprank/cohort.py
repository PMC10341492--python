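"""Synthetic cohort generation.

Draws animal-level endpoint values from normal laws parameterized by
published group summaries (mean, SEM -> SD via the source group size),
with rejection resampling to keep values inside endpoint bounds, and
builds body-weight trajectories with the study's dosing breakpoint
(0.3% cuprizone reduced to 0.275% on day 16 after ~10% weight loss).

Determinism contract: one root seed; each animal gets an independent
substream keyed by a stable hash of (seed, animal id), so enlarging a
cohort never reshuffles existing animals and identical inputs reproduce
bit-identical cohorts.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DoseSchedule, GroupParams, StudyDesign, StudyParams
from .errors import ConfigurationError

__all__ = [
    "Cohort",
    "generate_cohort",
    "generate_weight_trajectory",
    "weight_backbone",
    "measurement_days",
    "relative_weight_change",
]

_MAX_REJECTIONS = 10_000

#: days after the dose reduction before recovery is assumed to begin
_RECOVERY_LAG_DAYS = 2

#: expected fractional nadir of cuprizone-group body weight (10% loss)
_CUPRIZONE_NADIR_FRACTION = 0.90


@dataclass
class Cohort:
    """Animal-level endpoint table plus weight trajectories.

    ``endpoints`` is tidy: one row per (animal, region, endpoint) with
    columns animal_id, group, region, endpoint, value, excluded_flag.
    ``weights`` is long: animal_id, day, grams.
    """

    endpoints: pd.DataFrame
    weights: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_csv(self, directory: str | Path) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ep = directory / "cohort_endpoints.csv"
        wt = directory / "cohort_weights.csv"
        self.endpoints.to_csv(ep, index=False)
        self.weights.to_csv(wt, index=False)
        return ep, wt

    @classmethod
    def from_csv(cls, directory: str | Path) -> "Cohort":
        directory = Path(directory)
        return cls(
            endpoints=pd.read_csv(directory / "cohort_endpoints.csv"),
            weights=pd.read_csv(directory / "cohort_weights.csv"),
        )


def _animal_rng(seed: int, animal_id: str) -> np.random.Generator:
    """Substream for one animal, stable under cohort-size changes."""
    key = zlib.crc32(animal_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


def _draw_bounded(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float]
) -> float:
    """Normal draw, rejected until inside the closed bounds interval."""
    lo, hi = bounds
    if sd == 0.0:
        return float(mean)
    for _ in range(_MAX_REJECTIONS):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ConfigurationError(
        f"rejection sampling failed: N({mean}, {sd}) has negligible mass in [{lo}, {hi}]"
    )


def measurement_days(schedule: DoseSchedule) -> np.ndarray:
    """Weighing days: twice weekly through day 14, weekly thereafter."""
    early = [0, 3, 7, 10, 14]
    late = list(range(21, schedule.duration_days + 1, 7))
    if late[-1] != schedule.duration_days:
        late.append(schedule.duration_days)
    return np.array(early + late, dtype=int)


def weight_backbone(
    day,
    schedule: DoseSchedule,
    start_weight: float,
    final_weight: float,
    is_control: bool,
):
    """Deterministic piecewise-linear weight curve, evaluated at ``day``.

    Controls grow linearly from start to final weight.  Cuprizone animals
    drop to 90% of start weight by day 14 (the observed ~10% loss that
    triggered the dose reduction), hold that nadir until shortly after the
    reduction day, then recover linearly toward their final weight.
    """
    day = np.asarray(day, dtype=float)
    T = float(schedule.duration_days)
    if is_control:
        return start_weight + (final_weight - start_weight) * day / T
    nadir = _CUPRIZONE_NADIR_FRACTION * start_weight
    drop_end = 14.0
    recovery_start = float(schedule.reduction_day + _RECOVERY_LAG_DAYS)
    out = np.empty_like(day)
    m_drop = day <= drop_end
    m_plateau = (day > drop_end) & (day <= recovery_start)
    m_rec = day > recovery_start
    out[m_drop] = start_weight + (nadir - start_weight) * day[m_drop] / drop_end
    out[m_plateau] = nadir
    out[m_rec] = nadir + (final_weight - nadir) * (day[m_rec] - recovery_start) / (
        T - recovery_start
    )
    return out


def generate_weight_trajectory(
    group: str,
    schedule: DoseSchedule,
    start_weight: float,
    noise_sd: float,
    final_weight: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Simulate one animal's weighing series as a Series indexed by day.

    ``group`` is interpreted as control iff the label is ``"control"``.
    Day 0 and the final day are anchored exactly at ``start_weight`` and
    ``final_weight``; interior days get additive N(0, noise_sd) jitter.
    """
    if start_weight <= 0:
        raise ConfigurationError("start_weight must be positive")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    if final_weight is None:
        final_weight = start_weight
    if rng is None:
        rng = np.random.default_rng(0)
    days = measurement_days(schedule)
    grams = weight_backbone(
        days, schedule, start_weight, final_weight, is_control=(group == "control")
    ).astype(float)
    if noise_sd > 0:
        jitter = rng.normal(0.0, noise_sd, size=len(days))
        jitter[0] = 0.0
        jitter[-1] = 0.0
        grams = np.maximum(grams + jitter, 0.1)
    return pd.Series(grams, index=pd.Index(days, name="day"), name="grams")


def relative_weight_change(trajectory: pd.Series) -> float:
    """Percent change of final vs starting weight; negative = loss."""
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    if 0 not in trajectory.index:
        raise ValueError("trajectory has no day-0 entry")
    start = float(trajectory.loc[0])
    if start == 0:
        raise ValueError("starting weight is zero; relative change undefined")
    final = float(trajectory.iloc[-1])
    return 100.0 * (final - start) / start


def weight_loss_percent(trajectory: pd.Series, definition: str = "final") -> float:
    """Weight loss as percent of starting weight (positive = loss).

    ``definition="final"`` uses the end-of-study weight (the default
    reading of "loss relative to starting weight"); ``"max_drop"`` uses
    the trajectory minimum instead.
    """
    if definition == "final":
        return -relative_weight_change(trajectory)
    if definition == "max_drop":
        if 0 not in trajectory.index:
            raise ValueError("trajectory has no day-0 entry")
        start = float(trajectory.loc[0])
        if start == 0:
            raise ValueError("starting weight is zero")
        return 100.0 * (start - float(trajectory.min())) / start
    raise ValueError(f"unknown weight-loss definition {definition!r}")


def generate_cohort(params: StudyParams) -> Cohort:
    """Generate a full cohort from a study design plus group parameters.

    Endpoint values are drawn per animal from N(mean, sem*sqrt(source_n))
    with rejection outside the endpoint bounds.  WEIGHT_LOSS is drawn once
    per animal (it is an animal-level quantity shared by both regions) and
    the weight trajectory is constructed to match it exactly, so
    ``relative_weight_change(trajectory) == -WEIGHT_LOSS``.
    """
    design: StudyDesign = params.design
    seed = design.seed
    ep_rows: list[dict] = []
    wt_rows: list[dict] = []

    for group in design.groups:
        for i in range(design.n_per_group):
            animal_id = f"{group}_{i + 1:02d}"
            rng = _animal_rng(seed, animal_id)
            start_w = _draw_bounded(
                rng, params.weights.start_mean_g, params.weights.start_sd_g, (1.0, np.inf)
            )
            weight_loss: float | None = None
            for spec in design.endpoints:
                gp: GroupParams = params.params_for(group, spec.name, spec.region)
                if spec.name == "WEIGHT_LOSS":
                    if weight_loss is None:
                        weight_loss = _draw_bounded(rng, gp.mean, gp.sd, spec.bounds)
                    value = weight_loss
                else:
                    value = _draw_bounded(rng, gp.mean, gp.sd, spec.bounds)
                ep_rows.append(
                    {
                        "animal_id": animal_id,
                        "group": group,
                        "region": spec.region,
                        "endpoint": spec.name,
                        "value": value,
                        "excluded_flag": False,
                    }
                )
            if weight_loss is not None:
                final_w = start_w * (1.0 - weight_loss / 100.0)
                traj = generate_weight_trajectory(
                    group,
                    params.schedule,
                    start_w,
                    params.weights.noise_sd_g,
                    final_weight=final_w,
                    rng=rng,
                )
                for day, grams in traj.items():
                    wt_rows.append(
                        {"animal_id": animal_id, "day": int(day), "grams": float(grams)}
                    )

    design_hash = hashlib.sha256(
        design.model_dump_json().encode("utf-8")
    ).hexdigest()[:16]
    return Cohort(
        endpoints=pd.DataFrame(ep_rows),
        weights=pd.DataFrame(wt_rows, columns=["animal_id", "day", "grams"]),
        provenance={"seed": seed, "design_hash": design_hash},
    )
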