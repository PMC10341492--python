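"""End-to-end orchestration: simulate -> (images ->) quantify -> rank ->
test -> report, all seeded from one root seed and persisted as tidy CSV
stages so any stage can be re-run from its inputs.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cohort import Cohort, generate_cohort, weight_loss_percent
from .design import RANKING_ENDPOINTS, StudyParams, load_study_params
from .errors import ConfigurationError
from .images import ODFieldSpec, SpheroidFieldSpec, make_od_image, make_spheroid_image
from .quantify import DEFAULT_ALGORITHM_MAP, RoiGeometry, count_spheroids, optical_density_fraction
from .ranking import cumulative_ranks, endpoint_matrix_from_tidy
from .stats import compare_groups

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

_OD_ENDPOINTS = ("PLP_OD", "IBA1_OD", "GFAP_OD")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class RunConfig(BaseModel):
    """Configuration of one pipeline run."""

    workdir: Path
    seed: int = Field(ge=0, default=0)
    params_file: Optional[Path] = None
    n_per_group: Optional[int] = None
    with_images: bool = False  # re-measure OD/APP endpoints from synthetic images
    od_image_px: int = 192  # OD field edge length in pixels
    spheroid_roi_mm2: float = 0.25
    algorithm_overrides: dict[str, str] = Field(default_factory=dict)  # "PLP_OD/265" -> label
    invert: bool = False
    weight_loss_definition: str = "final"
    image_dir: Optional[Path] = None  # default: <workdir>/images

    def load_params(self) -> StudyParams:
        if self.params_file is not None and not Path(self.params_file).exists():
            raise ConfigurationError(f"params file {self.params_file} does not exist")
        params = load_study_params(self.params_file, seed=self.seed)
        if self.n_per_group is not None:
            params.design.n_per_group = self.n_per_group
        return params

    def algorithm_map(self) -> dict[tuple[str, int], str]:
        amap = dict(DEFAULT_ALGORITHM_MAP)
        for key, label in self.algorithm_overrides.items():
            name, region = key.split("/")
            if (name, int(region)) not in amap:
                raise ConfigurationError(f"unknown endpoint/region {key!r}")
            amap[(name, int(region))] = label
        return amap


def _image_seed(root_seed: int, *parts: str) -> int:
    return (int(root_seed) * 2654435761 + zlib.crc32("/".join(parts).encode())) % (2**31)


def _stage_simulate(config: RunConfig, params: StudyParams) -> Cohort:
    cohort = generate_cohort(params)
    cohort.to_csv(config.workdir)
    return cohort


def _stage_images_and_quantify(config: RunConfig, cohort: Cohort) -> pd.DataFrame:
    """Render one synthetic field per (animal, endpoint, region) whose ground
    truth is the animal's drawn endpoint value, then re-measure it with the
    protocol's threshold algorithm.  Returns the tidy endpoint table with
    OD/APP values replaced by image measurements."""
    amap = config.algorithm_map()
    img_dir = config.image_dir or (config.workdir / "images")
    rows = []
    sidecars = []
    ep = cohort.endpoints
    px = config.od_image_px
    sp_edge = int(round(np.sqrt(config.spheroid_roi_mm2 * 1e6)))  # 1 um/px
    for rec in ep.itertuples(index=False):
        value = rec.value
        if rec.endpoint in _OD_ENDPOINTS:
            spec = ODFieldSpec(
                width=px,
                height=px,
                true_fraction=min(max(rec.value / 100.0, 0.0), 1.0),
                seed=_image_seed(config.seed, rec.animal_id, rec.endpoint, str(rec.region)),
            )
            img = make_od_image(spec)
            value = optical_density_fraction(
                img.pixels,
                RoiGeometry(img.roi_mask, img.pixel_size),
                algorithm=amap[(rec.endpoint, rec.region)],
                invert=config.invert,
            )
        elif rec.endpoint == "APP_DENSITY":
            spec = SpheroidFieldSpec(
                width=sp_edge,
                height=sp_edge,
                true_density=rec.value,
                seed=_image_seed(config.seed, rec.animal_id, rec.endpoint, str(rec.region)),
            )
            img = make_spheroid_image(spec)
            value = count_spheroids(
                img.pixels, RoiGeometry(img.roi_mask, img.pixel_size), invert=config.invert
            )
        else:
            rows.append(rec._asdict())
            continue
        sidecars.append(
            img.save(img_dir / f"{rec.animal_id}_{rec.endpoint}_{rec.region}")
            | {"animal_id": rec.animal_id, "endpoint": rec.endpoint, "region": rec.region}
        )
        row = rec._asdict()
        row["value"] = value
        rows.append(row)
    pd.DataFrame(sidecars).to_csv(img_dir / "ground_truth.csv", index=False)
    return pd.DataFrame(rows)


def _stage_weight_loss(config: RunConfig, endpoints: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Recompute WEIGHT_LOSS from the persisted trajectories (honoring the
    configured definition); identical to the drawn values under 'final'."""
    losses = {
        animal: weight_loss_percent(
            traj.set_index("day")["grams"], config.weight_loss_definition
        )
        for animal, traj in cohort.weights.groupby("animal_id")
    }
    sel = endpoints["endpoint"] == "WEIGHT_LOSS"
    endpoints = endpoints.copy()
    endpoints.loc[sel, "value"] = endpoints.loc[sel, "animal_id"].map(losses)
    return endpoints


def _stage_rank(config: RunConfig, endpoints: pd.DataFrame, regions: list[int]) -> dict[int, pd.DataFrame]:
    summaries = {}
    for region in regions:
        matrix = endpoint_matrix_from_tidy(endpoints, region)
        result = cumulative_ranks(matrix)
        per_animal = result.ranks.copy()
        per_animal["cumulative_rank"] = result.cumulative
        per_animal["group"] = matrix.groups.reindex(per_animal.index)
        per_animal.to_csv(config.workdir / f"ranks_region{region}.csv")
        result.group_summary.to_csv(config.workdir / f"rank_summary_region{region}.csv")
        summaries[region] = result.group_summary
    return summaries


def _stage_stats(config: RunConfig, endpoints: pd.DataFrame, regions: list[int]) -> pd.DataFrame:
    rows = []
    for region in regions:
        for name in sorted(endpoints.loc[endpoints["region"] == region, "endpoint"].unique()):
            sub = endpoints[(endpoints["region"] == region) & (endpoints["endpoint"] == name)]
            grouped = {g: s["value"].to_numpy() for g, s in sub.groupby("group", sort=False)}
            report = compare_groups(grouped)
            rows.append(
                {
                    "region": region,
                    "endpoint": name,
                    "test": report.test,
                    "statistic": report.statistic,
                    "pvalue": report.pvalue,
                    "n_significant_pairs": int((report.pairwise["p_adj"] <= 0.05).sum()),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(config.workdir / "stats_summary.csv", index=False)
    return df


def _stage_report(
    config: RunConfig,
    params: StudyParams,
    endpoints: pd.DataFrame,
    rank_summaries: dict[int, pd.DataFrame],
) -> pd.DataFrame:
    """Compare realized group summaries with the configured (published) ones."""
    rows = []
    for (group, name, region), sub in endpoints.groupby(["group", "endpoint", "region"]):
        gp = params.params_for(group, name, region)
        rows.append(
            {
                "group": group,
                "endpoint": name,
                "region": region,
                "simulated_mean": sub["value"].mean(),
                "simulated_sem": sub["value"].sem(ddof=1),
                "configured_mean": gp.mean,
                "configured_sem": gp.sem,
            }
        )
    report = pd.DataFrame(rows).sort_values(["region", "endpoint", "group"])
    report.to_csv(config.workdir / "report_group_summaries.csv", index=False)
    _plot_ranks(config, rank_summaries)
    return report


def _plot_ranks(config: RunConfig, rank_summaries: dict[int, pd.DataFrame]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(rank_summaries), figsize=(5 * len(rank_summaries), 4))
    axes = np.atleast_1d(axes)
    for ax, (region, summary) in zip(axes, sorted(rank_summaries.items())):
        ax.bar(summary.index, summary["mean"], yerr=summary["sem"], capsize=3)
        ax.set_title(f"Region {region}")
        ax.set_ylabel("cumulative rank (mean ± SEM)")
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(config.workdir / "cumulative_ranks.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the run directory.

    Deterministic given the seed: re-running with an identical config
    reproduces byte-identical endpoint and rank CSVs.
    """
    config.workdir.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        params = config.load_params()
        stage = "simulate-cohort"
        cohort = _stage_simulate(config, params)
        endpoints = cohort.endpoints
        if config.with_images:
            stage = "simulate-images/quantify"
            endpoints = _stage_images_and_quantify(config, cohort)
        stage = "weight-loss"
        endpoints = _stage_weight_loss(config, endpoints, cohort)
        endpoints.to_csv(config.workdir / "endpoints.csv", index=False)
        stage = "rank"
        rank_summaries = _stage_rank(config, endpoints, params.design.regions)
        stage = "stats"
        _stage_stats(config, endpoints, params.design.regions)
        stage = "report"
        _stage_report(config, params, endpoints, rank_summaries)
    except Exception as e:  # noqa: BLE001 - stage-labeled re-raise
        raise PipelineError(stage, e) from e
    log = {
        "seed": config.seed,
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
    }
    (config.workdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return config.workdir
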