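"""Cumulative rank aggregation across endpoints — the study's composite
measure of cuprizone formulation efficacy.

Within each region, every animal is ranked on every endpoint with rank 1 =
weakest cuprizone-induced reaction (highest myelin optical density, lowest
gliosis, lowest spheroid density, lowest weight loss); ties get midranks.
Per-animal ranks are summed over the five endpoints into a cumulative
rank, and cumulative ranks are summarized per group as mean ± SEM.  High
cumulative rank = strong reaction, so a more effective formulation drives
its group mean up.

Animals missing any endpoint are excluded from the whole region's ranking
before ranks are assigned (one missing label would corrupt the sum), so
ranks always run 1..N over the N complete animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import RANKING_ENDPOINTS, Direction, ENDPOINT_DIRECTIONS
from .errors import NoRankableAnimalsError

__all__ = [
    "EndpointMatrix",
    "RankResult",
    "assign_ranks",
    "exclude_incomplete",
    "cumulative_ranks",
    "endpoint_matrix_from_tidy",
]


@dataclass
class EndpointMatrix:
    """Animals × endpoints value table for one region.

    ``values``: DataFrame indexed by animal_id, one column per endpoint,
    NaN = missing.  ``groups``: Series mapping animal_id -> group label.
    ``directions``: endpoint -> Direction.
    """

    values: pd.DataFrame
    groups: pd.Series
    directions: dict[str, Direction]

    def __post_init__(self) -> None:
        missing_dir = set(self.values.columns) - set(self.directions)
        if missing_dir:
            raise ValueError(f"endpoints without a declared direction: {missing_dir}")
        without_group = set(self.values.index) - set(self.groups.index)
        if without_group:
            raise ValueError(f"animals without a group label: {without_group}")


@dataclass
class RankResult:
    """Per-animal ranks, cumulative ranks, exclusions and group summaries."""

    ranks: pd.DataFrame  # animals × endpoints, midranks allowed
    cumulative: pd.Series  # animal_id -> sum of ranks
    excluded: list[str]
    group_summary: pd.DataFrame  # index group; columns mean, sem, n


def assign_ranks(values, direction: Direction | str) -> np.ndarray:
    """Rank one endpoint's values with rank 1 = weakest reaction.

    For ``higher_is_stronger`` endpoints ranks ascend with the value; for
    ``lower_is_stronger`` (PLP optical density, LFB score) they descend.
    Ties receive midranks.  Missing values must have been excluded first.
    """
    direction = Direction(direction)
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot rank an empty value list")
    if np.isnan(v).any():
        raise RuntimeError(
            "missing value reached assign_ranks; exclusion contract violated"
        )
    if direction is Direction.lower_is_stronger:
        v = -v
    return rankdata(v, method="average")


def exclude_incomplete(matrix: EndpointMatrix) -> tuple[EndpointMatrix, list[str]]:
    """Drop every animal missing at least one endpoint, from all endpoints."""
    complete = ~matrix.values.isna().any(axis=1)
    excluded = sorted(matrix.values.index[~complete])
    if not complete.any():
        raise NoRankableAnimalsError("no rankable animals: all were excluded")
    reduced = EndpointMatrix(
        values=matrix.values.loc[complete],
        groups=matrix.groups.loc[matrix.values.index[complete]],
        directions=matrix.directions,
    )
    return reduced, excluded


def cumulative_ranks(matrix: EndpointMatrix) -> RankResult:
    """Rank every endpoint, sum per animal, summarize per group.

    Requires a complete matrix (run :func:`exclude_incomplete` first).
    The rank-sum identity holds by construction: each endpoint's ranks sum
    to N(N+1)/2, so cumulative ranks sum to E·N(N+1)/2.
    """
    reduced, excluded = exclude_incomplete(matrix)
    ranks = pd.DataFrame(
        {
            ep: assign_ranks(reduced.values[ep].to_numpy(), reduced.directions[ep])
            for ep in reduced.values.columns
        },
        index=reduced.values.index,
    )
    cumulative = ranks.sum(axis=1)
    cumulative.name = "cumulative_rank"
    by_group = cumulative.groupby(reduced.groups)
    group_summary = pd.DataFrame(
        {
            "mean": by_group.mean(),
            "sem": by_group.sem(ddof=1),
            "n": by_group.size(),
        }
    )
    return RankResult(
        ranks=ranks,
        cumulative=cumulative,
        excluded=excluded,
        group_summary=group_summary,
    )


def endpoint_matrix_from_tidy(
    endpoints: pd.DataFrame,
    region: int,
    endpoint_names: tuple[str, ...] = RANKING_ENDPOINTS,
) -> EndpointMatrix:
    """Build a region's EndpointMatrix from the tidy cohort table.

    Rows flagged ``excluded_flag`` become missing values, so flagged
    animals drop out at :func:`exclude_incomplete`.
    """
    sub = endpoints[
        (endpoints["region"] == region) & endpoints["endpoint"].isin(endpoint_names)
    ].copy()
    if sub.empty:
        raise ValueError(f"no endpoint rows for region {region}")
    if "excluded_flag" in sub.columns:
        sub.loc[sub["excluded_flag"].astype(bool), "value"] = np.nan
    wide = sub.pivot_table(
        index="animal_id", columns="endpoint", values="value", dropna=False
    )
    # pivot_table drops all-NaN animals; reindex to keep them visible
    all_animals = sub["animal_id"].unique()
    wide = wide.reindex(all_animals)
    wide = wide[[n for n in endpoint_names if n in wide.columns]]
    groups = sub.drop_duplicates("animal_id").set_index("animal_id")["group"]
    directions = {n: ENDPOINT_DIRECTIONS[n] for n in wide.columns}
    return EndpointMatrix(values=wide, groups=groups, directions=directions)
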