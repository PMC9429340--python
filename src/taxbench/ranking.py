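"""Rank aggregation: per-stratum ranks and the weighted sum of ranks.

Within each (sample, rank-level, metric) stratum teams are ranked by
score — descending for F1 (1 best), ascending for the L1 norm and
weighted UniFrac (0 best) — with ties receiving the average of the
spanned ranks.  Ranks are aggregated per team as a weighted sum: weight 1
for F1 ranks, 0.5 for each abundance metric, and an optional per-sample
divisor for replicate groups (e.g. 4 for the four sequencing replicates
of a mock-community DNA standard).  The lowest weighted sum of ranks
(wsr) wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

#: Metrics ranked in ascending order (distance-like, 0 is best).
ASCENDING_METRICS = {"L1", "wUniFrac"}

STRATUM = ["sample_id", "level", "metric"]


class RankingError(ValueError):
    pass


@dataclass(frozen=True)
class RankWeights:
    """wsr weighting policy: metric weights plus per-sample replicate divisors."""

    f1: float = 1.0
    abundance: float = 0.5
    divisors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.f1 <= 0 or self.abundance <= 0:
            raise RankingError("weights must be positive")

    def metric_weight(self, metric: str) -> float:
        if metric == "F1":
            return self.f1
        if metric in ASCENDING_METRICS:
            return self.abundance
        raise RankingError(f"no weight policy for metric {metric!r}")

    def divisor(self, sample_id: str) -> float:
        return float(self.divisors.get(sample_id, 1.0))


def ranks_from_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Add a ``rank`` column to a long-format score table.

    Expects columns team, sample_id, level, metric, value.  Ranking is
    per stratum, direction-aware, average-rank on ties.
    """
    required = {"team", "value", *STRATUM}
    missing = required - set(scores.columns)
    if missing:
        raise RankingError(f"score table missing columns {sorted(missing)}")
    out = scores.copy()
    ascending = out["metric"].isin(ASCENDING_METRICS)
    ranks = pd.Series(index=out.index, dtype=float)
    for asc in (True, False):
        mask = ascending == asc
        if mask.any():
            ranks[mask] = (
                out.loc[mask]
                .groupby(STRATUM)["value"]
                .rank(ascending=asc, method="average")
            )
    out["rank"] = ranks
    return out


def weighted_sum_of_ranks(
    ranks: pd.DataFrame, weights: RankWeights | None = None
) -> pd.Series:
    """Per-team wsr, ascending (lowest = best performer)."""
    weights = weights or RankWeights()
    if "rank" not in ranks.columns:
        raise RankingError("rank table has no 'rank' column; run ranks_from_scores")
    table = ranks.copy()
    table["weighted"] = [
        row_rank * weights.metric_weight(metric) / weights.divisor(sample)
        for row_rank, metric, sample in zip(
            table["rank"], table["metric"], table["sample_id"]
        )
    ]
    return table.groupby("team")["weighted"].sum().sort_values()


def group_aggregate(
    scores: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Mean score per (group, level, metric[, team]) over member samples.

    Failed samples must already carry their worst score, so they pull the
    group mean down rather than disappearing.  Every sample must belong
    to exactly one group.
    """
    unassigned = sorted(set(scores["sample_id"]) - set(groups))
    if unassigned:
        raise RankingError(f"samples not assigned to any group: {unassigned}")
    table = scores.copy()
    table["group"] = table["sample_id"].map(groups)
    keys = ["group", "level", "metric"]
    if "team" in table.columns:
        keys.insert(0, "team")
    aggregated = table.groupby(keys, as_index=False)["value"].mean()
    # group means feed the same ranking machinery as per-sample scores
    return aggregated.rename(columns={"group": "sample_id"})
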