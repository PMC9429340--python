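"""Random-prediction null model and score flooring.

A submission score only means something if it beats chance.  For each
(sample, rank, metric) stratum a null distribution is built by scoring
many random predictions — N species drawn uniformly without replacement
from the reference pool, given i.i.d. uniform(0, 1) abundances and
normalised — against the gold standard.  The significance threshold is
the 95th percentile of the null in the favorable direction (upper tail
for F1, lower tail for the distance metrics L1 and weighted UniFrac).
Scores that fail to beat their threshold are replaced by it, so all
chance-level submissions carry the same weight in downstream ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .metrics import (
    HIGHER_IS_BETTER,
    MetricError,
    ScoreRecord,
    confusion_counts,
    l1_norm,
    precision_recall_f1,
    weighted_unifrac,
)
from .profiles import Profile, normalize, project_to_rank
from .ranks import canonical_rank
from .taxonomy import TaxonomyTree

#: Draws used by the full-scale analysis; tests and demos scale this down.
DEFAULT_DRAWS = 10_000

PERCENTILE = 95.0


class NullModelError(ValueError):
    pass


@dataclass
class NullDistribution:
    """Null score draws and significance threshold for one stratum."""

    metric: str
    level: str
    sample_id: str
    scores: np.ndarray
    threshold: float
    higher_is_better: bool

    @property
    def n_draws(self) -> int:
        return len(self.scores)


def random_prediction(
    species_pool: Sequence[int],
    n_species: int,
    rng: np.random.Generator,
) -> Profile:
    """Uniform random species-level prediction, normalised to sum to one."""
    if n_species > len(species_pool):
        raise NullModelError(
            f"n_species {n_species} exceeds pool size {len(species_pool)}"
        )
    chosen = rng.choice(len(species_pool), size=n_species, replace=False)
    values = rng.uniform(0.0, 1.0, size=n_species)
    total = values.sum()
    abundances = {
        int(species_pool[i]): float(v / total) for i, v in zip(chosen, values)
    }
    return Profile("random", {"species": abundances}, normalized=True)


def _score_one(
    pred: Profile, gold: Profile, tree: TaxonomyTree, metric: str, level: str
) -> float:
    if metric == "F1":
        pred_l = project_to_rank(pred, tree, level)
        gold_l = project_to_rank(gold, tree, level)
        return precision_recall_f1(confusion_counts(pred_l, gold_l, level))[2]
    if metric == "L1":
        pred_l = project_to_rank(pred, tree, level)
        gold_l = project_to_rank(gold, tree, level)
        return l1_norm(pred_l, gold_l, level)
    if metric == "wUniFrac":
        return weighted_unifrac(pred, gold, tree, level=level)
    raise MetricError(f"unknown metric {metric!r}")


def null_distribution(
    gold: Profile,
    tree: TaxonomyTree,
    metric: str,
    level: str,
    n_draws: int = DEFAULT_DRAWS,
    n_species: int | None = None,
    pool: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Null score distribution for one (sample, rank, metric) stratum.

    ``n_species`` defaults to the gold standard's species richness; the
    pool defaults to every species in the reference tree.  The threshold
    is the 95th percentile of the draws for metrics where higher is
    better, the 5th percentile for distances (linear interpolation
    between order statistics).
    """
    if n_draws < 1:
        raise NullModelError("n_draws must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    level = canonical_rank(level)
    gold_n = normalize(gold)
    if not gold_n.species:
        raise NullModelError(f"gold standard {gold.sample_id} has no species")
    if pool is None:
        pool = tree.species_keys()
    if n_species is None:
        n_species = len(gold_n.species)
    higher = HIGHER_IS_BETTER[metric]
    scores = np.empty(n_draws)
    for i in range(n_draws):
        pred = random_prediction(pool, n_species, rng)
        scores[i] = _score_one(pred, gold_n, tree, metric, level)
    q = PERCENTILE if higher else 100.0 - PERCENTILE
    threshold = float(np.percentile(scores, q))
    return NullDistribution(metric, level, gold.sample_id, scores, threshold, higher)


def floor_scores(
    records: Iterable[ScoreRecord],
    nulls: Mapping[tuple[str, str, str], NullDistribution],
) -> list[ScoreRecord]:
    """Replace scores not better than their null threshold by the threshold.

    ``nulls`` is keyed by (sample_id, level, metric).  Direction-aware and
    idempotent: a floored score equals its threshold and stays there.
    """
    out: list[ScoreRecord] = []
    for record in records:
        key = (record.sample_id, record.level, record.metric)
        try:
            null = nulls[key]
        except KeyError:
            raise NullModelError(f"no null distribution for stratum {key}")
        better = (
            record.value > null.threshold
            if null.higher_is_better
            else record.value < null.threshold
        )
        if better:
            out.append(record)
        else:
            out.append(replace(record, value=null.threshold, floored=True))
    return out


def null_table(
    gold_set: Iterable[Profile],
    tree: TaxonomyTree,
    metrics: Sequence[str] = ("F1", "L1", "wUniFrac"),
    levels: Sequence[str] = ("phylum", "genus", "species"),
    n_draws: int = DEFAULT_DRAWS,
    n_species: int | None = None,
    pool: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, str, str], NullDistribution]:
    """Null distributions for every (sample, level, metric) stratum."""
    rng = rng if rng is not None else np.random.default_rng()
    nulls: dict[tuple[str, str, str], NullDistribution] = {}
    for gold in gold_set:
        for level in levels:
            for metric in metrics:
                nulls[(gold.sample_id, canonical_rank(level), metric)] = (
                    null_distribution(
                        gold, tree, metric, level,
                        n_draws=n_draws, n_species=n_species, pool=pool, rng=rng,
                    )
                )
    return nulls
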