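"""Scoring metrics for taxonomic profiles.

Qualitative scoring uses presence/absence confusion counts at a given
rank (precision, recall, F1).  Quantitative scoring uses the L1 norm over
the union of taxa and a weighted UniFrac distance computed on the
seven-rank taxonomy tree: every (rank, taxon) pair reachable from a
species lineage is a branch at depth d (superkingdom = 1 ... species = 7)
carrying the fraction of each community descending through it,

    wUniFrac = sum_i d_i |a_i - b_i|  /  sum_i d_i (a_i + b_i)

which is 0 for identical profiles and 1 for profiles sharing no branch.
An alternative variant drops the depth factor from the numerator; its
maximum on a multi-rank tree is below 1, so the depth-weighted form is
the default.  A sample whose evaluation fails for any reason receives the
worst score for every metric: F1 (and precision/recall) 0, L1 norm 2,
weighted UniFrac 1.

Shannon diversity H' = -sum p ln p and the coefficient of determination
between predicted and gold-standard Shannon indices round out the
diversity-recovery analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import numpy as np
from sklearn.metrics import r2_score

from .profiles import (
    NormalizationError,
    Profile,
    ProfileError,
    normalize,
    project_to_rank,
)
from .ranks import MAX_DEPTH, canonical_rank, depth_of
from .taxonomy import TaxonomyTree

#: Worst scores assigned to failed samples, per metric.
WORST = {"F1": 0.0, "precision": 0.0, "recall": 0.0, "L1": 2.0, "wUniFrac": 1.0}

#: Metrics where a larger value is better.
HIGHER_IS_BETTER = {"F1": True, "precision": True, "recall": True,
                    "L1": False, "wUniFrac": False}

DEFAULT_LEVELS = ("phylum", "genus", "species")


class MetricError(ValueError):
    """Invalid input to a metric computation."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class Branch:
    """One (rank, taxon) branch with community fractions."""

    depth: int  # branches from the root, superkingdom = 1
    taxid: int
    a: float  # fraction of community 1 descending through the branch
    b: float  # fraction of community 2 descending through the branch


@dataclass
class ScoreRecord:
    sample_id: str
    level: str
    metric: str
    value: float
    failed: bool = False
    floored: bool = False


# ---------------------------------------------------------------------------
# Presence/absence metrics
# ---------------------------------------------------------------------------

def _support(profile: Profile, level: str) -> set[int]:
    return {t for t, ab in profile.abundances.get(level, {}).items() if ab > 0}


def confusion_counts(pred: Profile, gold: Profile, level: str) -> ConfusionCounts:
    """Presence/absence confusion counts at a rank (presence = abundance > 0).

    The unknown sentinel never matches a gold taxon: a predicted sentinel
    counts as a false positive.
    """
    level = canonical_rank(level)
    p, g = _support(pred, level), _support(gold, level)
    return ConfusionCounts(tp=len(p & g), fp=len(p - g), fn=len(g - p))


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R); 0/0 -> 0."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f1


# ---------------------------------------------------------------------------
# Abundance metrics
# ---------------------------------------------------------------------------

def l1_norm(pred: Profile, gold: Profile, level: str) -> float:
    """Sum of absolute abundance differences over the union of taxa, in [0, 2]."""
    if not (pred.normalized and gold.normalized):
        raise MetricError("L1 norm requires normalized profiles")
    level = canonical_rank(level)
    p = pred.abundances.get(level, {})
    g = gold.abundances.get(level, {})
    return sum(abs(p.get(t, 0.0) - g.get(t, 0.0)) for t in set(p) | set(g))


def branch_table(
    pred: Profile,
    gold: Profile,
    tree: TaxonomyTree,
    max_depth: int = MAX_DEPTH,
) -> list[Branch]:
    """Enumerate tree branches touched by either species-level profile.

    Each species contributes its fraction to one branch per lineage slot
    down to ``max_depth``; unknown slots pool into a per-depth sentinel
    branch.  Only branches with a + b > 0 are returned.
    """
    acc: dict[tuple[int, int], list[float]] = {}
    for prof, side in ((pred, 0), (gold, 1)):
        for taxid, ab in prof.species.items():
            if ab <= 0:
                continue
            lineage = tree.lineage_of(taxid)
            for slot_index, slot_taxid in enumerate(lineage.slots):
                depth = MAX_DEPTH - slot_index
                if depth > max_depth:
                    continue
                key = (depth, slot_taxid)
                entry = acc.setdefault(key, [0.0, 0.0])
                entry[side] += ab
    return [
        Branch(depth=d, taxid=t, a=ab[0], b=ab[1])
        for (d, t), ab in sorted(acc.items())
    ]


def weighted_unifrac(
    pred: Profile,
    gold: Profile,
    tree: TaxonomyTree,
    variant: str = "depth_weighted",
    level: str = "species",
) -> float:
    """Weighted UniFrac distance between two normalized species profiles.

    ``level`` truncates the tree at that rank's depth, so the metric can
    be reported per taxonomic rank; species uses the full 7-rank tree.
    An empty comparison (no branches) is the worst case, distance 1.
    """
    if not (pred.normalized and gold.normalized):
        raise MetricError("weighted UniFrac requires normalized profiles")
    if variant not in ("depth_weighted", "as_printed"):
        raise MetricError(f"unknown weighted UniFrac variant {variant!r}")
    branches = branch_table(pred, gold, tree, max_depth=depth_of(level))
    denom = sum(br.depth * (br.a + br.b) for br in branches)
    if denom == 0:
        return WORST["wUniFrac"]
    if variant == "depth_weighted":
        num = sum(br.depth * abs(br.a - br.b) for br in branches)
    else:
        num = sum(abs(br.a - br.b) for br in branches)
    return num / denom


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def shannon_index(profile: Profile, level: str = "species") -> float:
    """Shannon diversity H' = -sum p ln p over taxa with p > 0."""
    if not profile.normalized:
        raise MetricError("Shannon index requires a normalized profile")
    taxa = profile.abundances.get(canonical_rank(level), {})
    values = [p for p in taxa.values() if p > 0]
    if not values:
        raise MetricError(f"sample {profile.sample_id}: empty profile at {level}")
    return -sum(p * math.log(p) for p in values)


def diversity_r2(predicted_h: Sequence[float], gold_h: Sequence[float]) -> float:
    """Coefficient of determination of predicted vs gold Shannon indices.

    1 - SS_res/SS_tot with SS_tot taken about the gold values; may be
    negative for predictions worse than the gold mean.
    """
    if len(predicted_h) != len(gold_h):
        raise MetricError("predicted and gold Shannon lists differ in length")
    if len(gold_h) < 2:
        raise MetricError("need at least two samples for R^2")
    if np.var(np.asarray(gold_h, dtype=float)) == 0:
        raise MetricError("gold Shannon indices have zero variance; R^2 undefined")
    return float(r2_score(gold_h, predicted_h))


# ---------------------------------------------------------------------------
# Per-sample scoring
# ---------------------------------------------------------------------------

def worst_scores(sample_id: str, level: str) -> list[ScoreRecord]:
    """The failed-sample score triple: F1 = 0, L1 = 2, wUniFrac = 1."""
    return [
        ScoreRecord(sample_id, level, metric, WORST[metric], failed=True)
        for metric in ("F1", "L1", "wUniFrac")
    ]


def score_sample(
    pred: Profile | None,
    gold: Profile,
    tree: TaxonomyTree,
    levels: Iterable[str] = DEFAULT_LEVELS,
    variant: str = "depth_weighted",
) -> list[ScoreRecord]:
    """Score one prediction against its gold standard at each rank.

    Both profiles must already be translated onto the tree and carry
    species-level abundances; normalisation and projection to the
    requested ranks happen here.  Any exception while scoring the sample
    (missing prediction, unparsable or unnormalisable content) yields the
    worst-score records for every level with the failed flag set; an
    invalid gold standard, by contrast, aborts the batch.
    """
    levels = [canonical_rank(lv) for lv in levels]
    gold_n = normalize(gold)  # gold errors propagate: batch-level problem
    if not gold_n.species:
        raise MetricError(f"gold standard {gold.sample_id} has no species")
    records: list[ScoreRecord] = []
    try:
        if pred is None:
            raise MetricError(f"no prediction for sample {gold.sample_id}")
        pred_n = normalize(pred)
        if not pred_n.species:
            raise MetricError(f"empty prediction for sample {gold.sample_id}")
        for level in levels:
            pred_l = project_to_rank(pred_n, tree, level)
            gold_l = project_to_rank(gold_n, tree, level)
            _, _, f1 = precision_recall_f1(confusion_counts(pred_l, gold_l, level))
            records.append(ScoreRecord(gold.sample_id, level, "F1", f1))
            records.append(
                ScoreRecord(gold.sample_id, level, "L1",
                            l1_norm(pred_l, gold_l, level))
            )
            records.append(
                ScoreRecord(
                    gold.sample_id, level, "wUniFrac",
                    weighted_unifrac(pred_n, gold_n, tree, variant, level=level),
                )
            )
    except (MetricError, ProfileError, NormalizationError, KeyError):
        records = []
        for level in levels:
            records.extend(worst_scores(gold.sample_id, level))
    return records


def records_to_frame(records: Iterable[ScoreRecord], team: str | None = None):
    """Long-format DataFrame (sample_id, level, metric, value, failed, floored)."""
    import pandas as pd

    rows = [
        {
            "sample_id": r.sample_id,
            "level": r.level,
            "metric": r.metric,
            "value": r.value,
            "failed": r.failed,
            "floored": r.floored,
        }
        for r in records
    ]
    frame = pd.DataFrame(
        rows, columns=["sample_id", "level", "metric", "value", "failed", "floored"]
    )
    if team is not None:
        frame.insert(0, "team", team)
    return frame
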