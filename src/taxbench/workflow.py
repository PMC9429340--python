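"""End-to-end orchestration: challenge-mode and extended-benchmark runs.

Challenge mode reproduces the competition's order of operations:
translate each submission onto the reference tree, normalise, score the
three metrics at three ranks (3 x 3 x samples scores per team), floor
scores at their random-prediction null thresholds, rank per stratum, and
aggregate into the weighted sum of ranks.

Extended mode benchmarks pipelines at the species level only, averages
scores over dataset groups, compares low-abundance filtering variants
(none, fixed 1%, fixed 0.1%, Shannon-adaptive) side by side, and reports
how well each pipeline recovers within-sample Shannon diversity (R^2
against the gold standards).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .filtering import filter_adaptive, filter_fixed
from .metrics import (
    DEFAULT_LEVELS,
    MetricError,
    ScoreRecord,
    diversity_r2,
    records_to_frame,
    score_sample,
    shannon_index,
)
from .nullmodel import DEFAULT_DRAWS, NullDistribution, floor_scores, null_table
from .profiles import NormalizationError, Profile, ProfileError, ProfileSet, normalize
from .ranking import RankWeights, group_aggregate, ranks_from_scores, weighted_sum_of_ranks
from .taxonomy import TaxonomyTree, TranslationReport, translate_profile

FILTER_MODES = ("none", "fixed_1pct", "fixed_0.1pct", "adaptive")


class WorkflowError(ValueError):
    pass


@dataclass
class RunConfig:
    """Paths and settings for an orchestrated run (YAML-loadable)."""

    tree: str
    gold: str
    submissions: dict[str, str]  # team/pipeline name -> Bioboxes file
    out_dir: str = "results"
    levels: Sequence[str] = DEFAULT_LEVELS
    unifrac_variant: str = "depth_weighted"
    null_draws: int = DEFAULT_DRAWS
    null_n_species: int | None = None  # None: match gold richness per sample
    seed: int = 0
    f1_weight: float = 1.0
    abundance_weight: float = 0.5
    divisors: dict[str, float] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    contexts: dict[str, str] = field(default_factory=dict)  # sample -> gut|non_gut

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def weights(self) -> RankWeights:
        return RankWeights(self.f1_weight, self.abundance_weight, self.divisors)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Library-level pipelines (pure in-memory; the CLI wraps these with file I/O)
# ---------------------------------------------------------------------------

def translate_set(
    profiles: ProfileSet, tree: TaxonomyTree
) -> tuple[ProfileSet, list[TranslationReport]]:
    translated, reports = [], []
    for profile in profiles:
        out, report = translate_profile(profile, tree)
        translated.append(out)
        if report:
            reports.append(report)
    return ProfileSet(translated, source=profiles.source), reports


def score_submissions(
    gold_set: ProfileSet,
    submissions: Mapping[str, ProfileSet],
    tree: TaxonomyTree,
    levels: Sequence[str] = DEFAULT_LEVELS,
    variant: str = "depth_weighted",
) -> dict[str, list[ScoreRecord]]:
    """Per-team score records; missing or broken samples get worst scores."""
    per_team: dict[str, list[ScoreRecord]] = {}
    for team, profiles in submissions.items():
        records: list[ScoreRecord] = []
        for gold in gold_set:
            pred = None
            if gold.sample_id in profiles:
                try:
                    pred, _ = translate_profile(profiles[gold.sample_id], tree)
                except (ProfileError, KeyError):
                    pred = None
            records.extend(score_sample(pred, gold, tree, levels, variant))
        per_team[team] = records
    return per_team


@dataclass
class ChallengeResult:
    scores: pd.DataFrame  # raw scores, long format, one row per stratum x team
    floored: pd.DataFrame  # after null-model flooring (== scores if no nulls)
    ranks: pd.DataFrame
    wsr: pd.Series
    nulls: dict[tuple[str, str, str], NullDistribution]


def run_challenge_pipeline(
    tree: TaxonomyTree,
    gold_set: ProfileSet,
    submissions: Mapping[str, ProfileSet],
    levels: Sequence[str] = DEFAULT_LEVELS,
    variant: str = "depth_weighted",
    n_draws: int | None = DEFAULT_DRAWS,
    null_n_species: int | None = None,
    weights: RankWeights | None = None,
    rng: np.random.Generator | None = None,
) -> ChallengeResult:
    """Translate -> score -> floor -> rank -> weighted sum of ranks.

    ``n_draws=None`` (or 0) skips the null model, ranking raw scores.
    """
    gold_translated, _ = translate_set(gold_set, tree)
    per_team = score_submissions(gold_translated, submissions, tree, levels, variant)

    nulls: dict[tuple[str, str, str], NullDistribution] = {}
    if n_draws:
        nulls = null_table(
            gold_translated, tree, levels=levels,
            n_draws=n_draws, n_species=null_n_species, rng=rng,
        )
        floored_per_team = {
            team: floor_scores(records, nulls)
            for team, records in per_team.items()
        }
    else:
        floored_per_team = per_team

    scores = pd.concat(
        [records_to_frame(recs, team) for team, recs in per_team.items()],
        ignore_index=True,
    )
    floored = pd.concat(
        [records_to_frame(recs, team) for team, recs in floored_per_team.items()],
        ignore_index=True,
    )
    ranks = ranks_from_scores(floored)
    wsr = weighted_sum_of_ranks(ranks, weights)
    return ChallengeResult(scores, floored, ranks, wsr, nulls)


@dataclass
class ExtendedResult:
    group_scores: dict[str, pd.DataFrame]  # filter mode -> group-mean scores
    wsr: pd.DataFrame  # index: pipeline, columns: filter modes
    shannon_r2: pd.Series  # pipeline -> R^2 of predicted vs gold Shannon


def _apply_filter(profile: Profile, mode: str, context: str,
                  tree: TaxonomyTree) -> Profile:
    if mode == "none":
        return profile
    if mode == "fixed_1pct":
        return filter_fixed(profile, 0.01, tree=tree)
    if mode == "fixed_0.1pct":
        return filter_fixed(profile, 0.001, tree=tree)
    if mode == "adaptive":
        return filter_adaptive(profile, context, tree=tree)
    raise WorkflowError(f"unknown filter mode {mode!r}")


def run_extended_pipeline(
    tree: TaxonomyTree,
    gold_set: ProfileSet,
    submissions: Mapping[str, ProfileSet],
    groups: Mapping[str, str],
    contexts: Mapping[str, str] | None = None,
    filter_modes: Sequence[str] = FILTER_MODES,
    weights: RankWeights | None = None,
) -> ExtendedResult:
    """Species-level benchmark with per-group means and filter variants."""
    contexts = contexts or {}
    gold_translated, _ = translate_set(gold_set, tree)

    # Shannon-diversity recovery per pipeline (unfiltered predictions)
    gold_h: dict[str, float] = {}
    for gold in gold_translated:
        gold_h[gold.sample_id] = shannon_index(normalize(gold))
    shannon_rows = {}
    for team, profiles in submissions.items():
        pred_h, ref_h = [], []
        for sample_id, gh in gold_h.items():
            if sample_id not in profiles:
                continue
            try:
                pred, _ = translate_profile(profiles[sample_id], tree)
                pred_h.append(shannon_index(normalize(pred)))
                ref_h.append(gh)
            except (ProfileError, NormalizationError, MetricError, KeyError):
                continue
        try:
            shannon_rows[team] = diversity_r2(pred_h, ref_h)
        except MetricError:
            shannon_rows[team] = float("nan")
    shannon_r2 = pd.Series(shannon_rows, name="shannon_r2")

    group_scores: dict[str, pd.DataFrame] = {}
    wsr_columns: dict[str, pd.Series] = {}
    for mode in filter_modes:
        filtered_submissions: dict[str, ProfileSet] = {}
        for team, profiles in submissions.items():
            filtered = []
            for profile in profiles:
                context = contexts.get(profile.sample_id, "non_gut")
                try:
                    pred, _ = translate_profile(profile, tree)
                    pred = _apply_filter(normalize(pred), mode, context, tree)
                except (ProfileError, NormalizationError, MetricError):
                    pred = Profile(profile.sample_id, {"species": {}})
                filtered.append(pred)
            filtered_submissions[team] = ProfileSet(filtered, source=team)
        per_team = score_submissions(
            gold_translated, filtered_submissions, tree, levels=("species",)
        )
        scores = pd.concat(
            [records_to_frame(recs, team) for team, recs in per_team.items()],
            ignore_index=True,
        )
        grouped = group_aggregate(scores, groups)
        group_scores[mode] = grouped
        wsr_columns[mode] = weighted_sum_of_ranks(ranks_from_scores(grouped), weights)
    wsr = pd.DataFrame(wsr_columns)
    return ExtendedResult(group_scores, wsr, shannon_r2)


# ---------------------------------------------------------------------------
# File-level runs
# ---------------------------------------------------------------------------

def _load_inputs(config: RunConfig):
    from .profiles import read_bioboxes
    from .taxonomy import deserialize_tree

    tree = deserialize_tree(Path(config.tree).read_text())
    gold_set = read_bioboxes(Path(config.gold).read_text(), source="gold")
    submissions = {
        team: read_bioboxes(Path(path).read_text(), source=team)
        for team, path in config.submissions.items()
    }
    return tree, gold_set, submissions


def _stamp(config: RunConfig, out_dir: Path) -> None:
    meta = {"config_hash": config.digest(), "seed": config.seed}
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")


def run_challenge(config: RunConfig) -> ChallengeResult:
    """File-based challenge run; writes score/rank/wsr TSVs to out_dir."""
    tree, gold_set, submissions = _load_inputs(config)
    rng = np.random.default_rng(config.seed)
    result = run_challenge_pipeline(
        tree, gold_set, submissions,
        levels=config.levels, variant=config.unifrac_variant,
        n_draws=config.null_draws, null_n_species=config.null_n_species,
        weights=config.weights(), rng=rng,
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.scores.to_csv(out_dir / "scores.tsv", sep="\t", index=False)
    result.floored.to_csv(out_dir / "scores_floored.tsv", sep="\t", index=False)
    result.ranks.to_csv(out_dir / "ranks.tsv", sep="\t", index=False)
    result.wsr.rename("wsr").to_csv(out_dir / "wsr.tsv", sep="\t")
    if result.nulls:
        rows = [
            {"sample_id": n.sample_id, "level": n.level, "metric": n.metric,
             "threshold": n.threshold, "n_draws": n.n_draws}
            for n in result.nulls.values()
        ]
        pd.DataFrame(rows).to_csv(out_dir / "null_thresholds.tsv", sep="\t",
                                  index=False)
    _stamp(config, out_dir)
    return result


def run_extended(config: RunConfig) -> ExtendedResult:
    """File-based extended-benchmark run; writes per-mode tables to out_dir."""
    tree, gold_set, submissions = _load_inputs(config)
    if not config.groups:
        raise WorkflowError("extended mode needs a sample -> group mapping")
    result = run_extended_pipeline(
        tree, gold_set, submissions, config.groups, config.contexts,
        weights=config.weights(),
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for mode, frame in result.group_scores.items():
        frame.to_csv(out_dir / f"group_scores_{mode}.tsv", sep="\t", index=False)
    result.wsr.to_csv(out_dir / "wsr_by_filter.tsv", sep="\t")
    result.shannon_r2.to_csv(out_dir / "shannon_r2.tsv", sep="\t")
    _stamp(config, out_dir)
    return result
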