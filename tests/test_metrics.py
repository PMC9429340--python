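"""Scoring metrics: confusion counts, L1, weighted UniFrac, Shannon, R^2."""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from taxbench.metrics import (
    ConfusionCounts,
    MetricError,
    confusion_counts,
    diversity_r2,
    l1_norm,
    precision_recall_f1,
    score_sample,
    shannon_index,
    weighted_unifrac,
    worst_scores,
)
from taxbench.profiles import normalize
from taxbench.ranks import MAX_DEPTH
from taxbench.simulate import make_toy_fixtures
from taxbench.taxonomy import build_reference_tree, parse_ncbi_dump

from conftest import random_profile_on, species_profile


def brute_force_unifrac(pred, gold, tree, depth_weighted=True, max_depth=MAX_DEPTH):
    """Independent oracle: enumerate every (depth, taxon) branch by scanning
    all species lineages, summing each community's descending fraction."""
    branch_ids = set()
    for profile in (pred, gold):
        for sp in profile.species:
            lineage = tree.lineage_of(sp)
            for i, taxon in enumerate(lineage.slots):
                depth = MAX_DEPTH - i
                if depth <= max_depth:
                    branch_ids.add((depth, taxon))
    num = den = 0.0
    for depth, taxon in branch_ids:
        slot = MAX_DEPTH - depth
        a = sum(ab for sp, ab in pred.species.items()
                if tree.lineage_of(sp).slots[slot] == taxon)
        b = sum(ab for sp, ab in gold.species.items()
                if tree.lineage_of(sp).slots[slot] == taxon)
        num += (depth if depth_weighted else 1) * abs(a - b)
        den += depth * (a + b)
    return num / den if den else 1.0


class TestConfusion:
    @pytest.mark.parametrize(
        "pred,gold,expected",
        [
            ({1: 0.4, 2: 0.3, 4: 0.3}, {1: 0.5, 2: 0.3, 3: 0.2}, (2, 1, 1)),
            ({1: 0.5, 2: 0.5}, {1: 0.5, 2: 0.5}, (2, 0, 0)),
            ({5: 1.0}, {1: 0.5, 2: 0.5}, (0, 1, 2)),
        ],
    )
    def test_set_algebra(self, pred, gold, expected):
        profile_p = species_profile("s", pred)
        profile_g = species_profile("s", gold)
        c = confusion_counts(profile_p, profile_g, "species")
        assert (c.tp, c.fp, c.fn) == expected

    def test_zero_abundance_is_absence(self):
        c = confusion_counts(
            species_profile("s", {1: 0.0, 2: 1.0}),
            species_profile("s", {1: 0.5, 2: 0.5}),
            "species",
        )
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(2, 1, 1), (2 / 3, 2 / 3, 2 / 3)),
            (ConfusionCounts(0, 5, 3), (0.0, 0.0, 0.0)),
            (ConfusionCounts(4, 0, 0), (1.0, 1.0, 1.0)),
            (ConfusionCounts(0, 0, 0), (0.0, 0.0, 0.0)),  # 0/0 -> 0
        ],
    )
    def test_precision_recall_f1(self, counts, expected):
        assert precision_recall_f1(counts) == pytest.approx(expected)


class TestL1:
    def test_identical_profiles_distance_zero(self):
        p = normalize(species_profile("s", {1: 0.6, 2: 0.4}))
        assert l1_norm(p, p, "species") == 0.0

    def test_disjoint_profiles_distance_two(self):
        p = normalize(species_profile("s", {1: 0.6, 2: 0.4}))
        g = normalize(species_profile("s", {3: 0.5, 4: 0.5}))
        assert l1_norm(p, g, "species") == pytest.approx(2.0)

    def test_union_semantics_hand_case(self):
        g = normalize(species_profile("s", {1: 0.6, 2: 0.4}))
        p = normalize(species_profile("s", {1: 0.4, 2: 0.4, 3: 0.2}))
        assert l1_norm(p, g, "species") == pytest.approx(0.4)

    def test_requires_normalized_input(self):
        p = species_profile("s", {1: 0.5})
        with pytest.raises(MetricError):
            l1_norm(p, p, "species")

    @settings(max_examples=60, derandomize=True, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(seed=st.integers(0, 10_000))
    def test_range_symmetry_triangle(self, two_kingdom_tree, seed):
        rng = np.random.default_rng(seed)
        a = random_profile_on(two_kingdom_tree, rng)
        b = random_profile_on(two_kingdom_tree, rng)
        c = random_profile_on(two_kingdom_tree, rng)
        d_ab = l1_norm(a, b, "species")
        assert 0.0 <= d_ab <= 2.0 + 1e-12
        assert d_ab == pytest.approx(l1_norm(b, a, "species"))
        assert d_ab <= l1_norm(a, c, "species") + l1_norm(c, b, "species") + 1e-9

    @settings(max_examples=40, derandomize=True, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(seed=st.integers(0, 10_000))
    def test_aggregation_is_a_contraction(self, two_kingdom_tree, seed):
        """L1 at a higher rank never exceeds species-level L1."""
        from taxbench.profiles import project_all

        rng = np.random.default_rng(seed)
        a = project_all(random_profile_on(two_kingdom_tree, rng), two_kingdom_tree)
        b = project_all(random_profile_on(two_kingdom_tree, rng), two_kingdom_tree)
        species_d = l1_norm(a, b, "species")
        for level in ("genus", "family", "phylum", "superkingdom"):
            assert l1_norm(a, b, level) <= species_d + 1e-9


class TestWeightedUnifrac:
    def test_identity_is_zero_under_both_variants(self, two_kingdom_tree):
        p = normalize(species_profile("s", {100: 0.6, 200: 0.4}))
        for variant in ("depth_weighted", "as_printed"):
            assert weighted_unifrac(p, p, two_kingdom_tree, variant) == 0.0

    def test_root_disjoint_is_one_depth_weighted(self, two_kingdom_tree):
        p = normalize(species_profile("s", {100: 0.7, 101: 0.3}))
        g = normalize(species_profile("s", {200: 0.5, 201: 0.5}))
        assert weighted_unifrac(p, g, two_kingdom_tree) == pytest.approx(1.0)

    def test_root_disjoint_as_printed_is_quarter(self, two_kingdom_tree):
        # 14 unshared branches, denominator 2 * (1 + ... + 7) = 56
        p = normalize(species_profile("s", {100: 1.0}))
        g = normalize(species_profile("s", {200: 1.0}))
        assert weighted_unifrac(
            p, g, two_kingdom_tree, "as_printed"
        ) == pytest.approx(14 / 56)

    def test_congeneric_profiles_differ_only_at_species_depth(
        self, two_kingdom_tree
    ):
        from taxbench.metrics import branch_table

        p = normalize(species_profile("s", {100: 1.0}))
        g = normalize(species_profile("s", {101: 1.0}))
        differing = [
            br for br in branch_table(p, g, two_kingdom_tree) if br.a != br.b
        ]
        assert {br.depth for br in differing} == {MAX_DEPTH}

    def test_empty_comparison_is_worst_score(self, two_kingdom_tree):
        empty = normalize(species_profile("s", {}))
        assert weighted_unifrac(empty, empty, two_kingdom_tree) == 1.0

    def test_matches_brute_force_oracle_on_random_trees(self):
        """Oracle equivalence on 200 random toy trees of <= 50 species."""
        rng = np.random.default_rng(2024)
        max_delta = 0.0
        for _ in range(200):
            n_species = int(rng.integers(2, 51))
            n_genera = int(rng.integers(1, max(2, n_species // 2)))
            n_phyla = int(rng.integers(1, n_genera + 1))
            nodes, names, _ = make_toy_fixtures(n_species, n_genera, n_phyla, rng)
            tree = build_reference_tree(parse_ncbi_dump(nodes, names))
            pred = random_profile_on(tree, rng)
            gold = random_profile_on(tree, rng)
            got = weighted_unifrac(pred, gold, tree)
            want = brute_force_unifrac(pred, gold, tree)
            max_delta = max(max_delta, abs(got - want))
        assert max_delta < 1e-10

    @settings(max_examples=50, derandomize=True, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(seed=st.integers(0, 10_000))
    def test_range_and_symmetry(self, two_kingdom_tree, seed):
        rng = np.random.default_rng(seed)
        a = random_profile_on(two_kingdom_tree, rng)
        b = random_profile_on(two_kingdom_tree, rng)
        d = weighted_unifrac(a, b, two_kingdom_tree)
        assert 0.0 <= d <= 1.0 + 1e-12
        assert d == pytest.approx(weighted_unifrac(b, a, two_kingdom_tree))


class TestShannon:
    def test_single_taxon_is_zero(self):
        assert shannon_index(normalize(species_profile("s", {1: 1.0}))) == 0.0

    def test_uniform_profile_is_log_richness(self):
        p = normalize(species_profile("s", {i: 0.25 for i in range(4)}))
        assert shannon_index(p) == pytest.approx(math.log(4))

    def test_hand_case(self):
        p = normalize(species_profile("s", {1: 0.5, 2: 0.25, 3: 0.25}))
        assert shannon_index(p) == pytest.approx(1.0397, abs=1e-4)

    def test_empty_profile_fails(self):
        with pytest.raises(MetricError):
            shannon_index(normalize(species_profile("s", {})))


class TestDiversityR2:
    def test_perfect_prediction_is_one(self):
        assert diversity_r2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_constant_mean_prediction_is_zero(self):
        assert diversity_r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_hand_case(self):
        assert diversity_r2([1.1, 2.0, 2.9], [1.0, 2.0, 3.0]) == pytest.approx(0.99)

    def test_length_mismatch_and_zero_variance_rejected(self):
        with pytest.raises(MetricError):
            diversity_r2([1.0], [1.0, 2.0])
        with pytest.raises(MetricError):
            diversity_r2([1.0, 2.0], [2.0, 2.0])


class TestScoreSample:
    def test_perfect_prediction_scores_perfectly_at_all_levels(
        self, two_kingdom_tree
    ):
        gold = species_profile("s1", {100: 0.6, 200: 0.4})
        records = score_sample(gold.copy(), gold, two_kingdom_tree)
        by_metric = {(r.level, r.metric): r.value for r in records}
        for level in ("phylum", "genus", "species"):
            assert by_metric[(level, "F1")] == 1.0
            assert by_metric[(level, "L1")] == 0.0
            assert by_metric[(level, "wUniFrac")] == 0.0

    def test_absent_sample_gets_worst_scores_everywhere(self, two_kingdom_tree):
        gold = species_profile("s1", {100: 1.0})
        records = score_sample(None, gold, two_kingdom_tree)
        assert all(r.failed for r in records)
        values = {(r.level, r.metric): r.value for r in records}
        for level in ("phylum", "genus", "species"):
            assert values[(level, "F1")] == 0.0
            assert values[(level, "L1")] == 2.0
            assert values[(level, "wUniFrac")] == 1.0

    def test_worst_score_triple(self):
        records = worst_scores("s", "species")
        assert {(r.metric, r.value) for r in records} == {
            ("F1", 0.0), ("L1", 2.0), ("wUniFrac", 1.0)
        }
        assert all(r.failed for r in records)

    def test_19_samples_3_levels_3_metrics_yield_171_records(
        self, two_kingdom_tree, rng
    ):
        total = []
        for i in range(19):
            gold = random_profile_on(two_kingdom_tree, rng)
            gold = species_profile(f"s{i}", gold.species)
            total.extend(score_sample(gold.copy(), gold, two_kingdom_tree))
        assert len(total) == 171
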