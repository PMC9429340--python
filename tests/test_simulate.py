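"""Community simulator: designs, read accounting, and perturbations."""

import math

import numpy as np
import pytest

from taxbench.filtering import complexity_label
from taxbench.metrics import (
    confusion_counts,
    precision_recall_f1,
    shannon_index,
)
from taxbench.simulate import (
    CONGENERIC_GENUS_SIZE,
    SimulationError,
    SpeciesCatalog,
    _select_species,
    add_host_contamination,
    largest_remainder,
    make_toy_fixtures,
    perturb_profile,
    simulate_biased,
    simulate_high_complexity,
    simulate_low_complexity,
)

import pandas as pd


@pytest.fixture(scope="module")
def catalog():
    _, _, cat = make_toy_fixtures(600, 80, 6, np.random.default_rng(21))
    return cat


class TestLowComplexity:
    def test_reads_conserved_without_jitter(self, catalog, rng):
        sample = simulate_low_complexity(catalog, 5, 10_000, jitter=0.0, rng=rng)
        assert sum(sample.species_reads.values()) == 10_000

    def test_reads_proportional_to_priors(self):
        cat = SpeciesCatalog(pd.DataFrame({
            "taxid": [1, 2, 3],
            "genus_taxid": [10, 10, 11],
            "genome_length": [1e6] * 3,
            "gc_fraction": [0.5] * 3,
            "prior_abundance": [0.5, 0.3, 0.2],
        }))
        sample = simulate_low_complexity(
            cat, 3, 1000, jitter=0.0, rng=np.random.default_rng(0)
        )
        assert sorted(sample.species_reads.values(), reverse=True) == [500, 300, 200]

    def test_jitter_bounds_total_reads(self, catalog):
        rng = np.random.default_rng(8)
        for _ in range(10):
            sample = simulate_low_complexity(catalog, 5, 10_000, jitter=0.10,
                                             rng=rng)
            assert 10_000 <= sum(sample.species_reads.values()) <= 11_000

    def test_oversized_request_rejected(self, catalog, rng):
        with pytest.raises(SimulationError):
            simulate_low_complexity(catalog, 10_000, 1000, rng=rng)


class TestHighComplexity:
    def test_species_count_reaches_or_exceeds_target(self, catalog, rng):
        sample = simulate_high_complexity(catalog, 200, rng)
        assert len(sample.species_reads) >= 200 * 0.95  # minus zero-read tail

    def test_congeneric_phase_uses_genera_of_4_to_11_species(self, catalog, rng):
        target = 100
        species = _select_species(catalog.table, target, rng)
        genus_of = catalog.table.set_index("taxid")["genus_taxid"]
        sizes = catalog.table.groupby("genus_taxid").size()
        lo, hi = CONGENERIC_GENUS_SIZE
        for taxid in species[target // 2:]:  # the congeneric fill
            assert lo <= sizes[genus_of[taxid]] <= hi

    def test_log_coverages_recover_lognormal_minus1_1(self):
        """Mean/sd of log coverage match the design within 3 SE at n = 5000."""
        _, _, big = make_toy_fixtures(12_000, 1600, 12, np.random.default_rng(1))
        sample = simulate_high_complexity(big, 5000, np.random.default_rng(2))
        lengths = big.table.set_index("taxid")["genome_length"]
        log_cov = np.array([
            math.log(reads * 300.0 / lengths[taxid])
            for taxid, reads in sample.species_reads.items()
        ])
        n = len(log_cov)
        se_mean = 1.0 / math.sqrt(n)
        se_sd = 1.0 / math.sqrt(2 * (n - 1))
        assert abs(log_cov.mean() - (-1.0)) < 3 * se_mean + 0.01  # rounding slack
        assert abs(log_cov.std(ddof=1) - 1.0) < 3 * se_sd + 0.01


class TestBiased:
    def test_biased_half_carries_half_the_read_mass(self, catalog, rng):
        sample = simulate_biased(catalog, 100, "GC", rng)
        gc = catalog.table.set_index("taxid")["gc_fraction"]
        biased_mass = sum(
            r for t, r in sample.species_reads.items() if gc[t] > 0.6
        )
        total = sum(sample.species_reads.values())
        # rich species also appear in the unbiased half, so >= half the mass
        # must be rich; the strictly-biased allocation is half the total
        assert biased_mass >= total * 0.5 - 1
        assert sample.bias == "GC"

    def test_at_bias_selects_at_rich_species(self, catalog, rng):
        sample = simulate_biased(catalog, 100, "AT", rng)
        gc = catalog.table.set_index("taxid")["gc_fraction"]
        at_rich_mass = sum(
            r for t, r in sample.species_reads.items() if (1 - gc[t]) > 0.6
        )
        assert at_rich_mass >= sum(sample.species_reads.values()) * 0.5 - 1

    def test_no_rich_species_is_an_error(self, rng):
        flat = SpeciesCatalog(pd.DataFrame({
            "taxid": range(1, 41),
            "genus_taxid": [100 + i // 5 for i in range(40)],
            "genome_length": [1e6] * 40,
            "gc_fraction": [0.5] * 40,
        }))
        with pytest.raises(SimulationError, match="rich"):
            simulate_biased(flat, 20, "GC", rng)


class TestHostContamination:
    def test_host_fraction_always_in_8_to_11_percent(self, catalog):
        rng = np.random.default_rng(31)
        for _ in range(20):
            sample = simulate_low_complexity(catalog, 10, 50_000, rng=rng)
            with_host = add_host_contamination(sample, rng=rng)
            fraction = with_host.host_reads / with_host.total_reads
            assert 0.079 <= fraction <= 0.111

    def test_hand_checked_host_read_count(self, catalog):
        sample = simulate_low_complexity(
            catalog, 5, 10_000, jitter=0.0, rng=np.random.default_rng(0)
        )

        class FixedRng:
            def uniform(self, lo, hi):
                return 0.10

        with_host = add_host_contamination(sample, rng=FixedRng())
        assert with_host.host_reads == 1111

    def test_gold_standard_excludes_host(self, catalog, rng):
        sample = simulate_low_complexity(catalog, 5, 10_000, rng=rng)
        with_host = add_host_contamination(sample, rng=rng)
        assert with_host.gold.species == sample.gold.species

    def test_double_contamination_rejected(self, catalog, rng):
        sample = add_host_contamination(
            simulate_low_complexity(catalog, 5, 10_000, rng=rng), rng=rng
        )
        with pytest.raises(SimulationError):
            add_host_contamination(sample, rng=rng)


class TestGoldProfiles:
    def test_gold_is_exact_read_proportions(self, catalog, rng):
        sample = simulate_high_complexity(catalog, 60, rng)
        total = sum(sample.species_reads.values())
        for taxid, reads in sample.species_reads.items():
            assert sample.gold.species[taxid] == pytest.approx(reads / total)
        assert sum(sample.gold.species.values()) == pytest.approx(1.0)

    def test_complexity_labels_match_design_extremes(self, catalog):
        rng = np.random.default_rng(17)
        few_uniform = simulate_low_complexity(catalog, 5, 10_000, rng=rng)
        assert few_uniform.complexity in ("low", "high")
        assert complexity_label(shannon_index(few_uniform.gold)) == \
            few_uniform.complexity
        _, _, big = make_toy_fixtures(3000, 400, 10, np.random.default_rng(9))
        many = simulate_high_complexity(big, 1000, rng)
        assert many.complexity == "high"

    def test_largest_remainder_hits_the_total_exactly(self, rng):
        for _ in range(20):
            weights = rng.uniform(0.01, 1.0, size=int(rng.integers(1, 30)))
            total = int(rng.integers(1, 100_000))
            counts = largest_remainder(weights, total)
            assert counts.sum() == total and (counts >= 0).all()


class TestPerturbation:
    def test_null_perturbation_is_identity(self, catalog, rng):
        sample = simulate_low_complexity(catalog, 10, 10_000, rng=rng)
        pred = perturb_profile(sample.gold, rng=rng)
        assert pred.species == pytest.approx(sample.gold.species)

    def test_ten_fps_on_ten_species_gold_halve_precision(self, catalog):
        rng = np.random.default_rng(13)
        sample = simulate_low_complexity(catalog, 10, 10_000, rng=rng)
        pred = perturb_profile(
            sample.gold, n_fp=10, pool=catalog.table["taxid"].tolist(), rng=rng
        )
        precision, recall, _ = precision_recall_f1(
            confusion_counts(pred, sample.gold, "species")
        )
        assert precision == pytest.approx(0.5)
        assert recall == pytest.approx(1.0)

    def test_dropout_rate_recovers_recall(self):
        """recall ~ 1 - fn_rate at large richness (3 SE tolerance)."""
        _, _, big = make_toy_fixtures(3000, 400, 10, np.random.default_rng(9))
        rng = np.random.default_rng(29)
        sample = simulate_high_complexity(big, 800, rng)
        n = len(sample.gold.species)
        pred = perturb_profile(sample.gold, fn_rate=0.5, rng=rng)
        _, recall, _ = precision_recall_f1(
            confusion_counts(pred, sample.gold, "species")
        )
        se = math.sqrt(0.25 / n)
        assert abs(recall - 0.5) < 3 * se

    def test_fp_pool_exhaustion_rejected(self, catalog, rng):
        sample = simulate_low_complexity(catalog, 10, 1000, rng=rng)
        with pytest.raises(SimulationError, match="pool"):
            perturb_profile(sample.gold, n_fp=5,
                            pool=list(sample.gold.species), rng=rng)


class TestToyFixtures:
    def test_same_seed_identical_fixtures(self):
        a = make_toy_fixtures(40, 8, 3, np.random.default_rng(5))
        b = make_toy_fixtures(40, 8, 3, np.random.default_rng(5))
        assert a[0] == b[0] and a[1] == b[1]
        pd.testing.assert_frame_equal(a[2].table, b[2].table)

    def test_inconsistent_counts_rejected(self, rng):
        with pytest.raises(SimulationError):
            make_toy_fixtures(5, 10, 2, rng)
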