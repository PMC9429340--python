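"""Shared fixtures: hand-built toy taxonomies and profile helpers."""

from __future__ import annotations

import numpy as np
import pytest

from taxbench.profiles import Profile
from taxbench.taxonomy import Lineage, TaxonomyTree


def make_lineage(species, genus, family, order, klass, phylum, superkingdom):
    return Lineage((species, genus, family, order, klass, phylum, superkingdom))


def species_profile(sample_id: str, abundances: dict[int, float],
                    normalized: bool = False) -> Profile:
    return Profile(sample_id, {"species": dict(abundances)}, normalized=normalized)


@pytest.fixture
def two_kingdom_tree() -> TaxonomyTree:
    """Complete 7-rank tree with two superkingdoms.

    Kingdom 2: phylum 10 > class 11 > order 12 > family 13 > genera 14, 15;
    species 100, 101 (genus 14) and 102 (genus 15).
    Kingdom 3: phylum 20 > ... > genus 24; species 200, 201.
    """
    lineages = {
        100: make_lineage(100, 14, 13, 12, 11, 10, 2),
        101: make_lineage(101, 14, 13, 12, 11, 10, 2),
        102: make_lineage(102, 15, 13, 12, 11, 10, 2),
        200: make_lineage(200, 24, 23, 22, 21, 20, 3),
        201: make_lineage(201, 24, 23, 22, 21, 20, 3),
    }
    names = {2: "KingdomA", 3: "KingdomB", 10: "PhylumA", 20: "PhylumB"}
    return TaxonomyTree(lineages, names=names)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_profile_on(tree: TaxonomyTree, rng: np.random.Generator,
                      n_species: int | None = None) -> Profile:
    """Random normalized species profile over a tree's species keys."""
    pool = tree.species_keys()
    n = n_species or rng.integers(1, len(pool) + 1)
    chosen = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
    values = rng.uniform(0.1, 1.0, size=len(chosen))
    values /= values.sum()
    return Profile(
        "random",
        {"species": {pool[i]: float(v) for i, v in zip(chosen, values)}},
        normalized=True,
    )
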