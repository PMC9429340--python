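"""Synthetic gold-standard communities and perturbed predictions.

The simulator reproduces the benchmark's community designs so the whole
scoring stack can be exercised without any sequencing data:

* low/medium complexity (< 500 species): species drawn uniformly from a
  catalog of candidates, reads allocated proportionally to their prior
  (gut-survey) abundances, with a 0-10% jitter on the read budget;
* high complexity (>= 500 species): per-species coverage drawn from a
  log-normal with log-scale mean -1 and sd 1; half the species picked
  uniformly, the other half filled genus-by-genus from genera holding
  4-11 species (all species of a chosen genus enter, stressing
  species-level discrimination), stopping once the target is reached or
  exceeded;
* AT/GC-biased designs: half the read mass goes to species rich in the
  chosen base class (base fraction > 0.60), the other half is unbiased;
  each half is again split into uniform and congeneric picks.  Below 500
  species the biased design uses log-normal(1.2, 0.8) coverages;
* host contamination: 8-11% of the final read total, excluded from the
  gold standard.

Reads are integers obtained by expectation plus largest-remainder
rounding, so gold-standard profiles (read proportions) are exact.
Perturbed copies of a gold standard emulate profiler output: false
negatives by random dropout, false positives injected at low abundance,
multiplicative log-normal noise on surviving abundances.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .filtering import complexity_label
from .metrics import shannon_index
from .profiles import Profile

READ_LENGTH = 150  # paired-end, so a read pair covers 2 * READ_LENGTH bases
HOST_FRACTION_RANGE = (0.08, 0.11)
CONGENERIC_GENUS_SIZE = (4, 11)  # genera eligible for the congeneric phase
RICH_BASE_FRACTION = 0.60  # AT- or GC-content above this marks a "rich" genome
HIGH_COMPLEXITY_MIN = 500

CATALOG_COLUMNS = ["taxid", "genus_taxid", "genome_length", "gc_fraction",
                   "prior_abundance"]


class SimulationError(ValueError):
    pass


@dataclass
class SpeciesCatalog:
    """Reference species table: taxID, genus, genome length, GC, prior."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(CATALOG_COLUMNS[:4]) - set(self.table.columns)
        if missing:
            raise SimulationError(f"catalog missing columns {sorted(missing)}")
        if "prior_abundance" not in self.table.columns:
            self.table = self.table.assign(prior_abundance=np.nan)
        if self.table["taxid"].duplicated().any():
            raise SimulationError("duplicate taxIDs in catalog")
        if (self.table["genome_length"] <= 0).any():
            raise SimulationError("genome lengths must be positive")
        gc = self.table["gc_fraction"]
        if ((gc < 0) | (gc > 1)).any():
            raise SimulationError("GC fractions must lie in [0, 1]")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, text: str) -> "SpeciesCatalog":
        return cls(pd.read_csv(io.StringIO(text), sep="\t"))

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)

    def rich_subset(self, bias: str,
                    threshold: float = RICH_BASE_FRACTION) -> "pd.DataFrame":
        """Rows whose AT (or GC) base fraction exceeds the rich threshold."""
        if bias == "GC":
            mask = self.table["gc_fraction"] > threshold
        elif bias == "AT":
            mask = (1.0 - self.table["gc_fraction"]) > threshold
        else:
            raise SimulationError(f"bias must be 'AT' or 'GC', got {bias!r}")
        return self.table[mask]


@dataclass(frozen=True)
class SimulationDesign:
    """Knobs of one community design (defaults = the benchmark's values)."""

    target_species: int = 1000
    coverage_model: str = "lognormal"  # or "prior_abundance"
    lognormal_mu: float = -1.0
    lognormal_sigma: float = 1.0
    congeneric_fraction: float = 0.5
    bias: str = "none"  # none | AT | GC
    biased_read_fraction: float = 0.5
    total_reads: int = 1_000_000
    read_jitter: float = 0.10
    host_fraction_range: tuple[float, float] = HOST_FRACTION_RANGE
    read_length: int = READ_LENGTH


@dataclass
class CommunitySample:
    """Simulated gold standard: integer read counts plus derived profile."""

    sample_id: str
    species_reads: dict[int, int]
    host_reads: int = 0
    bias: str = "none"
    complexity: str = ""
    gold: Profile = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.species_reads.values()):
            raise SimulationError("negative read count")
        if self.gold is None:
            self.gold = gold_profile(self.sample_id, self.species_reads)
        if not self.complexity:
            self.complexity = complexity_label(shannon_index(self.gold))

    @property
    def total_reads(self) -> int:
        return sum(self.species_reads.values()) + self.host_reads


def gold_profile(sample_id: str, species_reads: dict[int, int]) -> Profile:
    """Exact read-proportion profile (host reads excluded)."""
    total = sum(species_reads.values())
    if total <= 0:
        raise SimulationError("community has no species reads")
    abundances = {t: r / total for t, r in species_reads.items() if r > 0}
    return Profile(sample_id, {"species": abundances}, normalized=True)


def largest_remainder(weights: Sequence[float], total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise SimulationError("weights must have positive sum")
    exact = w / w.sum() * total
    counts = np.floor(exact).astype(int)
    shortfall = total - counts.sum()
    if shortfall:
        order = np.argsort(exact - counts)[::-1]
        counts[order[:shortfall]] += 1
    return counts


# ---------------------------------------------------------------------------
# Community designs
# ---------------------------------------------------------------------------

def simulate_low_complexity(
    catalog: SpeciesCatalog,
    n_species: int,
    total_reads: int,
    jitter: float = 0.10,
    rng: np.random.Generator | None = None,
    sample_id: str = "low",
) -> CommunitySample:
    """Uniformly drawn species with prior-proportional read allocation."""
    rng = rng if rng is not None else np.random.default_rng()
    candidates = catalog.table[catalog.table["prior_abundance"].notna()]
    if n_species > len(candidates):
        raise SimulationError(
            f"n_species {n_species} exceeds {len(candidates)} candidates with priors"
        )
    rows = candidates.iloc[
        rng.choice(len(candidates), size=n_species, replace=False)
    ]
    total = int(round(total_reads * (1.0 + rng.uniform(0.0, jitter))))
    counts = largest_remainder(rows["prior_abundance"].to_numpy(), total)
    reads = {int(t): int(c) for t, c in zip(rows["taxid"], counts)}
    return CommunitySample(sample_id, reads, bias="none")


def _congeneric_fill(
    pool: pd.DataFrame,
    already: set[int],
    n_missing: int,
    rng: np.random.Generator,
) -> list[int]:
    """Fill species by taking whole genera of 4-11 (pool) species until the
    shortfall is covered or exceeded."""
    sizes = pool.groupby("genus_taxid")["taxid"].apply(list)
    eligible = [
        (genus, members)
        for genus, members in sizes.items()
        if CONGENERIC_GENUS_SIZE[0] <= len(members) <= CONGENERIC_GENUS_SIZE[1]
    ]
    if not eligible:
        raise SimulationError("no genera with 4-11 species available")
    order = rng.permutation(len(eligible))
    picked: list[int] = []
    for idx in order:
        if len(picked) >= n_missing:
            break
        _, members = eligible[idx]
        picked.extend(m for m in members if m not in already and m not in picked)
    if len(picked) < n_missing:
        raise SimulationError("congeneric genera exhausted before reaching target")
    return picked


def _select_species(
    pool: pd.DataFrame, target_n: int, rng: np.random.Generator
) -> list[int]:
    """Half uniform draws, half whole-genus congeneric fills."""
    n_uniform = target_n // 2
    if n_uniform > len(pool):
        raise SimulationError("species pool smaller than uniform half")
    uniform = [
        int(t)
        for t in pool["taxid"].iloc[
            rng.choice(len(pool), size=n_uniform, replace=False)
        ]
    ]
    congeneric = _congeneric_fill(pool, set(uniform), target_n - n_uniform, rng)
    return uniform + congeneric


def _coverage_reads(
    catalog: SpeciesCatalog,
    taxids: Sequence[int],
    mu: float,
    sigma: float,
    rng: np.random.Generator,
    read_length: int = READ_LENGTH,
) -> dict[int, int]:
    lengths = catalog.table.set_index("taxid")["genome_length"]
    coverage = rng.lognormal(mean=mu, sigma=sigma, size=len(taxids))
    reads = {}
    for taxid, cov in zip(taxids, coverage):
        n = int(round(cov * float(lengths.loc[taxid]) / (2 * read_length)))
        if n > 0:
            reads[int(taxid)] = n
    if not reads:
        raise SimulationError("all species received zero reads")
    return reads


def simulate_high_complexity(
    catalog: SpeciesCatalog,
    target_n: int,
    rng: np.random.Generator | None = None,
    read_length: int = READ_LENGTH,
    sample_id: str = "high",
) -> CommunitySample:
    """Log-normal(-1, 1) coverage design with a congeneric second half."""
    rng = rng if rng is not None else np.random.default_rng()
    species = _select_species(catalog.table, target_n, rng)
    reads = _coverage_reads(catalog, species, -1.0, 1.0, rng, read_length)
    return CommunitySample(sample_id, reads, bias="none")


def simulate_biased(
    catalog: SpeciesCatalog,
    target_n: int,
    bias: str,
    rng: np.random.Generator | None = None,
    read_length: int = READ_LENGTH,
    rich_threshold: float = RICH_BASE_FRACTION,
    sample_id: str | None = None,
) -> CommunitySample:
    """AT- or GC-biased design: half the reads from base-rich species.

    Below 500 species the coverages come from log-normal(1.2, 0.8), at or
    above from log-normal(-1, 1).  The biased half's read mass is scaled
    to match the unbiased half's exactly (up to integer rounding).
    """
    rng = rng if rng is not None else np.random.default_rng()
    rich = catalog.rich_subset(bias, rich_threshold)
    if rich.empty:
        raise SimulationError(f"catalog has no {bias}-rich species")
    if target_n < HIGH_COMPLEXITY_MIN:
        mu, sigma = 1.2, 0.8
    else:
        mu, sigma = -1.0, 1.0
    n_unbiased = target_n // 2
    n_biased = target_n - n_unbiased
    unbiased_species = _select_species(catalog.table, n_unbiased, rng)
    biased_species = [
        t for t in _select_species(rich, n_biased, rng)
        if t not in set(unbiased_species)
    ]
    if not biased_species:
        raise SimulationError("no distinct biased species selected")
    unbiased_reads = _coverage_reads(catalog, unbiased_species, mu, sigma, rng,
                                     read_length)
    # biased half: coverage-proportional, scaled to the unbiased read mass
    lengths = catalog.table.set_index("taxid")["genome_length"]
    weights = rng.lognormal(mu, sigma, size=len(biased_species)) * np.array(
        [float(lengths.loc[t]) for t in biased_species]
    )
    biased_counts = largest_remainder(weights, sum(unbiased_reads.values()))
    reads = dict(unbiased_reads)
    for taxid, count in zip(biased_species, biased_counts):
        if count > 0:
            reads[taxid] = reads.get(taxid, 0) + int(count)
    return CommunitySample(
        sample_id or f"{bias.lower()}_biased", reads, bias=bias
    )


def add_host_contamination(
    sample: CommunitySample,
    fraction_range: tuple[float, float] = HOST_FRACTION_RANGE,
    rng: np.random.Generator | None = None,
) -> CommunitySample:
    """Add host reads making up 8-11% of the final total.

    The gold standard is unchanged: host reads are contamination, not
    community members.  Applying this twice is an error.
    """
    if sample.host_reads > 0:
        raise SimulationError(f"sample {sample.sample_id} already has host reads")
    rng = rng if rng is not None else np.random.default_rng()
    f = rng.uniform(*fraction_range)
    species_total = sum(sample.species_reads.values())
    host = int(round(f / (1.0 - f) * species_total))
    return CommunitySample(
        sample.sample_id,
        dict(sample.species_reads),
        host_reads=host,
        bias=sample.bias,
        complexity=sample.complexity,
        gold=sample.gold.copy(),
    )


# ---------------------------------------------------------------------------
# Synthetic predictions
# ---------------------------------------------------------------------------

def perturb_profile(
    gold: Profile,
    fn_rate: float = 0.0,
    n_fp: int = 0,
    fp_abundance_scale: float = 1e-3,
    noise_sd: float = 0.0,
    pool: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
) -> Profile:
    """Emulate an imperfect profiler on a gold standard.

    Each gold species is dropped with probability ``fn_rate``; ``n_fp``
    species absent from the gold standard are injected with log-normal
    low abundances scaled by ``fp_abundance_scale`` (false positives are
    predominantly low-abundance species, as observed for real profilers);
    surviving abundances get multiplicative exp(N(0, noise_sd)) noise.
    The result is renormalized.
    """
    if not 0.0 <= fn_rate <= 1.0:
        raise SimulationError("fn_rate must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    abundances: dict[int, float] = {}
    for taxid, ab in gold.species.items():
        if fn_rate > 0 and rng.uniform() < fn_rate:
            continue
        value = ab
        if noise_sd > 0:
            value *= math.exp(rng.normal(0.0, noise_sd))
        abundances[taxid] = value
    if n_fp > 0:
        if pool is None:
            raise SimulationError("a species pool is required to inject FPs")
        candidates = [t for t in pool if t not in gold.species]
        if len(candidates) < n_fp:
            raise SimulationError(
                f"pool exhausted: {len(candidates)} candidates for {n_fp} FPs"
            )
        chosen = rng.choice(len(candidates), size=n_fp, replace=False)
        for i in chosen:
            abundances[int(candidates[i])] = float(
                fp_abundance_scale * rng.lognormal(0.0, 1.0)
            )
    total = sum(abundances.values())
    if total <= 0:
        return Profile(gold.sample_id, {"species": {}}, normalized=False)
    return Profile(
        gold.sample_id,
        {"species": {t: v / total for t, v in abundances.items()}},
        normalized=True,
    )


# ---------------------------------------------------------------------------
# Toy fixtures
# ---------------------------------------------------------------------------

def make_toy_fixtures(
    n_species: int,
    n_genera: int,
    n_phyla: int,
    rng: np.random.Generator | None = None,
) -> tuple[str, str, SpeciesCatalog]:
    """Random but internally consistent toy taxonomy plus species catalog.

    Emits nodes.dmp / names.dmp text in the NCBI dump dialect.  Every
    phylum carries a full class/order/family chain, genera are spread
    over families and species over genera, so all lineages are complete.
    Genome lengths are uniform on [1, 10] Mbp, GC on [0.25, 0.75], and
    priors are normalised log-normal draws.
    """
    if not n_species >= n_genera >= n_phyla >= 1:
        raise SimulationError("need n_species >= n_genera >= n_phyla >= 1")
    rng = rng if rng is not None else np.random.default_rng()

    nodes: list[tuple[int, int, str]] = [(1, 1, "no rank")]
    names: dict[int, str] = {1: "root"}
    next_id = 2

    def add(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        taxid = next_id
        next_id += 1
        nodes.append((taxid, parent, rank))
        names[taxid] = name
        return taxid

    superkingdom = add(1, "superkingdom", "Bacteria")
    family_ids: list[int] = []
    for p in range(n_phyla):
        phylum = add(superkingdom, "phylum", f"Phylum{p}")
        klass = add(phylum, "class", f"Class{p}")
        order = add(klass, "order", f"Order{p}")
        family_ids.append(add(order, "family", f"Family{p}"))

    genus_ids: list[int] = []
    for g in range(n_genera):
        parent = family_ids[g % len(family_ids)]
        genus_ids.append(add(parent, "genus", f"Genus{g}"))

    species_ids: list[int] = []
    genus_of: dict[int, int] = {}
    # each genus gets at least one species; the rest are spread at random
    assignment = list(range(n_genera))
    assignment += [int(i) for i in rng.integers(0, n_genera, n_species - n_genera)]
    rng.shuffle(assignment)
    for s, g in enumerate(assignment):
        sp = add(genus_ids[g], "species", f"Species{s}")
        species_ids.append(sp)
        genus_of[sp] = genus_ids[g]

    nodes_text = "".join(f"{t}\t|\t{p}\t|\t{r}\t|\n" for t, p, r in nodes)
    names_text = "".join(
        f"{t}\t|\t{n}\t|\t\t|\tscientific name\t|\n" for t, n in names.items()
    )

    priors = rng.lognormal(0.0, 1.0, size=n_species)
    catalog = SpeciesCatalog(
        pd.DataFrame(
            {
                "taxid": species_ids,
                "genus_taxid": [genus_of[s] for s in species_ids],
                "genome_length": rng.integers(1_000_000, 10_000_001, n_species),
                "gc_fraction": rng.uniform(0.25, 0.75, n_species),
                "prior_abundance": priors / priors.sum(),
            }
        )
    )
    return nodes_text, names_text, catalog
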