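"""Taxonomic profiles and Bioboxes profiling-format I/O.

A :class:`Profile` maps, per taxonomic rank, taxon identifiers (NCBI-style
taxIDs) to relative abundances stored as unitless fractions.  Profiles are
read and written in the Bioboxes profiling format (tab-separated sections
headed by ``@SampleID``, with ``@@TAXID RANK TAXPATH TAXPATHSN PERCENTAGE``
data rows); percentages in files become fractions in memory.

Higher ranks can be (re)computed from species rows by projection through a
reference taxonomy tree: the abundance of a genus, say, is the sum of the
abundances of the species whose lineage passes through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping

from .ranks import MAX_DEPTH, RANKS, canonical_rank, depth_of

if TYPE_CHECKING:  # pragma: no cover
    from .taxonomy import TaxonomyTree

#: Tolerance on per-rank abundance sums when validating normalisation.
SUM_TOL = 1e-6


class ProfileError(ValueError):
    """Malformed profile content or format violation."""


class NormalizationError(ProfileError):
    """A rank could not be normalised (zero total abundance)."""


@dataclass
class Profile:
    """Relative-abundance profile of one sample.

    Parameters
    ----------
    sample_id:
        Sample identifier, unique within a :class:`ProfileSet`.
    abundances:
        Mapping rank name -> {taxID -> fraction}.  Fractions are
        non-negative; a normalised profile sums to 1 per rank.
    normalized:
        True once :func:`normalize` has been applied.
    """

    sample_id: str
    abundances: dict[str, dict[int, float]] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        for rank, taxa in self.abundances.items():
            for taxid, ab in taxa.items():
                if ab < 0:
                    raise ProfileError(
                        f"negative abundance {ab} for taxID {taxid} "
                        f"at rank {rank} in sample {self.sample_id}"
                    )

    @property
    def species(self) -> dict[int, float]:
        return self.abundances.get("species", {})

    def rank_sum(self, rank: str) -> float:
        return sum(self.abundances.get(rank, {}).values())

    def ranks(self) -> list[str]:
        """Ranks present, in canonical root-to-leaf order."""
        present = set(self.abundances)
        ordered = [r for r in RANKS if r in present]
        ordered.extend(sorted(present - set(RANKS)))
        return ordered

    def copy(self) -> "Profile":
        return Profile(
            self.sample_id,
            {rank: dict(taxa) for rank, taxa in self.abundances.items()},
            self.normalized,
        )


@dataclass
class ProfileSet:
    """Ordered collection of profiles from one source (team / pipeline)."""

    profiles: list[Profile] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        ids = [p.sample_id for p in self.profiles]
        if len(ids) != len(set(ids)):
            raise ProfileError(f"duplicate sample_ids in ProfileSet {self.source!r}")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[Profile]:
        return iter(self.profiles)

    def __getitem__(self, sample_id: str) -> Profile:
        for p in self.profiles:
            if p.sample_id == sample_id:
                return p
        raise KeyError(sample_id)

    def __contains__(self, sample_id: str) -> bool:
        return any(p.sample_id == sample_id for p in self.profiles)

    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]


# ---------------------------------------------------------------------------
# Bioboxes profiling format
# ---------------------------------------------------------------------------

_DATA_COLUMNS = ("TAXID", "RANK", "TAXPATH", "TAXPATHSN", "PERCENTAGE")


def read_bioboxes(text: str, source: str = "") -> ProfileSet:
    """Parse one or more Bioboxes profiling sections into a ProfileSet.

    Percentages are divided by 100; per-rank totals may sum to less than
    (but not more than) 100 percent.  Raises :class:`ProfileError` on a
    missing ``@SampleID``, a negative percentage, or a rank whose
    percentages exceed 100.
    """
    profiles: list[Profile] = []
    sample_id: str | None = None
    columns: dict[str, int] = {}
    abundances: dict[str, dict[int, float]] = {}

    def flush() -> None:
        nonlocal sample_id, abundances
        if sample_id is None:
            return
        _check_rank_sums(sample_id, abundances)
        profiles.append(Profile(sample_id, abundances))
        sample_id, abundances = None, {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if line.startswith("@@"):
            header = [c.strip().upper() for c in line[2:].split("\t")]
            columns = {name: i for i, name in enumerate(header)}
            continue
        if line.startswith("@"):
            key, _, value = line[1:].partition(":")
            key = key.strip().lower()
            if key == "sampleid":
                flush()
                sample_id = value.strip()
            # @Version, @Ranks, @TaxonomyID are accepted and ignored:
            # rank tokens are taken from the data rows themselves.
            continue
        # data row
        if sample_id is None:
            raise ProfileError(f"line {lineno}: data row before any @SampleID header")
        fields = line.split("\t")
        try:
            idx_tax = columns.get("TAXID", 0)
            idx_rank = columns.get("RANK", 1)
            idx_pct = columns.get("PERCENTAGE", len(fields) - 1)
            taxid = int(fields[idx_tax])
            rank = canonical_rank(fields[idx_rank])
            pct = float(fields[idx_pct])
        except (IndexError, ValueError) as exc:
            raise ProfileError(f"line {lineno}: malformed data row: {line!r}") from exc
        if pct < 0:
            raise ProfileError(f"line {lineno}: negative percentage {pct}")
        abundances.setdefault(rank, {})
        abundances[rank][taxid] = abundances[rank].get(taxid, 0.0) + pct / 100.0
    flush()

    if not profiles:
        raise ProfileError("no @SampleID section found")
    return ProfileSet(profiles, source=source)


def _check_rank_sums(sample_id: str, abundances: Mapping[str, Mapping[int, float]]) -> None:
    for rank, taxa in abundances.items():
        total = sum(taxa.values())
        if total > 1.0 + SUM_TOL:
            raise ProfileError(
                f"sample {sample_id}: rank {rank} abundances sum to "
                f"{total * 100:.4f}% (> 100%)"
            )


def write_bioboxes(profiles: ProfileSet | Profile, tree: "TaxonomyTree") -> str:
    """Serialise profiles to Bioboxes profiling text.

    TAXPATH is the pipe-separated root-to-taxon chain of taxIDs derived
    from the reference tree; unknown lineage slots appear as empty fields,
    following the Bioboxes convention for missing ranks.
    """
    if isinstance(profiles, Profile):
        profiles = ProfileSet([profiles])
    chunks: list[str] = []
    for profile in profiles:
        lines = [
            f"@SampleID:{profile.sample_id}",
            "@Version:0.9.1",
            "@Ranks:" + "|".join(RANKS),
            "",
            "@@" + "\t".join(_DATA_COLUMNS),
        ]
        for rank in profile.ranks():
            depth = depth_of(rank) if rank in RANKS else MAX_DEPTH
            for taxid, ab in profile.abundances[rank].items():
                path_ids = _taxpath(tree, taxid, rank, depth)
                taxpath = "|".join(
                    "" if t == tree.unknown_id else str(t) for t in path_ids
                )
                taxpathsn = "|".join(
                    "" if t == tree.unknown_id else tree.names.get(t, str(t))
                    for t in path_ids
                )
                lines.append(
                    f"{taxid}\t{rank}\t{taxpath}\t{taxpathsn}\t{ab * 100:.6f}"
                )
        chunks.append("\n".join(lines))
    return "\n\n".join(chunks) + "\n"


def _taxpath(tree: "TaxonomyTree", taxid: int, rank: str, depth: int) -> list[int]:
    lineage = tree.lineage_containing(taxid, rank)
    if lineage is None:
        raise ProfileError(
            f"taxID {taxid} at rank {rank} has no lineage in the reference tree"
        )
    root_to_leaf = list(reversed(lineage.slots))  # superkingdom ... species
    return root_to_leaf[:depth]


# ---------------------------------------------------------------------------
# Normalisation and projection
# ---------------------------------------------------------------------------

def normalize(profile: Profile) -> Profile:
    """Rescale every rank to sum to one.  Idempotent.

    Raises :class:`NormalizationError` if a non-empty rank has zero total
    abundance (callers treat this as a failed sample).
    """
    out: dict[str, dict[int, float]] = {}
    for rank, taxa in profile.abundances.items():
        if not taxa:
            out[rank] = {}
            continue
        total = sum(taxa.values())
        if total <= 0:
            raise NormalizationError(
                f"sample {profile.sample_id}: rank {rank} has zero total abundance"
            )
        out[rank] = {t: ab / total for t, ab in taxa.items()}
    return Profile(profile.sample_id, out, normalized=True)


def project_to_rank(profile: Profile, tree: "TaxonomyTree", level: str) -> Profile:
    """Derive a higher-rank profile by summing species abundances.

    Species whose lineage has the unknown sentinel at the requested slot
    are pooled under the sentinel.  Raises :class:`ProfileError` if a
    species is absent from the tree (translate the profile first).
    """
    level = canonical_rank(level)
    if level not in RANKS:
        raise ProfileError(f"unknown rank {level!r}")
    if level == "species":
        return Profile(profile.sample_id, {"species": dict(profile.species)},
                       profile.normalized)
    slot = MAX_DEPTH - depth_of(level)  # index into leaf-to-root lineage slots
    out: dict[int, float] = {}
    for taxid, ab in profile.species.items():
        lineage = tree.lineage_map.get(tree.resolve(taxid))
        if lineage is None:
            raise ProfileError(
                f"species taxID {taxid} not in reference tree; translate first"
            )
        parent = lineage.slots[slot]
        out[parent] = out.get(parent, 0.0) + ab
    return Profile(profile.sample_id, {level: out}, profile.normalized)


def project_all(profile: Profile, tree: "TaxonomyTree",
                levels: Iterable[str] = RANKS) -> Profile:
    """Species profile expanded to every requested rank by projection."""
    abundances: dict[str, dict[int, float]] = {}
    for level in levels:
        abundances[canonical_rank(level)] = project_to_rank(
            profile, tree, level
        ).abundances[canonical_rank(level)]
    return Profile(profile.sample_id, abundances, profile.normalized)
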