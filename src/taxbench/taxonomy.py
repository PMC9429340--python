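"""Reference seven-rank taxonomy tree and taxID reconciliation.

Profilers ship their own reference databases, so the same organism can be
reported under different, or obsolete, taxIDs.  For a fair comparison all
profiles are mapped onto one frozen reference tree built from NCBI-style
``nodes.dmp`` / ``names.dmp`` dumps.  The tree is a dictionary keyed by
species and subspecies taxIDs whose value is the taxID lineage over the
seven canonical ranks (species, genus, family, order, class, phylum,
superkingdom).  Lineages missing the species or superkingdom rank, or
missing more than three of the seven ranks, are pruned; up to three
missing ranks are filled with an "unknown" sentinel taxID.

Reconciliation of a foreign profile applies three rules: (i) subspecies
collapse onto their species, abundances summed; (ii) obsolete taxIDs are
replaced via the merged-ID table (chains resolved); (iii) colliding
replacements have their abundances summed.  TaxIDs that resolve nowhere
are dropped and reported, never fatal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping

from .profiles import Profile
from .ranks import MAX_DEPTH, RANKS, canonical_rank

#: Default sentinel for a missing lineage slot.  Negative, so it can never
#: collide with a real (positive) taxID.
UNKNOWN_ID = -1
UNKNOWN_TOKEN = "unknown"

#: Lineage slot order, leaf to root.
LINEAGE_RANKS: tuple[str, ...] = tuple(reversed(RANKS))


class TaxonomyError(ValueError):
    """Structural problem in taxonomy input or tree construction."""


@dataclass(frozen=True)
class Lineage:
    """Seven-slot taxID lineage, ordered species -> superkingdom.

    The species and superkingdom slots always hold real taxIDs; at most
    three of the seven slots may be the unknown sentinel.
    """

    slots: tuple[int, int, int, int, int, int, int]
    unknown_id: int = UNKNOWN_ID

    def __post_init__(self) -> None:
        if len(self.slots) != MAX_DEPTH:
            raise TaxonomyError(f"lineage needs {MAX_DEPTH} slots, got {len(self.slots)}")
        if self.slots[0] == self.unknown_id or self.slots[-1] == self.unknown_id:
            raise TaxonomyError("species and superkingdom slots must be known")
        if self.n_unknown > 3:
            raise TaxonomyError("more than three unknown lineage slots")

    @property
    def species(self) -> int:
        return self.slots[0]

    @property
    def superkingdom(self) -> int:
        return self.slots[-1]

    @property
    def n_unknown(self) -> int:
        return sum(1 for s in self.slots if s == self.unknown_id)

    def at_rank(self, rank: str) -> int:
        return self.slots[MAX_DEPTH - 1 - RANKS.index(canonical_rank(rank))]


@dataclass
class RawTaxonomy:
    """Parsed node and name records from an NCBI-style dump.

    ``nodes`` maps taxID -> (parent taxID, rank name); ``names`` holds
    scientific names only.
    """

    nodes: dict[int, tuple[int, str]] = field(default_factory=dict)
    names: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.nodes)


def _split_dmp_line(line: str) -> list[str]:
    # NCBI dump dialect: fields separated by <tab>|<tab>, record ends <tab>|
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def parse_ncbi_dump(nodes_text: str, names_text: str) -> RawTaxonomy:
    """Parse nodes.dmp / names.dmp content.

    Only "scientific name"-class name records are retained.  A malformed
    record raises :class:`TaxonomyError` naming the line; so does a
    duplicated taxID in nodes.
    """
    raw = RawTaxonomy()
    for lineno, line in enumerate(nodes_text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line)
        if len(fields) < 3:
            raise TaxonomyError(f"nodes.dmp line {lineno}: expected >= 3 fields")
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise TaxonomyError(f"nodes.dmp line {lineno}: non-integer taxID") from exc
        if taxid in raw.nodes:
            raise TaxonomyError(f"nodes.dmp line {lineno}: duplicate taxID {taxid}")
        raw.nodes[taxid] = (parent, canonical_rank(fields[2]))
    for lineno, line in enumerate(names_text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line)
        if len(fields) < 4:
            raise TaxonomyError(f"names.dmp line {lineno}: expected >= 4 fields")
        try:
            taxid = int(fields[0])
        except ValueError as exc:
            raise TaxonomyError(f"names.dmp line {lineno}: non-integer taxID") from exc
        if fields[3].strip().lower() == "scientific name":
            raw.names[taxid] = fields[1].strip()
    return raw


def parse_merged_dump(text: str) -> dict[int, int]:
    """Parse merged.dmp (obsolete taxID -> replacement)."""
    merged: dict[int, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line)
        if len(fields) < 2:
            raise TaxonomyError(f"merged.dmp line {lineno}: expected 2 fields")
        merged[int(fields[0])] = int(fields[1])
    return merged


@dataclass
class TaxonomyTree:
    """Species/subspecies-keyed lineage dictionary plus ID reconciliation maps."""

    lineage_map: dict[int, Lineage]
    names: dict[int, str] = field(default_factory=dict)
    merged: dict[int, int] = field(default_factory=dict)
    unknown_id: int = UNKNOWN_ID

    def resolve(self, taxid: int) -> int:
        """Follow the merged-ID table (already chain-resolved)."""
        return self.merged.get(taxid, taxid)

    def lineage_of(self, taxid: int) -> Lineage:
        lineage = self.lineage_map.get(self.resolve(taxid))
        if lineage is None:
            raise KeyError(f"taxID {taxid} not in reference tree")
        return lineage

    @cached_property
    def _rank_members(self) -> dict[str, set[int]]:
        members: dict[str, set[int]] = {rank: set() for rank in RANKS}
        for lineage in self.lineage_map.values():
            for slot, taxid in zip(LINEAGE_RANKS, lineage.slots):
                if taxid != self.unknown_id:
                    members[slot].add(taxid)
        return members

    def rank_members(self, rank: str) -> set[int]:
        """All taxIDs appearing at a rank across retained lineages."""
        return self._rank_members[canonical_rank(rank)]

    def species_keys(self) -> list[int]:
        """Keys that are species proper (not subspecies aliases)."""
        return sorted(t for t, lin in self.lineage_map.items() if lin.species == t)

    def lineage_containing(self, taxid: int, rank: str) -> Lineage | None:
        """Some lineage whose slot at `rank` is `taxid` (for TAXPATH output)."""
        taxid = self.resolve(taxid)
        if canonical_rank(rank) == "species":
            return self.lineage_map.get(taxid)
        return self._rank_representative.get((canonical_rank(rank), taxid))

    @cached_property
    def _rank_representative(self) -> dict[tuple[str, int], Lineage]:
        rep: dict[tuple[str, int], Lineage] = {}
        for lineage in self.lineage_map.values():
            for slot, taxid in zip(LINEAGE_RANKS, lineage.slots):
                rep.setdefault((slot, taxid), lineage)
        return rep

    def fraction_incomplete(self) -> float:
        """Fraction of keys whose lineage has at least one unknown slot."""
        if not self.lineage_map:
            return 0.0
        n = sum(1 for lin in self.lineage_map.values() if lin.n_unknown > 0)
        return n / len(self.lineage_map)


def _resolve_merged_chains(merged: Mapping[int, int]) -> dict[int, int]:
    resolved: dict[int, int] = {}
    for start in merged:
        seen = {start}
        current = start
        while current in merged:
            current = merged[current]
            if current in seen:
                raise TaxonomyError(f"cyclic merged-taxID chain through {start}")
            seen.add(current)
        if current != start:
            resolved[start] = current
    return resolved


def build_reference_tree(
    raw: RawTaxonomy,
    merged_records: Mapping[int, int] | None = None,
    unknown_id: int = UNKNOWN_ID,
) -> TaxonomyTree:
    """Construct the pruned seven-rank reference tree.

    Each species node and each of its sub-species descendants becomes a
    key; the value lineage is assembled by walking ancestors and keeping
    the seven canonical ranks ("domain" counts as superkingdom).  A key is
    dropped when species or superkingdom is missing or when more than
    three ranks are missing; otherwise missing slots get ``unknown_id``.
    """
    if unknown_id in raw.nodes:
        raise TaxonomyError(f"unknown sentinel {unknown_id} collides with a real taxID")
    merged = _resolve_merged_chains(merged_records or {})

    species_lineage: dict[int, Lineage | None] = {}

    def lineage_for_species(species_id: int) -> Lineage | None:
        if species_id in species_lineage:
            return species_lineage[species_id]
        found: dict[str, int] = {}
        current = species_id
        seen: set[int] = set()
        while True:
            if current in seen:
                raise TaxonomyError(f"cyclic parent links at taxID {current}")
            seen.add(current)
            parent, rank = raw.nodes[current]
            if rank in RANKS and rank not in found:
                found[rank] = current
            if parent == current or parent not in raw.nodes:
                break
            current = parent
        lineage: Lineage | None
        if "species" not in found or "superkingdom" not in found:
            lineage = None
        elif sum(1 for r in RANKS if r not in found) > 3:
            lineage = None
        else:
            slots = tuple(found.get(r, unknown_id) for r in LINEAGE_RANKS)
            lineage = Lineage(slots, unknown_id)
        species_lineage[species_id] = lineage
        return lineage

    def nearest_species(taxid: int) -> int | None:
        current = taxid
        seen: set[int] = set()
        while True:
            if current in seen:
                raise TaxonomyError(f"cyclic parent links at taxID {current}")
            seen.add(current)
            parent, rank = raw.nodes[current]
            if rank == "species":
                return current
            if parent == current or parent not in raw.nodes:
                return None
            current = parent

    lineage_map: dict[int, Lineage] = {}
    for taxid in raw.nodes:
        species_id = nearest_species(taxid)
        if species_id is None:
            continue
        lineage = lineage_for_species(species_id)
        if lineage is not None:
            lineage_map[taxid] = lineage

    return TaxonomyTree(lineage_map, dict(raw.names), merged, unknown_id)


def lineage_of(tree: TaxonomyTree, taxid: int) -> Lineage:
    """Lineage of a key (species, subspecies, or obsolete alias of either)."""
    return tree.lineage_of(taxid)


# ---------------------------------------------------------------------------
# Profile translation
# ---------------------------------------------------------------------------

@dataclass
class TranslationReport:
    """Unresolvable taxIDs dropped during translation, with their mass."""

    sample_id: str
    dropped: list[tuple[str, int, float]] = field(default_factory=list)

    @property
    def dropped_mass(self) -> float:
        return sum(ab for _, _, ab in self.dropped)

    def __bool__(self) -> bool:
        return bool(self.dropped)


def translate_profile(
    profile: Profile, tree: TaxonomyTree
) -> tuple[Profile, TranslationReport]:
    """Map a profile's taxIDs onto the reference tree.

    Applies subspecies collapse, obsolete-ID replacement and collision
    summation; taxIDs resolvable neither through the tree nor the merged
    table are dropped and listed in the report.  Total output abundance is
    the input total minus the reported dropped mass.
    """
    report = TranslationReport(profile.sample_id)
    out: dict[str, dict[int, float]] = {}
    for rank, taxa in profile.abundances.items():
        translated: dict[int, float] = {}
        for taxid, ab in taxa.items():
            current = tree.resolve(taxid)
            if rank == "species":
                lineage = tree.lineage_map.get(current)
                if lineage is None:
                    report.dropped.append((rank, taxid, ab))
                    continue
                current = lineage.species  # collapses subspecies keys
            elif current != tree.unknown_id and current not in tree.rank_members(rank):
                report.dropped.append((rank, taxid, ab))
                continue
            translated[current] = translated.get(current, 0.0) + ab
        out[rank] = translated
    normalized = profile.normalized and not report.dropped
    return Profile(profile.sample_id, out, normalized), report


# ---------------------------------------------------------------------------
# Lineage-table serialisation
# ---------------------------------------------------------------------------

_TABLE_HEADER = ("taxid",) + LINEAGE_RANKS


def serialize_tree(tree: TaxonomyTree) -> str:
    """Write the lineage map as an 8-column TSV (key + 7 slots, leaf->root)."""
    lines = ["\t".join(_TABLE_HEADER)]
    for taxid in sorted(tree.lineage_map):
        slots = tree.lineage_map[taxid].slots
        row = [str(taxid)] + [
            UNKNOWN_TOKEN if s == tree.unknown_id else str(s) for s in slots
        ]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def deserialize_tree(text: str, unknown_id: int = UNKNOWN_ID) -> TaxonomyTree:
    """Read a lineage table written by :func:`serialize_tree`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != list(_TABLE_HEADER):
        raise TaxonomyError("lineage table: missing or malformed header row")
    lineage_map: dict[int, Lineage] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(_TABLE_HEADER):
            raise TaxonomyError(
                f"lineage table line {lineno}: expected {len(_TABLE_HEADER)} columns"
            )
        try:
            key = int(fields[0])
            slots = tuple(
                unknown_id if f == UNKNOWN_TOKEN else int(f) for f in fields[1:]
            )
        except ValueError as exc:
            raise TaxonomyError(f"lineage table line {lineno}: bad value") from exc
        lineage_map[key] = Lineage(slots, unknown_id)
    return TaxonomyTree(lineage_map, unknown_id=unknown_id)
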