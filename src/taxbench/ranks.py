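"""Canonical seven-rank vocabulary shared across the toolkit.

Every profile, lineage and tree in taxbench lives on a fixed ladder of
seven taxonomic ranks, superkingdom down to species.  Subspecies and
strains are collapsed onto species, so species is the deepest rank.
"""

from __future__ import annotations

#: Ranks in root-to-leaf order.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Depth of each rank counted in branches from the tree root
#: (superkingdom = 1 ... species = 7).
DEPTH: dict[str, int] = {rank: i + 1 for i, rank in enumerate(RANKS)}

#: Rank-name synonyms normalised on input ("domain" is used
#: interchangeably with "superkingdom" in NCBI-style dumps).
RANK_ALIASES: dict[str, str] = {"domain": "superkingdom"}

MAX_DEPTH = len(RANKS)


def canonical_rank(name: str) -> str:
    """Lower-case a rank token and resolve synonyms; returns the token
    unchanged if it is not one of the seven canonical ranks."""
    token = name.strip().lower()
    return RANK_ALIASES.get(token, token)


def depth_of(rank: str) -> int:
    """Branch count from the root for a canonical rank."""
    return DEPTH[canonical_rank(rank)]
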