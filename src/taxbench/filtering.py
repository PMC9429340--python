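"""Low-abundance species filtering: fixed and Shannon-adaptive thresholds.

Most profilers over-call rare species, so removing predicted species
below an abundance cutoff trades recall for precision.  Besides a fixed
cutoff (1% or 0.1%), a stepwise context-dependent rule picks the cutoff
from the sample's predicted Shannon diversity: diverse samples genuinely
contain many rare species and are filtered less aggressively.

Rule (thresholds as fractions of the community):

    non-gut:  H' in [0, 2.5] -> 1%;  (2.5, 4.5] -> 0.1%;  > 4.5 -> none
    gut:      H' in [0, 2.5] -> 0.1%;  > 2.5 -> none

Band edges belong to the lower band.  Removal is strict (< threshold), so
a species sitting exactly at the cutoff survives.  Samples with Shannon
index below 3 are labelled low-complexity, at or above 3 high-complexity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .metrics import shannon_index
from .profiles import Profile, normalize, project_all
from .ranks import RANKS

if TYPE_CHECKING:  # pragma: no cover
    from .taxonomy import TaxonomyTree

#: Shannon-index cutoff separating low- from high-complexity samples.
COMPLEXITY_THRESHOLD = 3.0


class FilterError(ValueError):
    """Invalid filtering parameters or unfilterable profile."""


@dataclass(frozen=True)
class FilterRule:
    """Ordered (Shannon upper bound, abundance threshold) breakpoints.

    Bounds are inclusive upper edges of each band; the final bound is
    infinite.  Thresholds must not increase with diversity.
    """

    context: str
    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.breakpoints]
        thresholds = [t for _, t in self.breakpoints]
        if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
            raise FilterError("Shannon bounds must be strictly increasing")
        if not math.isinf(bounds[-1]):
            raise FilterError("final band must be unbounded")
        if any(t2 > t1 for t1, t2 in zip(thresholds, thresholds[1:])):
            raise FilterError("thresholds must be non-increasing with diversity")

    def threshold(self, shannon: float) -> float:
        if shannon < 0:
            raise FilterError(f"negative Shannon index {shannon}")
        for bound, thr in self.breakpoints:
            if shannon <= bound:
                return thr
        raise AssertionError("unreachable: final band is unbounded")


NON_GUT_RULE = FilterRule(
    "non_gut", ((2.5, 0.01), (4.5, 0.001), (math.inf, 0.0))
)
GUT_RULE = FilterRule("gut", ((2.5, 0.001), (math.inf, 0.0)))

RULES = {"non_gut": NON_GUT_RULE, "gut": GUT_RULE}


def adaptive_threshold(shannon: float, context: str) -> float:
    """Abundance threshold (fraction) selected by the stepwise rule."""
    try:
        rule = RULES[context]
    except KeyError:
        raise FilterError(f"unknown context {context!r}; expected gut or non_gut")
    return rule.threshold(shannon)


def filter_fixed(
    profile: Profile,
    threshold: float,
    renormalize: bool = True,
    tree: "TaxonomyTree | None" = None,
) -> Profile:
    """Drop species with abundance strictly below ``threshold``.

    With ``renormalize`` the surviving abundances are rescaled to sum to
    one.  If a tree is given, ranks above species are re-projected from
    the filtered species set; otherwise only the species rank is kept.
    An all-filtered profile is returned empty (callers score it as a
    failed sample).
    """
    if not 0.0 <= threshold <= 1.0:
        raise FilterError(f"threshold {threshold} outside [0, 1]")
    surviving = {t: ab for t, ab in profile.species.items() if ab >= threshold}
    out = Profile(profile.sample_id, {"species": surviving}, normalized=False)
    if not surviving:
        return out
    if renormalize:
        out = normalize(out)
    if tree is not None:
        levels = [r for r in profile.ranks() if r in RANKS]
        out = project_all(out, tree, levels or ("species",))
    return out


def filter_adaptive(
    profile: Profile,
    context: str,
    renormalize: bool = True,
    tree: "TaxonomyTree | None" = None,
) -> Profile:
    """Filter with the threshold chosen from the profile's own (predicted,
    pre-filter, species-level) Shannon index."""
    reference = profile if profile.normalized else normalize(profile)
    threshold = adaptive_threshold(shannon_index(reference, "species"), context)
    return filter_fixed(profile, threshold, renormalize=renormalize, tree=tree)


def complexity_label(shannon: float) -> str:
    """"low" below a Shannon index of 3, "high" at or above it."""
    return "low" if shannon < COMPLEXITY_THRESHOLD else "high"
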