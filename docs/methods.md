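# Methods

This note documents the models and procedures taxbench implements, the
choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate about real data.

## Reference taxonomy tree

Profilers ship precomputed reference databases, so the same organism
may be reported under different or obsolete taxIDs. All evaluation
therefore happens on a single frozen seven-rank tree (superkingdom,
phylum, class, order, family, genus, species; "domain" is accepted as a
synonym of superkingdom) built from NCBI-style `nodes.dmp`/`names.dmp`
dumps. The tree is a dictionary keyed by species *and* subspecies
taxIDs; the value is the seven-slot taxID lineage, with subspecies keys
sharing their species' lineage, making species the deepest rank.

Pruning: a leaf is dropped if its lineage lacks species or
superkingdom, or if more than three of the seven ranks are missing;
with three or fewer missing, the absent slots are set to an "unknown"
sentinel. The sentinel defaults to −1 (serialized as the token
`unknown`), which cannot collide with real NCBI taxIDs, all positive.

Translation of a foreign profile applies three rules: subspecies
collapse onto their species with abundances summed; obsolete taxIDs are
replaced through a merged-ID table (chains a→b→c are resolved to their
terminal ID at build time, cycles are an error); and colliding
replacements have their abundances summed. A taxID resolvable neither
through the tree nor the merged table is **dropped and reported** with
its abundance rather than raising — an offline artifact cannot defer to
an interactive taxonomy-website lookup, and a dropped-but-logged taxon
keeps the run going while preserving the mass ledger (output total =
input total − reported dropped mass). Translation is idempotent.

## Metrics

Presence/absence at a rank uses strict positivity (abundance > 0); no
epsilon, since profile values are exact rationals of reported
percentages. Precision TP/(TP+FP), recall TP/(TP+FN),
F1 = 2PR/(P+R); every 0/0 is defined as 0, consistent with the
worst-score convention below.

The L1 norm is summed over the **union** of predicted and gold taxa
(absent taxa contribute 0), the only reading under which the maximum of
2 for disjoint normalized profiles holds.

Weighted UniFrac treats every (rank, taxon) pair reachable from a
species lineage as a branch at depth d (superkingdom 1 … species 7)
carrying the fraction of each community descending through it; unknown
lineage slots pool into one sentinel branch per depth. The default
form is

    wU = Σ d_i |a_i − b_i| / Σ d_i (a_i + b_i),

which is exactly 0 for identical profiles and exactly 1 when no branch
is shared. A variant without the depth factor in the numerator is kept
behind `variant="as_printed"`; its maximum on a seven-rank tree is 1/4
for root-disjoint single-species profiles, so it cannot serve as a
[0, 1]-calibrated distance and is not the default. Per-rank reporting
truncates the branch set at the requested rank's depth; the species
level uses the full tree.

Failed samples — missing from a submission, unparsable, empty after
translation or filtering, or raising anywhere during scoring — receive
worst scores: F1 (and precision/recall) 0, L1 norm 2, weighted
UniFrac 1. An invalid *gold standard* aborts the batch instead, since
it invalidates every comparison.

Shannon diversity is H′ = −Σ p ln p over positive abundances (the
standard sign convention; thresholds below are positive magnitudes).
Diversity recovery across samples is the coefficient of determination
1 − SS_res/SS_tot of predicted vs gold H′ (computed with
`sklearn.metrics.r2_score`, SS_tot about the gold values; may be
negative).

## Null model and flooring

Random predictions draw N species uniformly without replacement from
the reference pool, assign i.i.d. uniform(0, 1) values, and normalize.
N is configurable and defaults to the gold standard's species richness
— a neutral choice that makes the null match the sample's scale. The
pool defaults to all species of the tree; the challenge's 1886-species
pool is a configuration value, not a constant.

Each (sample, rank, metric) stratum gets its own distribution (default
10,000 draws; tests and demos scale down) and a threshold at the 95th
percentile *in the favorable direction* — upper tail for F1, lower
tail for the distances. Direction-awareness is required: an upper-tail
threshold on a distance would declare most random predictions
"significant". Percentiles use numpy's linear interpolation between
order statistics, fixed for reproducibility. Scores not strictly
better than their threshold are replaced by it and flagged; flooring
is idempotent and order-preserving among significant scores.

## Rank aggregation

Within each stratum teams are ranked by score (F1 descending,
distances ascending), ties receiving the average of the spanned ranks,
so rank sums are always n(n+1)/2. The weighted sum of ranks uses
weight 1 for F1 and 0.5 for each abundance metric (balancing one binary
metric against two abundance metrics), with per-sample divisors for
replicate groups (e.g. 4 for four sequencing replicates of the same
DNA standard). Missing submissions are converted to worst scores
*before* ranking so the field size is constant; flooring, when nulls
are supplied, also precedes ranking. Extended-benchmark runs reuse the
same weights — the only stated policy — and this is configurable.
Group aggregation takes the arithmetic mean over member samples, with
failed samples contributing their worst scores.

## Abundance filtering

Fixed filtering removes species with abundance **strictly below** the
threshold, so a species at exactly 1% survives a 1% cutoff. Filtered
profiles are renormalized by default (the distance metrics' ranges
assume unit mass); a no-renormalize mode exists for sensitivity
checks. Higher ranks are re-projected from the filtered species set.

The adaptive rule selects the threshold from the **predicted** profile's
species-level Shannon index, computed before filtering: non-gut samples
get 1% / 0.1% / no filtering over H′ bands 0–2.5 / 2.5–4.5 / > 4.5;
gut samples get 0.1% / none over 0–2.5 / > 2.5. Band edges belong to
the lower band (H′ = 2.5 → the more aggressive threshold); the
predicted index is used because it is what a user has without ground
truth, and predicted diversity tracks gold diversity well for most
profilers. Samples are labelled low-complexity below H′ = 3 and
high-complexity at or above it.

## Community simulation

The simulator emulates the benchmark's composition designs, not
sequencing: reads are integer counts, never sequences (no read
simulator, error model or host genome is involved), and gold standards
are exact read proportions by construction. Reads are allocated by
expectation plus largest-remainder rounding rather than multinomial
sampling, so the gold standard equals the design exactly; sampling
noise between design and truth, present in real read simulation, is
deliberately absent.

* Low/medium complexity (< 500 species): species drawn uniformly from
  catalog candidates carrying prior abundances; reads proportional to
  renormalized priors; read budget jittered upward by uniform(0, 10%).
* High complexity: per-species coverage ~ log-normal with log-scale
  mean −1 and sd 1 (parameters of the underlying normal, the CAMI
  convention); expected reads = coverage × genome length / (2 × 150 bp,
  paired-end). Half the target species are uniform draws; the rest are
  filled genus-by-genus from genera holding 4–11 species, taking *all*
  species of each chosen genus until the target is reached or exceeded
  (overshoot kept, per the stopping rule) — a deliberate stress test of
  species-level discrimination among congenerics.
* AT/GC bias: "rich" genomes have the chosen base class above a 0.60
  base-content fraction (the threshold is configurable; the ratio
  phrasing is ambiguous between a 60% fraction and a 0.6 ratio, and the
  fraction reading is implemented). Half the read mass goes to rich
  species, half unbiased, each half again split uniform/congeneric;
  below 500 species the coverages use log-normal(1.2, 0.8).
* Host contamination: a fraction f ~ uniform(0.08, 0.11) of the final
  total, i.e. round(f/(1−f) × species reads) host reads, added once;
  the gold standard excludes them.

Synthetic "pipelines" are perturbed gold standards: dropout with a
false-negative rate, low-abundance log-normal false positives, and
multiplicative log-normal noise, then renormalization. This reproduces
the dominant error modes observed in real profilers (false positives
concentrated at low abundance; abundance noise) but not their
database-driven, phylogenetically structured mistakes — so passing
end-to-end tests demonstrates the correctness of the *evaluation
machinery*, not any claim about particular real profilers.

The toy fixture generator emits an internally consistent random
taxonomy (every phylum with a full class/order/family chain, so
constructed lineages are complete; incomplete-lineage handling is
exercised by dedicated hand-built dumps in the tests) plus a matching
catalog with genome lengths uniform on [1, 10] Mbp, GC on [0.25, 0.75],
and normalized log-normal priors.

## Problem sizes and numerical choices

The test suite runs everything at toy scale, chosen so each suite
completes in seconds while still estimating what it checks: oracle
equivalence for the tree metric on 200 random taxonomies of up to 50
species (agreement < 1e−10); rank-sum conservation on 1,000 random
score tables; log-normal design recovery at 5,000 species (3 standard
errors); and an end-to-end challenge of 10 samples × 3 pipelines with
1,000 null draws per stratum at the species level. Abundance-sum
checks use a 1e−6 tolerance on normalization flags and 1e−9 on mass
conservation; Bioboxes round-trips preserve abundances to 6 decimals
(percentages are written with six decimal places).

## Known limitations

* No read-level simulation; sequencing error, mappability and
  database-content effects are out of scope.
* The real challenge's taxonomy (1.9 M keys) and private submissions
  are not shipped; published team-level wsr values are therefore not
  reproducible here, and the toolkit's correctness is established on
  synthetic data and closed-form cases instead.
* Per-rank weighted UniFrac is defined by truncating the tree at the
  requested depth; other conventions (e.g. computing it once on the
  full tree) would give identical species-level values but different
  phylum/genus strata.
* The adaptive-filter thresholds are fixed empirical constants, not
  learned from data; contexts other than gut/non-gut are not modelled.
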