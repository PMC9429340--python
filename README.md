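# taxbench

A benchmarking toolkit for **taxonomic metagenome profilers** — the
machinery needed to ask, reproducibly, "which profiling pipeline best
recovers the composition of a microbiome sample?"

Shotgun metagenomics classifiers (Kraken/Bracken, CLARK, MetaPhlAn,
mOTU, Kaiju, ...) each report, per sample, the relative abundance of
taxa at ranks from phylum down to species — but against their own,
often mutually inconsistent, reference taxonomies. taxbench provides
the full evaluation stack used in crowdsourced profiler challenges:

* **Taxonomy reconciliation** — a frozen seven-rank reference tree
  (superkingdom, phylum, class, order, family, genus, species) built
  from NCBI-style `nodes.dmp`/`names.dmp` dumps, with pruning of
  incomplete lineages (species/superkingdom required, at most three
  missing ranks filled with an "unknown" sentinel), subspecies collapse,
  and obsolete-taxID remapping.
* **Metrics** — presence/absence scoring via precision, recall and
  F1 = 2PR/(P+R); abundance scoring via the L1 norm
  Σᵢ|xᵢ − xᵢᴳˢ| ∈ [0, 2] over the union of taxa, and a weighted UniFrac
  distance on the taxonomy tree,
  Σᵢ dᵢ|aᵢ − bᵢ| / Σᵢ dᵢ(aᵢ + bᵢ) ∈ [0, 1], where aᵢ, bᵢ are the
  community fractions descending through branch *i* and dᵢ its depth
  from the root. Failed samples receive worst scores (F1 0, L1 2,
  UniFrac 1).
* **Null model** — scores are floored at the 95th percentile (in the
  favorable direction) of 10,000 random-prediction scores, so
  chance-level submissions all weigh the same.
* **Rank aggregation** — per-stratum ranks (average ranks on ties) are
  combined into a weighted sum of ranks (wsr): weight 1 for F1, 0.5 for
  each abundance metric, optional replicate divisors. Lowest wsr wins.
* **Abundance filtering** — fixed cutoffs (1%, 0.1%) and a stepwise
  context-dependent rule driven by the sample's Shannon index
  H′ = −Σ p ln p (non-gut: 1%/0.1%/none over H′ bands 0–2.5/2.5–4.5/>4.5;
  gut: 0.1%/none over 0–2.5/>2.5).
* **Community simulation** — gold standards with the benchmark designs
  (uniform low-complexity, log-normal(−1, 1) coverages with congeneric
  genus fills, AT/GC-biased read mass, 8–11% host contamination) and
  perturbed synthetic "pipelines", so the whole stack is testable with
  no downloads.

Profiles travel in the [Bioboxes profiling
format](https://github.com/bioboxes/rfc/blob/master/data-format/profiling.mkd);
score and rank tables are long-format TSV.

## Worked example

`examples/run_challenge.py` simulates ten communities, has three
synthetic teams of decreasing quality predict them, and runs the full
challenge pipeline (500 null draws):

```
weighted sum of ranks (lower is better):
  careful       71.0
  average      122.0
  careless     167.0

53 of 270 scores were at chance level and floored to their null threshold.
mean species-level scores per team:
metric       F1     L1  wUniFrac
team
average   0.803  0.476     0.152
careful   0.969  0.081     0.026
careless  0.402  1.240     0.384
```

The careful team finds nearly every species (F1 0.97) with almost exact
abundances (L1 0.08 of a possible 2), so it accumulates the best ranks
in almost every (sample, rank, metric) stratum and wins with the lowest
wsr. The other examples cover scoring a single profile, Shannon-adaptive
filtering, the null model, and the community simulator — each prints
the numbers it computes and what they mean.

A thin CLI mirrors the library (`taxbench tree build`, `simulate`,
`score`, `null`, `filter`, `rank`, `run-challenge`, `run-extended`);
see `taxbench --help`.

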