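# Methods

## Consensus model

Each scoring system is treated as an independent nominator with its own
shortlisting rule applied on its own scale; the pipeline never
recomputes the underlying scores. Rules are explicit objects with five
kinds: `ge`, `gt`, `le` (threshold comparisons, strict/non-strict made
explicit per source because published wordings differ between a table
header and the running text), `top_fraction` (rank cut) and
`membership` (presence in a curated list is itself the evidence). The
replication configuration uses `ge 0.9` for the mutation-intolerance
pLi score, `le 0.05` for the network q-value, `gt 0` for the damage
score, `top_fraction 0.10` for the percentile list and `membership` for
the curated database.

Two conventions are deliberate choices where the source material is
silent:

* **`top_fraction` ties** — the cut keeps exactly `floor(f·n)` genes
  after sorting by descending score with a lexicographic symbol
  tie-break. Any other convention (keep-all-ties, random) either makes
  the shortlist size data-dependent or non-deterministic.
* **Absent genes** — a gene missing from a source's table is a
  non-member of that shortlist (vote 0), not missing data. The voting
  therefore needs no imputation model, at the cost of penalizing genes
  a source simply never scored.

The consensus set is `{g : votes(g) ≥ k}` and is inclusive: the genes
found by all n sources are contained in the ≥ k set. Venn region counts
assign each gene to exactly one region (its full membership pattern),
so regions sum to the union; the region count 2^n − 1 caps support at
six sets.

Gene identity is exact string match after upper-casing and trimming.
Alias/history resolution is out of scope: the consumed sources publish
plain symbols, and silent aliasing would make the set arithmetic
irreproducible. A known consequence is that cross-database symbol
drift (e.g. a protein-network database mis-mapping one well-known
synaptic gene to a paralog) is documented behaviour, not repaired.

## Expression stratification

"Average of the median" is the arithmetic mean over tissue-level
median-TPM columns; each brain sub-region counts as one tissue with no
re-weighting — the simplest reading, and the only one that needs no
extra parameters. The label rules at threshold t (default 3 TPM):

| avg_cns | avg_pt | label |
|---|---|---|
| < t | < t | `excluded_low` |
| ≥ t | < t | `cns_specific` |
| any | ≥ t | `cns_pt` |

The boundary is *kept at exactly t* (≥), consistent with describing the
excluded genes as "below t in both groups". The three labels partition
the input by construction, and raising t can only demote a gene
(cns_pt → cns_specific → excluded), never promote it — both properties
are asserted on random matrices in the test suite.

The heatmap exporter bin-codes values with breakpoints
`(3, 9, 31, 99)`, with exactly-zero TPM as its own bin (the
"not expressed" band). The published color legend these defaults mirror
leaves the 3–9 range uncovered; here that range falls into the second
band `(3, 9]`, and the breakpoints are an explicit argument so any
other banding can be supplied. Hierarchical clustering of the original
visualization is not reproduced; rows are emitted in two blocks
(cns_specific, then cns_pt), each sorted by descending CNS mean — a
deterministic order that groups the same genes the dendrogram would.

## Overlap statistics

The over-representation test is the one-sided hypergeometric upper
tail, the same test the standard geneset-overlap tools perform. It is
implemented directly (log-binomials via `gammaln`, accumulated with
`logsumexp`) rather than delegated, and the test suite checks it two
ways: against exhaustive draw enumeration for every feasible instance
with universe ≤ 12 (to 1e−12 relative error) and against exact
rational-arithmetic tail sums and `scipy.stats.hypergeom.sf` on larger
random instances. Odds ratios come from the 2×2 table with +inf on a
zero denominator cell; Jaccard is overlap over union within the
universe.

The background universe is always an explicit argument. ORA web tools
differ silently in their background (whole genome vs reference set),
which changes every p-value; here the replication-shaped study uses
the union of all source-table genes, and any gene of a query or term
outside the universe is dropped and counted in the result rather than
silently kept.

BH-FDR is the step-up procedure computed over *all* terms tested, after
which the report is truncated to the top-K smallest p-values (default
K = 50, the usual reporting cut of phenotype-ontology ORA), ties broken
by term name. DEG overlaps are plain set counts per study
(`|query ∩ (up ∪ down)|`, and per direction) plus the
"dysregulated at least once" union count; DEG lists are consumed as
published, never recomputed.

## Interconnectivity

The pathway matrix holds `|P_i ∩ P_j ∩ G|` with `|P_i ∩ G|` on the
diagonal. "Highly interconnected" is operationalized as the degree at
`min_shared = 1` (count of partner pathways sharing at least one gene
of G); the cut is a parameter because shared-gene-count notation in the
literature is not formally defined. The double-counting identity
Σ_i diagonal(i) = Σ_g (#pathways containing g) is asserted on random
instances.

## Synthetic data

The generators define the study conditions for all tests:

* **Score sources** — planted genes pass each source's rule
  independently with probability `p_hit = 0.9`, background genes with
  `p_bg = 0.05`; the score is then drawn uniformly on the
  corresponding side of the threshold, so for comparison rules the
  realized shortlist *is* the Bernoulli draw and planted recall at
  k of n has the closed form `Σ_{j≥k} C(n,j) p_hit^j (1−p_hit)^{n−j}`
  (0.91854 at k = 4, n = 5). For the rank-based `top_fraction` rule the
  draw only decides the score band while the cut keeps exactly
  `floor(f·n)` genes — a documented approximation, which is why the
  recall validation uses comparison/membership rules throughout.
* **Expression** — per-tissue values are log-normal (non-negative,
  heavy-tailed, the right general shape for median-TPM data) with
  class-specific medians: 5t centrally / t/5 peripherally for
  cns_specific, 5t everywhere for cns_pt, t/5 everywhere for low, with
  log-sd 0.5. Class fractions default to 28.5% / 63% / 8.5%, the split
  a consensus ASD geneset shows after tissue filtering; tissue counts
  default to 13 CNS / 40 peripheral, the GTEx v7 column split. What is
  *not* emulated: tissue–tissue correlation, gene-length/GC effects,
  and correlation between scoring systems (real systems share training
  data). Passing tests therefore certify the pipeline's arithmetic and
  statistics under known truth, not real-data performance.
* **Genesets** — one planted term samples members without replacement
  with weight `enrichment_odds` (default 10) on the planted genes;
  odds = 1 is the null generator used for type-I calibration and
  odds → ∞ the noise-free limit.

One top-level seed expands into per-component streams via
`SeedSequence(seed, spawn_key=(component_index,))` with a fixed,
append-only component table, so adding a generator never perturbs
existing streams; all outputs are byte-deterministic under a fixed
seed, and each run writes a `truth.json` manifest sufficient to score
any downstream stage.

## Pipeline and determinism

The orchestrator validates the whole config up front (collecting every
error, not the first), runs the stages in study order, logs per-stage
counts and writes a JSON manifest. The manifest carries no wall-clock
timestamps — timing goes to the log — so two runs of the same study are
byte-identical, which the acceptance suite asserts. The manifest also
self-checks the partition invariant (excluded + cns_specific + cns_pt
equals the anchored geneset size).

Problem sizes in the shipped validation runs (5000-gene studies,
1000 planted genes for the recall check, 200 ORA replicates, 2000 null
replicates) are chosen so the whole suite runs on a laptop in well
under a minute while keeping Monte-Carlo standard errors small enough
for 3·SE assertions to be meaningful.

## Known limitations

* No network retrieval of any external database; all inputs are local
  TSV/GMT files, and no annotation collections are bundled.
* Symbol matching is purely lexical (see above).
* The one-sided hypergeometric is conservative on discrete support; the
  null calibration test asserts rejection ≤ α + 3·SE, not equality.
* Excel inputs must be exported to TSV/CSV first; GCT 1.2 is accepted
  for expression matrices.
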