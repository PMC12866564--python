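# Methods

This note documents the models, decision rules and numerical choices
behind phyllopan, and what the synthetic-data experiments do and do not
establish about real genome panels.

## Data model

The central object is the orthogroup gene-count matrix: non-negative
integer counts of genes per (isolate, orthogroup), stored internally as
isolates × orthogroups because every statistic groups by isolate.
OrthoFinder emits the transpose; the reader validates the optional
`Total` column against row sums and drops it. Genes OrthoFinder leaves
outside every orthogroup are carried as a per-isolate count (sidecar
TSV, default 0) so that catalogue summaries (`total = assigned +
unassigned`) are conserved. Identifiers are opaque, case-sensitive
strings throughout; no normalization is applied.

eggNOG-mapper annotation files are addressed by column name (`query`,
`COG_category`, `KEGG_ko`) so that both v1 and v2 header layouts parse;
unknown extra columns are ignored. Multi-letter COG strings split into
letter sets; `ko:` prefixes are stripped; `-` is the missing value.
Because real `.annotations` files carry no isolate or orthogroup
mapping, the reader honours optional `isolate` / `orthogroup` columns
(which the simulator emits) and otherwise derives the isolate from the
gene-id prefix before the first underscore, leaving the orthogroup
`UNASSIGNED`.

## Pangenome partition

Soft-core membership is an inclusive threshold on occupancy: an
orthogroup is core iff it is present (count > 0) in at least a fraction
τ of isolates, default τ = 0.95. Occupancy can alternatively be counted
over distinct group labels (`core_unit="group"`) for panels where the
natural unit is the species or genus rather than the isolate; the
default is the isolate.

Combination assignment removes the core first, so core and combination
sets are disjoint categories. Each remaining orthogroup determines the
set C of groups containing it; it is assigned to C only if its
within-group occupancy reaches `strict_fraction` (default 0.95) in
*every* member group, otherwise it is `unclassified`. This strict rule
is what produces the large unclassified pools seen in real panels:
most accessory orthogroups are present in only part of each source's
isolates. `--strict-fraction 0` recovers the plain any-presence rule.
The disjoint-union invariant (core ∪ combinations ∪ unclassified =
all orthogroups, pairwise disjoint) is asserted on every run.

Reported percentages are rounded half-up to one decimal; all internal
computation keeps full precision.

## Statistical kernels

* **Fisher's exact test** computes the hypergeometric pmf over the
  support via log-gamma, and the two-sided p as the sum of
  probabilities of tables (same margins) whose probability does not
  exceed the observed one — the "method of small p-values" used by
  mainstream statistics libraries. A relative tolerance of 1e-7 guards
  float near-ties. The odds ratio is the unconditional sample estimator
  ad/bc (+∞ for bc = 0 with ad > 0, NaN when both vanish); the log odds
  ratio applies a Haldane–Anscombe 0.5 correction only when a zero cell
  occurs, and flags it.
* **Benjamini–Hochberg** is the step-up procedure
  `adj_(i) = min_{j≥i}(p_(j)·m/j)` capped at 1, returned in input
  order; **Bonferroni** is `min(1, p·m)`.
* **Mann–Whitney U** uses `U = #{x_i > y_j} + ½·#ties`. Exact mode
  tabulates the full permutation distribution of U over all
  C(n₁+n₂, n₁) relabelings of the observed (possibly tied) pooled
  values with a dynamic program over doubled midranks — exactly
  equivalent to enumeration (and tested against it) but polynomial in
  n, so `auto` mode uses it up to n₁+n₂ = 20 and falls back to the
  tie-corrected normal approximation with continuity correction beyond.
  Exact mode matters: at 8 vs 8 the normal approximation is badly
  conservative in the far tail (its smallest attainable two-sided p is
  ~9e-4 versus the exact floor 2/12870 ≈ 1.6e-4), which costs real
  sensitivity after BH correction over thousands of orthogroups.
  Two-sided p is `P(|U − μ| ≥ |U_obs − μ|)`; the permutation
  distribution is symmetric about μ = n₁n₂/2 under exchangeability.
* **ROC/AUC**: AUC is the fraction of positive–negative pairs ranked
  correctly with ties counting ½ (U/(n₁n₂)); ROC points move tie
  groups together.

A null-calibration experiment (10,000 simulated 20+20 normal datasets)
keeps the two-sided rejection rate at α = 0.05 inside [0.03, 0.07];
the measured rate is ≈ 0.047-0.049 depending on seed.

## COG enrichment

Counting is at the gene level, matching the convention of comparing
gene counts between a target set and the core: a gene with k category
letters contributes once to each letter; genes with no COG annotation
count only toward the set total (so proportions are relative to all
genes of the set). Expected frequencies come from the soft core's
genes. Two effect summaries are emitted — the deviation
`D = 100·(p_obs/p_core − 1)` and the representation `R = D + 100` —
because published heatmaps alternate between the two conventions
("> 50%" over-representation means D > 50, while in-text values like
"215%" are R). Classification: `over` iff D > 50 and p_adj < α,
`under` iff D < −50 and p_adj < α, `low-support` (taking precedence)
when the category has fewer than `min_gene_support` genes across the
comparison (default 200) — a reporting filter, not a drop. BH is
applied within each target set across its categories by default; a
global scope is available since the right choice depends on how many
sets a study reports together.

## Per-genus differential analysis

Within one genus, each orthogroup's per-isolate gene counts (raw
counts, not presence — copy-number shifts are part of the signal) are
compared between the target source and all others with the
Mann–Whitney test; BH runs across the tested orthogroups. Orthogroups
absent from the genus entirely are excluded before BH to avoid paying
multiplicity for impossible tests (`--test-all` disables this).
Direction is taken from group means. The compact letter display for
group-metric comparisons uses the insert-and-absorb algorithm; the
emitted letters are checked against the pairwise table (groups sharing
a letter are never significantly different) on every call.

## Pathway completeness

Definitions follow KEGG module syntax: space-separated units are
required steps (AND, loosest binding), commas are alternatives (OR),
`+` joins complex subunits (AND, tightest), parentheses group, a
leading `-` marks a unit optional. Optional units are pruned before
scoring rather than scored as free. Scoring is leaf = KO present,
AND = arithmetic mean of children (fraction of required steps
satisfied), OR = maximum over alternatives; a definition that is
entirely optional has no defined score and is reported missing. This
mean/max semantics is a deliberate simplification of graph-weighted
completeness tools: it preserves the ordering of "more complete"
comparisons, which is all the downstream source comparisons use, and
it is monotone — adding a KO never lowers a score (property-tested).
Per-isolate KO sets are the deduplicated union over the isolate's
genes; completeness depends on presence, not copy number. Restriction
mode scores only genes whose orthogroup lies in a supplied set (e.g. a
partition category).

## Classification harness

Labels are binary (1 iff the isolate's source equals the target).
Learners sit behind a registry with a fit/predict contract; the
references are a 100-tree random forest and a linear-kernel SVM from
scikit-learn — the harness (folds, metrics, importance) is what this
package provides, not the learners. Features are raw orthogroup counts
by default, with binary-presence and log1p transforms available, since
count scaling is a modelling choice the data do not force.

Repeated stratified k-fold (default 5 splits × 10 repeats) gives the
within-panel reference accuracy; its SD is reported across all folds.
LOGO-CV holds out each genus once; leakage (train ∩ test ≠ ∅) is
asserted per fold, and AUC is reported missing when a held-out genus is
single-class. Feature importance is model-agnostic permutation
importance: mean test-accuracy drop over 20 within-column shuffles,
deterministic given the seed, ties broken by feature id; constant
features score exactly 0. (Attribution methods that require the
original explanation library are deliberately not reproduced.)

## Synthetic-data generator

The generator emulates the structure of a multi-genus yeast genome
panel and writes the exact dialects the readers parse:

* **Panel**: default 4 genera × 15 isolates (5 leaf, 3 flower, 3 soil,
  2 human, 2 water each) — 60 isolates, leaf most represented, as in
  leaf-focused culture collections.
* **Core** (default 1,200 orthogroups): present in every isolate
  before dropout; per-present-cell counts are 1 + Poisson(μ−1) with
  μ = 2, so presence is guaranteed and the mean matches the baseline.
* **Genus backbones** (800 per genus): confined to one genus, presence
  probability 0.9. Taxonomy is thereby the dominant axis of variation,
  which is what makes cross-genus classifiers overfit in the
  confounded experiments.
* **Shared accessory** (400): random ≥2-genus subsets at presence 0.7.
* **Planted source-enriched orthogroups** (50): baseline Poisson(μ)
  counts plus a deterministic additive shift +λ (default 5) in
  target-source isolates — an "additive count shift" in the literal
  sense, with mean μ+λ. (Drawing target counts from Poisson(μ+λ)
  instead spreads the effect too thin for an 8 vs 8 rank test to reach
  0.9 sensitivity after BH over 2,000 orthogroups; the additive shift
  is the reading under which the recovery experiment has its intended
  operating point.)
* **Source-unique orthogroups** (60 per source): confined to one
  isolation source; the target source's unique orthogroups carry the
  planted COG bias (default category Q at 3× baseline frequency,
  renormalized).
* **Occupancy cap**: every non-core orthogroup is capped strictly
  below τ occupancy by zeroing randomly chosen isolates (non-target
  isolates first for planted orthogroups, so the shift survives).
  Zero-dropout soft-core recovery is therefore exact by construction —
  a calibration property, not a finding.
* **COG letters**: genes are annotated with probability 0.8; letters
  drawn from a uniform baseline over the 23 categories, 15% of
  annotated genes get a second letter.
* **Pathways**: disjoint KO pools per pathway, 3-6 steps of single
  KOs, OR-pairs or `+`-complexes. The first pathway is granted in full
  to target-source isolates and only strictly partially elsewhere, so
  it is 100% complete exactly in the target source.
* **ASV table**: designated core taxa present in every sample;
  non-core taxa capped strictly below the 80% prevalence threshold;
  designated low-abundance taxa kept far below 0.1% mean relative
  abundance in both years.

Everything is driven by one `numpy` generator seeded from the config;
identical seeds give byte-identical files.

**What the generator does not emulate**: phylogenetic covariance
within genera (isolates are exchangeable given genus), gene-family
birth–death dynamics, overdispersion beyond Poisson (no negative
binomial by default), annotation errors, and assembly-quality
artifacts. Recovery results on synthetic data therefore demonstrate
that the decision rules and tests behave as designed under their
stated model — not that real panels meet that model.

## Experiment scales

Desk-scale problem sizes were chosen so the full suite runs in minutes
on one CPU while keeping each experiment's statistical structure:

* differential recovery: 1 genus, 8 leaf vs 8 other isolates, 2,000
  orthogroups (1,100 core + 850 backbone + 50 planted, no
  source-unique orthogroups — those are genuinely source-associated
  and would contaminate the null set), 20 seeds;
* COG recovery: 2 genera × (4 leaf + 4 soil), 150 core + 40
  source-unique orthogroups per source, 50 replicates, with the
  low-support threshold set to 50 genes to match the fixture's gene
  counts (the default 200 is calibrated to full-size panels);
* classification panels: 4 genera × 16 isolates, ~160-310 orthogroup
  features; the separable panel plants a 10-column leaf-only block
  (wide enough that feature-subsampling ensembles see it in every
  tree), the confounded panel plants a 10-column backbone of a genus
  that is 87.5% leaf-derived and makes it the only informative signal.

## Known limitations

* The strict-combination reading of the partition is one defensible
  interpretation of "unique and shared orthogroup" categories with a
  large unplaced remainder; the `--strict-fraction` dial exposes the
  whole family of rules.
* Exact Mann–Whitney beyond n₁+n₂ ≈ 40 becomes memory-heavy in the
  rank-sum DP; `auto` switches to the normal approximation well before
  that.
* Pathway completeness values are comparable within this package but
  are not numerically interchangeable with graph-weighted external
  tools.
* The community module implements decision rules (abundance filter,
  prevalence core, recovery) only; differential abundance and
  ordination belong to dedicated amplicon toolchains.
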