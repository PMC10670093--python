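# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `xtalk`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Catalog harmonization

Raw inputs are `(symbol, compartment, source)` rows restricted to the
three-compartment vocabulary {ER, mitochondria, cytosol} (case-insensitive,
with common synonyms such as "mito", "cytoplasm", "endoplasmic
reticulum"). Aliases are mapped to canonical symbols first; rows sharing a
canonical symbol merge with union semantics over compartments and sources;
rows with out-of-vocabulary compartments are rejected, logged and counted.
Harmonization is idempotent and order-independent (both are tested).

Manual curation steps in typical organelle screens (for example
verification of "organelle specificity" against an expression atlas) have
no published decision rule, so the package replaces them with an explicit,
configurable **primary-compartment policy**. The default,
`source_majority`, assigns the compartment supported by the most sources
and breaks ties by a priority order (mitochondria > ER > cytosol —
mitochondrial annotations are typically the best curated of the three, and
a deterministic total order is required for reproducibility). All
multi-compartment labels are retained alongside the primary. No proteins
are discarded for being multi-localized; they are only logged.

## Interaction graph

Graphs are simple and undirected. Edges with an endpoint outside the
catalog are dropped and counted (closed-world assumption). Edge confidence
is read and carried but ignored downstream: paths are unweighted hop
paths and density is unweighted, because the screen's distance notion is
interaction steps, not interaction strength. Density uses the loopless
normalization `2e / (n(n−1))` (defined as 0 for a single node); k-cores
are computed by iterative pruning (via networkx) and validated against a
subset-enumeration oracle.

## Complex detection (MCODE)

The molecular-complex-detection procedure is implemented from scratch.

**Vertex weighting.** For vertex *v*, take the induced subgraph of its
closed neighborhood `N[v]`, restrict it to vertices with degree ≥
`degree_cutoff` inside it (single pass; the subsequent core computation
prunes any residual sparsity), find the highest k-core of the restriction,
and set `w(v) = k_max × density(highest k-core)`. A vertex whose filtered
neighborhood has no edges weighs 0. This "core-clustering coefficient"
damps the effect of sparsely attached neighbors that a plain clustering
coefficient would count.

**Growth.** Seeds are processed in decreasing weight, ties broken by
(degree, symbol) so the order is total. From an unassigned seed, breadth
first up to `max_depth`, a neighbor is admitted on its first qualifying
encounter if `w ≥ (1 − vwp) · w(seed)`; each vertex is examined at most
once per complex, and vertices already in an earlier complex are never
re-admitted (rejected vertices remain available to later seeds, which
lets a vertex rejected by a foreign seed still join its own community).

**Post-processing.** *Haircut* takes the 2-core of the complex (iterated
degree-1 removal; never disconnects a connected complex). *Fluff* (off by
default) adds boundary neighbors whose closed-neighborhood density exceeds
`fluff_density_threshold`; fluff additions are single-pass (neighbors of
fluffed vertices are not rescanned), may overlap other complexes, and are
reported separately. Complexes need ≥ 2 members and ≥ 1 edge; they are
scored `density × size` and ranked with total tie-breaking (score, size,
lexicographically smallest member).

**Defaults** follow the canonical release: `degree_cutoff=2`, `vwp=0.2`,
`haircut=true`, `fluff=false`, `fluff_density_threshold=0.1`,
`max_depth=100`. All are exposed in the config and CLI.

## Meta differential expression

Each study is a genes × samples matrix on a log2-like additive scale with
case/control labels. The per-gene statistic is the pooled-variance
two-sample *t* (the linear-model contrast for a two-group design) with
`df = n₁ + n₀ − 2` and a two-sided p-value; zero pooled variance is
floored at 1e−12 so exact separation yields an extreme finite statistic.
An optional moderation switch (off by default) shrinks pooled variances
toward their median with 4 prior degrees of freedom — a deliberately
simple stabilizer for very small groups, not a full empirical-Bayes fit.

Across studies, Fisher's combined probability `X² = −2 Σ ln pᵢ` is
referred to the upper tail of χ² with `2k` degrees of freedom, where *k*
counts the studies in which the gene was measured (platforms differ; genes
missing from a study are combined over the rest). Zero p-values are
clamped to 1e−300 with a warning; values outside [0, 1] are rejected. DEG
calling uses strict `p < α` with no multiple-testing correction by
default, matching the screen convention this reproduces; a
Benjamini–Hochberg mode is available and recommended for real analyses.
Clusters containing at least `min_hits` DEGs (default 1) are flagged as
disease-associated.

The combined-probability reading of the cross-study test is a deliberate
interpretation: combining per-gene p-values across the three studies is
the only construction consistent with per-study linear-model statistics
followed by a single "Fisher" p-value per gene. Sign concordance across
studies is not enforced.

## Linker scoring

Within the selected tri-compartment cluster's induced subgraph, every
cytosolic member *c* receives
`bridge(c) = min over (e ∈ ER, m ∈ mito) [d(e, c) + d(c, m)]`
computed by two multi-source BFS sweeps. This min-sum statistic is the
weakest faithful formalization of "the shortest path connecting the two
organelles through a cytosolic protein": it does not require *c* to lie on
a single ER→mito geodesic, only to be simultaneously close to both
organelles. Ties are broken by (more minimal witness paths, higher degree,
symbol), encoding "crucial" as path multiplicity; unreachable cytosolic
members rank last with infinite bridge. Witness paths are explicit simple
concatenations ER→…→c→…→m of minimal total length, enumerated
deterministically (capped at 10⁴, which only matters on degenerate tie
structures and is logged). Paths are confined to the cluster subgraph —
the relay claim is about the module, not the whole network. Multi-localized
proteins contribute under their primary compartment.

Alternatives such as betweenness centrality or current-flow measures are
intentionally absent from the default path.

## Validation statistics

ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the
control-group mean ΔCt (calibrator choice exposed); fold = `2^−ΔΔCt`.
No amplification-efficiency correction is applied. One-way ANOVA uses the
classical sum-of-squares decomposition with an upper-tail F p-value;
degenerate zero within-group variance with unequal means reports p at the
1e−300 floor with a flag. Tukey HSD is backed by the studentized-range
distribution (`scipy.stats.tukey_hsd`, Tukey–Kramer for unequal n) and is
cross-checked against statsmodels in the tests.

## Synthetic data: what it emulates, and what it does not

All generators draw from one explicit integer seed through
`numpy.random.SeedSequence` spawns; identical calls are byte-identical.

* **Catalogs** use largest-remainder rounding so compartment counts are
  exact; the default proportions reproduce a 243/1399/1299 three-way split
  of 2941 proteins. A `multilocal_rate` fraction (rounded to an exact
  count) receives a second compartment drawn uniformly from the other two.
* **Networks** are planted-partition graphs: within each planted complex,
  edges appear with `p_in`; elsewhere with `p_bg`, **except that no
  background edge joins two planted members**. This keeps within-complex
  density exactly `p_in` and keeps the planted communities well-defined:
  a random bridge between two planted complexes would merge them into one
  true community (and any density-based clustering would legitimately
  return the union), making recovery metrics ill-posed.
* **The relay motif** is four nodes — cytosol `c` adjacent to
  mitochondrial `m₁, m₂`, each adjacent to one ER node `e` — injected into
  a planted complex; any direct `c`–ER edge is removed so the planted
  linker's bridge is exactly 3 (2 hops to the ER, 1 to a mitochondrion).
* **Expression** is additive Gaussian on a log2-like scale: baselines
  `μ_g ~ N(8, 2)` shared across studies, noise `N(0, σ)`, and a planted
  DEG set (shared across studies) shifted by `δ` in cases, so `δ` *is* the
  log2 fold change. Group sizes accept per-study (case, control) pairs, so
  unbalanced designs (e.g. three studies totalling 277 samples) are
  expressible; within the packaged fixture the 114/94/69 study sizes are
  split 57/57, 47/47 and 35/34 — the original group compositions are not
  published, so equal-as-possible splits are used.
* **Ct tables** hold the reference gene constant in expectation and shift
  the target by `−log2(fold)` per group, with Gaussian noise on both Ct
  columns.

Not emulated: interaction confidence-score distributions, probe-level
microarray artifacts (normalization, batch, probe-to-gene collapsing),
cross-study heterogeneity of effect sizes, and correlated expression
between genes. Passing recovery tests therefore demonstrates correctness
of the algorithms under the stated generative model, not robustness to
real-data artifacts.

## The packaged end-to-end fixture

`fixtures.reference_screen_fixture` reproduces the *structure* of a published
organelle screen: 2941 proteins; three planted complexes of 84, 66 and 44
members over a sparse 150-node background, all mutually disconnected so
complex boundaries are exact; expression with a 15% DEG set at δ = 1.5,
σ = 1; and a 3 × 25-sample Ct table with planted folds 0.5 / 0.9 / 1.0.

Two constructions deserve justification:

* The two large complexes are **circulant graphs** (every member adjacent
  to its 41, resp. 28, nearest ring neighbors: 3444 and 1848 internal
  edges) and the third complex has a **complete 37-member mitochondrial
  core**. Vertex-transitive cores give every member an identical MCODE
  weight, so seeded growth recovers each complex exactly and the fixture's
  expected structure is deterministic across seeds. Erdős–Rényi cores at
  the same densities occasionally fragment under the 20% weight tolerance
  (degree fluctuations push some members below the admission threshold),
  which is a property of the detection algorithm worth testing — but on
  the *recovery* benchmark, not inside the structural reference fixture.
* The fixture's recommended clustering parameters enable **fluff**
  (`fixtures.REFERENCE_SCREEN_MCODE`). The relay linker and the ER endpoint
  attach to the complex through only two edges each; they are exactly the
  dense-neighborhood boundary vertices the fluff stage exists to recover,
  and without it the growth stage (correctly) leaves them outside the
  dense core. The two mitochondrial intermediates are wired as hubs of the
  core so they are always carried by growth itself.

The planted-linker recovery fixture scales the 44-member composition down
to 25 nodes (18 mitochondrial / 6 cytosolic / 1 ER) with sparse internal
background (`p = 0.02`) plus the motif.

## Numerical and determinism choices

Variance floor 1e−12 (t statistics); p-value clamp floor 1e−300 (Fisher,
degenerate ANOVA); witness enumeration cap 10⁴ paths. All orderings
(seeds, complex ranks, linker ranks, witness lists) are total, so every
stage is deterministic given its inputs. Pipeline outputs contain no
timestamps, and the manifest records config, seed and SHA-256 of every
output, so identical configs reproduce byte-identical runs; for that
reason the output directory is taken from the config rather than
timestamped.

## Problem sizes used in tests and the acceptance script

Oracle equivalence runs exhaustively on all 996 connected graphs with at
most 7 vertices (subset-enumeration brute force) and on 100 random
25-node tri-labeled graphs (Floyd–Warshall triple enumeration).
Planted-complex recovery uses two size-20 complexes at `p_in = 0.9` in a
200-node `p_bg = 0.02` background over 10 seeds; linker recovery uses 20
regenerations of the 25-node fixture. Calibration and power use 2000
genes × 3 studies × 10 samples/group. These sizes give stable Monte-Carlo
estimates (binomial SE ≈ 0.005 on the null DEG rate) while keeping the
full suite under half a minute on one CPU.

## Known limitations

* The MCODE implementation is the undirected, non-overlapping variant;
  fluff is the only source of overlap and is reported, not silently
  merged.
* Fisher's method assumes independent studies and ignores effect
  direction; two studies with strong opposite effects combine to a small
  p-value.
* Unadjusted per-gene thresholds at α = 0.05 over thousands of genes
  imply a substantial false-discovery load by construction; the BH mode
  exists for real analyses.
* The bridge-length statistic treats all interactions equally; confidence
  weighting and flow-based centralities are out of scope.
* Group demographic confounding, amplification efficiency, and any
  docking/simulation stages of the original screen are out of scope.
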