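# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate
about real data.

## Ratio processing

The unit of measurement is a two-color focused-array hybridization: a Cy3
control sample and a Cy5 test sample co-hybridized on one chip carrying
~228 immune-related genes, each as four replicate spots, with five
housekeeping genes (α-tubulin, β₂-microglobulin, β-actin, GAPDH,
transferrin receptor) as internal controls.

**Background correction.** Each channel is corrected as
`max(fg − bg, floor)` with `floor` = 1 intensity unit. Scanner software
conventions vary here; the floor guarantees strictly positive downstream
ratios, which the log transforms and the normalization both require. The
floor only binds when background exceeds foreground, i.e. for spots that
are effectively absent.

**Replicate aggregation.** The per-gene value of a chip is the **median**
of the four replicate spot ratios (configurable to the mean). The
per-array summary of replicate spots is ambiguous between median and mean
in common practice; the median is chosen as the default because it is
robust to a single aberrant spot out of four, which is the dominant
replicate-level failure mode. Spots flagged `bad` are excluded before
aggregation; a gene whose spots are all flagged propagates as missing
(NaN), is excluded from filtering and clustering, and is counted in the run
log.

**Normalization.** All ratios on a chip are divided by the chip's ratio
for a housekeeping reference gene, β-actin (ACTB) by default and
configurable to any housekeeping-flagged gene (β₂-microglobulin is the
common alternative). After normalization the reference row is exactly 1.0
in every condition, and the operation is idempotent — both are enforced,
not approximate, properties.

**Ratio semantics.** The default chip design hybridizes each treated
sample against same-time vehicle, so the matrix holds test:vehicle ratios;
treatment:LPS ratios — the quantity the hit tables and kinetic profiles
use — are then the ratio of ratios
(compound+LPS : vehicle)/(LPS : vehicle). A `lps_ref` configuration
supports chip designs whose control channel is the LPS-only sample
directly.

**Differential rule.** A gene is called changed iff its linear ratio
satisfies r ≥ T or r ≤ 1/T with T = 3, comparisons inclusive at full float
precision (a printed value of 0.33 passes the down rule since
0.33 ≤ 1/3). Under the `any_treatment` rule one passing treatment
suffices; under `all_treatments` every selected treatment must pass and a
missing value fails the gene. Hit tables are sorted by functional category
(cytokines, chemotaxis/migration, inflammatory response, other) then Entrez
gene id, matching the layout of the printed tables.

## Kinetic regulation modes

Gene responses are classified on the log₂ treatment:LPS profile using
three anchor times: early 0.5 h, delayed 2 h, up 4 h (all configurable; the
default grid is the five assay times 0.5, 2, 4, 12, 48 h). A direction
call at an anchor uses a symmetric threshold θ: DOWN iff log₂ r ≤ −θ, UP
iff ≥ +θ, NONE otherwise. Default θ = log₂ 1.5 ≈ 0.585: large enough to
sit several standard deviations above replicate-level noise at the
simulator's default σ, far below the threefold hit threshold. The class
definitions, applied in precedence order so the classes partition the
genes:

1. **early down → up**: DOWN at 0.5 h and UP at 4 h;
2. **delayed down → up**: not DOWN at 0.5 h, DOWN at 2 h, UP at 4 h;
3. **early none → up**: NONE at 0.5 h and UP at 4 h;
4. **other**: everything else.

A profile that is NONE early, DOWN delayed and UP at 4 h satisfies both a
loose reading of (3) and the definition of (2); precedence gives it to
delayed-down, keeping the groups disjoint. The LPS-only (vs vehicle)
profile additionally tags each gene Up or Down: by the first time point's
call if it clears θ, otherwise by the sign of the largest-magnitude
excursion anywhere in the profile (an all-zero profile defaults to Up).

**Concordance** between treatments is, for each mode group of a reference
treatment, the percentage of that group's genes assigned the same mode by
the other treatment, rounded half-up to one decimal (so 17 of 23 reports
as 73.9). Self-concordance of any non-empty group is exactly 100.0; empty
groups report n_group = 0 with an undefined (NaN) percentage and a flag
rather than a fabricated zero.

## UPGMA clustering

Distances between profiles are Euclidean distance on log₂ ratios
(default) or 1 − Pearson correlation of log₂ ratios; the metric is a free
choice in this kind of analysis and Euclidean-on-log₂ is taken as default
because the profiles being clustered are log₂ ratio curves. The
agglomeration is the classic unweighted-average scheme: repeatedly merge
the closest pair; the distance from the merged cluster to any other is the
size-weighted mean of member distances. Ties on the minimum distance are
broken toward the pair whose smallest original leaf indices are
lexicographically least — an arbitrary but deterministic rule.
Implementation is the direct O(n³) algorithm (the inputs here are a few
hundred items at most); scipy's average linkage serves as an independent
cross-check in the tests, never as the implementation. Leaf order places
the child containing the smaller original index on the left at every
merge; Newick export uses the ultrametric convention (node height = half
the merge distance), so leaf-to-leaf path lengths in the exported tree
equal cophenetic distances.

## Key-node search

The search runs on a directed multigraph whose edges carry a sign
(`activate`/`inhibit`); parallel edges with opposite signs are legitimate
and kept, identical duplicates are collapsed, and self-loops are dropped
with a warning. For each candidate node, breadth-first search yields
shortest directed depths truncated at L edges (default L = 4 — four
hierarchical levels of regulation, inclusive). Coverage of a query gene
set is the fraction reachable within L; candidates are ranked by coverage
(desc), then max depth (asc), then mean depth (asc), then node id. A query
gene may itself be a candidate, but self-coverage requires a directed
cycle of length ≥ 1 — depth-0 self-cover is disallowed.

Sign consistency is computed by a dynamic program over BFS layers that
tracks, for every covered gene, the set of net signs achievable along
*shortest* paths (product rule: odd inhibitions ⇒ net inhibition). A gene
is consistent if any of its shortest paths predicts its observed direction
under an assumed regulator state; the reported value takes the better of
the two states (active-up / active-down). Consistency annotates the
ranking and never filters, since real curated networks mix signs and the
observed directions reflect more than one mechanism. Genes covered only
through a cycle back to the candidate itself carry no layered sign
information and are excluded from the consistency denominator.

## Synthetic data: what it emulates, what it does not

**Array simulator.** Spot intensities are generated as
`background + base × abundance × noise` (control channel) and
`background + base × abundance × e × noise` (test channel), with gene
abundances log-uniform over (0.05, 20) × base so background flooring is
exercised at the low end, and independent per-channel log-normal noise of
standard deviation σ (natural-log space, default 0.1). The recorded bg
columns equal the constant background, so subtraction recovers the signal
and a noiseless run reproduces planted effects exactly through the whole
chain — the round-trip test. Housekeeping genes always carry e = 1.

What this does **not** model: spatial artifacts, dye bias (no dye-swap),
saturation, correlated replicate noise within a print-tip group, and
pixel-level statistics inside a spot. Passing recovery tests therefore
demonstrate correctness of the processing chain under a clean error model,
not robustness to every real-world artifact; the fold-change rule itself
has no error control beyond the threshold.

**Network simulator.** A planted regulator is wired to each of 10 query
genes through fresh intermediate nodes at depths sampled in [1, L], with
the deepest wiring forced to exactly L: this makes any node upstream of
the regulator overshoot the bound, so the planted node is the unique
full-coverage candidate by construction. Distractors are wired to strict
subsets (7 of 10 by default). Filler edges are drawn among background
nodes and from query genes downstream only, so they cannot create
accidental full-coverage competitors. Query directions are the net sign of
each planted chain, making the planted node's sign consistency 1.0 — a
positive control, not a claim about curated databases.

**Fixtures.** The three table fixtures transcribe the printed hit tables
verbatim (45, 16 and 30 rows; every row passes its table's threshold rule
for at least one triggering treatment). The five network fixtures are
constructed synthetic stand-ins (labelled `synthetic` in their filenames):
plausible canonical topologies in which the named regulator (ERK1/2,
Rad23A, E6-AP, Lck) is the unique common denominator of the corresponding
gene set within four levels. They support topology-level tests only, never
numeric claims.

## Problem sizes and numerical choices

- The filter-recovery study uses 50 simulated experiments of a two-chip
  design (LPS and one co-treatment at 0.5 h, 228 genes × 4 spots), 20
  planted genes at fold 4 or 0.25, σ = 0.1; sensitivity and
  false-discovery proportion are pooled over the 1000 planted gene-slots.
  This size gives ~±0.7% standard error on the pooled sensitivity while
  keeping a full run in seconds.
- UPGMA is cross-checked on 200 random matrices with n ≤ 8 leaves
  (continuous distances — ties occur with probability zero) at 1e-9
  tolerance on merge heights and cophenetic matrices.
- Key-node recovery uses 100 networks of ~200 nodes. Coverage
  monotonicity in L is asserted on every instance.
- Percent rounding is decimal half-up (not banker's rounding) to one
  decimal, matching how such percentages are conventionally printed.
- All simulators are fully determined by their integer seed; identical
  seeds produce byte-identical files.

## Known limitations

- The threefold rule is a fixed effect-size cutoff with no multiplicity
  control; sensitivity/FDR claims hold under the simulator's noise model
  only.
- Mode classification reads three anchor times only; structure between
  anchors (e.g. transient spikes at 12 h) lands in "other".
- The key-node search treats the network as ground truth; coverage is
  purely topological and depth-bounded, and sign consistency considers
  shortest paths only.
- With a single-gene normalization reference, noise in the reference gene
  propagates to every ratio on the chip; a pooled multi-gene reference
  would be more stable but is not the convention this design follows.
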