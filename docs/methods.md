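# Methods

## Age scale

Gene ages live on an ordered scale of 11 clade strata: Prokaryota (1),
early Eukaryota (2), Viridiplantae (3), Unikonta (4), Opisthokonta (5),
Metazoa (6), Radiata (7), Bilateria (8), Chordata (9), Vertebrata (10),
Mammalia (11); short labels Pr, E, V, U, O, M, R, B, Ch, Vr, Ma.  Lower
rank means more ancient.  All age arithmetic — comparisons, enrichment,
PTM "jump" distances — runs on these integer ranks, and the full scale
is always used: Radiata (rank 7) counts as a step even in data sets
where no gene is dated to it, so distances are stable across inputs.
Labels are exact tokens, matched case-insensitively ("V" is
Viridiplantae, "Vr" Vertebrata).

## Phylogenetic profiles

A profile cell (gene, species) is 1 iff at least one bidirectional
ortholog hit with confidence score ≥ `min_score` exists.  The default
`min_score` is 0.05, the conventional confidence floor of
pairwise-ortholog runs; raising the threshold can only remove
presences (tested as a monotonicity property).  The seed organism's
column is always 1 for its own genes.  The original search-engine
parameters (in-paralog confidence, overlap and coverage cutoffs,
scoring matrices) belong to the upstream orthology run and are carried
as provenance only, never recomputed.

**Transitive extension.**  Distant homologs can be recovered through a
secondary seed organism: if human gene *g* has a bidirectional hit
*g′* in, say, budding yeast, and *g′* has a bidirectional hit in a
species where *g* itself was missed, that cell becomes 1 with
`transitive` provenance.  A link whose anchor (*g* present in the seed
organism) is missing is ignored with a warning.  The operation never
removes presences and is idempotent.

**Isolated hits.**  A presence is flagged `isolated` when its age
group holds at most `max_group_support` (default 1) carrier species
for that gene and the nearest other stratum with any presence is at
least `min_gap` (default 2) ranks away.  This targets the
single-bacterium-then-animals pattern that usually indicates
contamination, annotation error or horizontal transfer, without
flagging ordinary patchy presence in adjacent strata.  Flags are
advisory: the matrix is never altered, and only the oldest-hit age
assignment consumes them (below).

**Clustering.**  Gene rows are clustered by unweighted average linkage
(UPGMA) on Euclidean distances between 0/1 vectors.  The
agglomeration is written out by hand rather than delegated, because
binary data produce frequent distance ties and we require a fixed
tie-break — merge the pair whose smallest original row index is lowest
— to make the leaf order bit-reproducible.  On tie-free continuous
data the merge heights match `scipy.cluster.hierarchy.linkage`
exactly; the O(n³) cost is irrelevant at the ~10²-gene scale this
package targets.

**Loss detection.**  For chosen target species (typically model
organisms), a zero cell is reported as a candidate loss iff the gene is
present in at least one species of a strictly older stratum — the gene
predates the target's stratum, so absence there is loss, not late
birth.  Absence in a draft genome is treated identically in the matrix
but the record carries a "draft genome" note, since confident loss
claims need complete assemblies.

## Gene ages

**Oldest hit.**  The age is the rank of the most ancient stratum with
a presence.  With `discount_isolated` on, a minimum supported only by
isolated-flagged cells is skipped in favour of the next-oldest solid
stratum, and the result is flagged `discounted_isolated_hit`.

**Dollo parsimony.**  One gain, on the branch into the MRCA of all
carriers; inside that clade a node is ancestrally present iff its
subtree retains a carrier, and each maximal carrier-free subtree costs
one loss on its stem.  This labelling is the unique minimum-loss
single-gain reconstruction (verified against exhaustive enumeration).
Cost is the number of losses.

**Wagner parsimony.**  Sankoff bottom-up cost propagation over states
{absent, present} with weights `gain_cost` and `loss_cost` (defaults
1/1 — the conventional symmetric choice; the original analyses do not
state their penalty, and the tests cover other ratios), followed by a
top-down backtrace.  A present root is itself charged as a gain on the
branch into the root, so "primordial" presence is never free.  Ties
prefer the absent state, at the root and at every backtrace decision;
this makes the labelling deterministic (the stated rule "prefer loss
over gain" does not decide event-versus-no-event ties, so absence
preference is used uniformly).  Multifurcations are handled natively
by summing over children.

**Age from a reconstruction.**  The age is the rank of the oldest
stratum with a leaf below the gain branch.  When Wagner parsimony
yields several gains, the gain whose subtree contains the reference
organism (human by default) dates the gene; a gene found in no other
species is dated to the youngest rank (oldest hit) or to a terminal
gain (parsimony).  On trees whose age groups are monophyletic — as in
the packaged fixture tree — the Dollo age provably equals the
oldest-hit age.

**Emergence curves.**  Per stratum (all genes, or one curve per
functional tier / subnetwork, counting multi-membership genes once per
stratum), the curve value at rank r is the fraction of genes with age
≤ r.  Normalization is by stratum size (curves end at 1.0); an
alternative normalization by per-group species counts is available via
`group_sizes` for sensitivity analyses, since "normalized by group
size" is ambiguous between the two readings.

## Enrichment statistics

Per age group, the 2×2 table (input in/not in group × background
in/not in group) feeds a two-sided Fisher exact test, defined as the
sum of hypergeometric probabilities of tables at least as extreme as
observed; any zero margin returns p = 1 by convention.  The
implementation delegates to `scipy.stats.fisher_exact` and is verified
against an independent hypergeometric enumeration over all tables with
margins ≤ 30 (relative tolerance 1e-7).  Bonferroni correction uses m
= number of groups with nonzero background count.  Input genes are
removed from the background before testing, so the samples are
disjoint.  The global comparison is a Mann-Whitney U on the two rank
lists: exact by enumeration over label assignments when n₁+n₂ ≤ 12
(correct under ties, where library "exact" methods are not), normal
approximation with tie correction otherwise.  Ages are in rank units
by default; an optional rank→MYA map changes only the summary
means/medians, never the tests.

## PTM age coupling

The pair table is harmonized before any counting: each gene receives
its modal rank over all its appearances (target and modifier roles),
ties breaking toward the older rank, and every rewritten cell is
logged.  On the packaged DDR table this changes exactly one cell
(CHEK2, printed once as early Eukaryota in its target row but Unikonta
in its six modifier rows) and is what reconciles the table with its
published category totals.  Self-modifications (5 of the 99 pairs) are
excluded from all statistics and from randomization.

**Free null.**  Each replicate permutes the modifier column against
the fixed target column, preserving the pair count and both marginal
age distributions — the minimal null consistent with "shuffling the
interacting pairs".  Replicates that create a self-pair are redrawn
wholesale, keeping the sample space identical to the observed one.
Recorded statistics per replicate: the category triple, the number of
different-age pairs, and small/large jump counts.

**Stratified null.**  Modifiers are permuted only within each observed
category stratum.  Each pair keeps its stratum label — the observed
(same, younger, older) triple is preserved exactly by construction —
while its jump size is recomputed from the reassigned modifier's age.
(Recomputing categories after a within-stratum shuffle could flip
them; keeping the labels is what makes the scheme an exact
conditional null for the jump-size distribution given the category
counts.)  The headline directional statistic is the number of large
jumps among pairs whose modifier predates the target.

A jump is |target rank − modifier rank| over the full 11-rank scale;
jumps < 3 ranks are "small", ≥ 3 "large" (configurable threshold).
Empirical p-values use (r+1)/(n+1) smoothing; two-sided p doubles the
smaller tail, capped at 1.  All randomization flows from
`numpy.random.default_rng(seed)`; results are bit-reproducible given
(seed, replicates).  The default 1,000 replicates reproduce the scale
of the original analysis and give ±1.5% Monte-Carlo error on the
p-values that matter here.

## Synthetic data

The profile generator implements the Dollo generative story: a gene is
born on one branch (drawn so the planted age follows a configurable
distribution over strata) and every branch below loses it
independently with probability `loss_rate`, permanently.  Replaying
the recorded truth events reproduces the matrix bit-exactly, which is
itself a test invariant.  Default study conditions mirror the DDR
analysis: 118 genes on the 12-leaf fixture tree, age mass concentrated
at early Eukaryota (~0.6) with ~0.1 at Prokaryota, and loss rate 0.3
for the noisy-recovery checks.  A Wagner-style generator (independent
per-branch gain/loss from an absent root) exists for multi-gain
recovery tests.  The PTM generator plants age assortativity: with
probability `assortativity` the modifier is drawn from same-age genes,
else uniformly; PTM types default to the observed DDR proportions
(P 0.77, U 0.14, S 0.06, A 0.02, deA 0.01).

What the generators do *not* emulate: sequence-level evolution and
alignment/orthology errors, correlated loss across genes (each history
is independent), draft-genome false absences, and horizontal transfer.
Passing recovery tests therefore demonstrates correctness of the
inference machinery under its own model assumptions, not robustness to
real-data artifacts.

## Numerical and design notes

* Trees may be multifurcating everywhere; no algorithm assumes binary.
* Species columns are ordered by (group rank, species code); display
  order is a presentation concern.
* The per-database enrichment figures published for the DDR depend on
  external ortholog-family databases and are not reproduced; the
  module reproduces the statistical machinery and report schema, which
  is what the structural tests cover.  Likewise the 47-proteome DDR
  profile requires the original proteome downloads; all profile-stage
  tests run on synthetic data with known truth.
* Degenerate inputs: all-zero profile rows raise (no age is defined);
  empty strata are omitted from curves with a warning; a stratum of
  size 1 permutes to itself; a network in which every permutation
  yields a self-pair errors out after a bounded number of redraws.
* Problem sizes in the test suite (500 oracle trees of ≤ 8 leaves,
  118-gene simulated profiles, 1,000-replicate nulls, Fisher sweep to
  margin 30) were chosen so every check is exact or has ≥ 3-sigma
  headroom at desk scale.
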