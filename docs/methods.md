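# Methods

## Scope and data model

The package works entirely on gene *coordinates and labels* — no
sequences.  A `GeneRecord` is a 1-based, inclusive interval on a scaffold
with a strand, an ortholog-group label (e.g. `PDIA2`, `RhoGDIg`) and a
family assignment (`PDI`, `RhoGDI`, `other`).  All quantities downstream
(gaps, interposed counts, TSS distances) are defined on this
representation.  BED-style half-open input is converted at the boundary
(`read_enhancer_table(..., bed=True)`); scaffold names are compared as
exact strings, with an explicit `--strip-chr` opt-in on the CLI rather
than silent normalization.

The packaged human fixture interprets the shared "sense reading" of each
pair as the strand of both genes (Forward → `+`, Reverse → `-`); the
source table states that the two genes of a pair share transcription
direction but does not list per-gene strands, so this mapping is a
documented assumption.  Unknown strands in user input are rejected, not
defaulted, because strand drives both the orientation criterion and TSS
placement.

## Microsynteny detection

A candidate pair is any (PDI-family, RhoGDI-family) gene combination on
one scaffold.  Three criteria apply, all configurable via `PairCriteria`:

| parameter | default | unit | rationale |
|---|---|---|---|
| `max_intergenic_bp` | 500,000 | bp | admits the largest conserved vertebrate gaps (~85–200 kb in the coelacanth) while rejecting same-chromosome placements > 1 Mb apart, which the comparative data treat as disrupted |
| `max_interposed` | 3 | genes | operationalizes "no or very few genes interposed"; a gene counts when its interval midpoint lies strictly between the pair's facing boundaries |
| `require_same_orientation` | true | — | shared transcription direction is part of the conserved arrangement |

The intergenic distance is the plain boundary difference
`max(0, max(starts) − min(ends))`, without a −1 gap correction; at the
two-significant-figure reporting precision both conventions agree on
every published value.  Distances are formatted half-up at two
significant figures (`format_kb`), matching the printed 0.14 / 2.9 / 7.0
kb values; enhancer-block *sizes* instead use one decimal place
(`block_size_kb`), which is the evident convention of the published
block table (a 399 bp block prints as 0.4, not 0.40).

Matching is greedy one-pair-per-gene: candidates are ranked by
(intergenic distance, gene IDs lexicographically) and a gene is consumed
by its first pair.  Detection is a pure function of annotation +
criteria; permuting input rows cannot change the result, and relaxing
any single threshold never removes a reported pair.

## Dollo reconstruction

Cluster presence is a three-state character per species: `present`,
`absent`, `unknown`.  `unknown` is first-class so that unannotated
genomes and missed-ortholog calls do not masquerade as losses.  Under
the single-gain constraint the optimal gain is the edge above the MRCA
of the `present` leaves (enlarging the gain clade can only add absent
leaves requiring losses), and the minimal loss set consists of the
maximal subtrees below the gain containing no `present` leaf and at
least one `absent` leaf — one loss each.  All-`unknown` subtrees are
reconstructed as retaining the cluster (no event is cheaper than one).
Both claims are verified in tests against an exhaustive oracle that
enumerates every gain placement and every loss-edge subset on random
trees of ≤ 8 leaves.

Node ages are annotations supplied with the tree (`date_node`); no
molecular dating or branch-length inference is performed.  `date_node`
returns `None` for unannotated nodes.

## Reconciliation

`reconcile_duplications` implements duplication-only LCA reconciliation.
Polytomies are rejected (with a message instructing resolution) rather
than resolved silently — the trees this operates on are small and
binary, and silent resolution would manufacture duplication counts.  The
duplication set is invariant under child swaps and species relabeling,
and matches an independent path-intersection implementation in tests.
The packaged three-paralog cluster tree yields two duplications at the
vertebrate ancestor under either of the two possible sister resolutions
of the paralog clusters, which is asserted explicitly since the nesting
is read from a figure.

## Disruption auditing

`classify_disruption` decomposes an "absent" matrix cell: both or one
member gene missing (`both_genes_lost` / `one_gene_lost`), both present
on one scaffold but failing the pair criteria
(`unlinked_same_scaffold`), or on different scaffolds
(`unlinked_different_scaffold`).  It is deliberately decoupled from the
presence matrix so absence can be audited into loss vs. rearrangement.

## Enhancer blocks and CAMP calls

Signed TSS distance is measured from the TSS to the nearest block
boundary (0 when the block spans the TSS), negative when the block lies
upstream relative to the gene's own transcription direction.  A pair is
called a CAMP when at least one block is within `window_kb` (default
100, covering every published |TSS distance|, max 74.1 kb) of *both*
genes; the call is monotone in the window.  The published TSS distances
come from an external TSS annotation and are stored as data, not
recomputed — the computed distances from the fixture's coordinate-derived
TSSs agree in sign and rough magnitude but not digit-for-digit, which is
expected and not an error.  One published block row (GH12F014945) prints
a 19.1 kb size against a 666 bp location span; it is flagged
`consistent=False` and excluded from size validation.

## Co-regulation calls and qPCR

`regulation_call` codes a gene `0` / `up` / `down` from a
control-vs-treated matrix: expressed iff the all-sample mean ≥
`min_expr` (default 10, the scale at which the source treats single-digit
read counts as effectively absent); `log2fc = log2((mean_t + c)/(mean_c +
c))` with pseudocount `c = 1`; a call requires `|log2fc| ≥ min_log2fc`
(default 1).  The source states no thresholds, so all three are declared
configuration surfaced in the CLI config.  This is a descriptive coding,
not differential expression: no dispersion model, no multiple-testing
correction.  Note the pseudocount makes `log2fc` scale-dependent; exact
scale invariance holds at `c = 0`.

ΔΔCt fold change is `2^(−(mean ΔCt_treated − mean ΔCt_control))` with
ΔCt = Ct(target) − Ct(housekeeping).  `delta_ct_regression` is ordinary
least squares (scipy) with r² = squared Pearson correlation; zero
variance in x is a hard error.

## Simulator

The generator emulates the inferred history class directly: one cluster
gain on a designated branch, optional en-bloc duplications (both genes,
order, strands and spacing copied; new cluster label and ortholog
groups) on designated descendant branches, and four Poisson processes
with mean rate × branch length per branch — gene loss, segmental
inversion (strand-flipping), single-gene translocation, and background
gene insertion.  Defaults: 20 background genes on 2 scaffolds, 2 kb
genes, 50 kb background spacing, 500 bp within-cluster gap, all
stochastic rates 0 (the zero-noise regime used for exact-recovery
checks); stochastic tests use loss rates 0.05–0.3 per unit branch
length on unit-length branches.

Design specifics:

* Loss is modeled per cluster: each existing cluster accrues its own
  Poisson(rate × length) events, one event deleting one member gene, so
  pair survival to a leaf is exactly `exp(−rate × path length from the
  gain)` — the closed form used as an independent check.  The root
  carries no branch, so no stochastic events accrue above it.
* Translocation relocates a single gene to a distant slot (another
  scaffold or ≥ 5 positions away), producing unlinking-without-loss; new
  clusters never insert inside an existing intact pair.
* Cluster intactness is strict adjacency + equal strand; any event
  breaking it emits an explicit `unlink` event, and `replay_truth`
  propagates gain/duplication/loss/unlink down the tree to produce the
  ground-truth presence matrix.
* One `numpy` generator seeded from `SimParams.seed` drives everything;
  fixed seed ⇒ bit-identical output.

What the simulator does **not** emulate: sequence evolution, realistic
chromosome counts or gene-length/spacing distributions, assembly
fragmentation, annotation error (`unknown` states never arise from the
simulator), regulatory elements, and re-linking of a broken pair by a
later rearrangement (a broken cluster is treated as permanently absent
in the truth matrix; an unlikely reunion would be scored present by
detection but absent by truth).  Passing recovery tests therefore
demonstrates correctness of the inference machinery under the stated
generative model, not robustness to real-genome annotation artifacts.

## Problem sizes and numerical choices

Property tests run on random binary trees of ≤ 8 leaves (where
exhaustive Dollo/reconciliation oracles are tractable: ≤ 2^14 loss
subsets per gain placement), 50-seed simulator round-trips, and 1,000
randomized distance/interposed checks against brute-force base-set
oracles — sizes chosen so the whole suite runs in seconds while the
oracles remain genuinely exhaustive.  Rounding uses decimal half-up
throughout (never banker's rounding), tie-breaks in pair matching are
lexicographic on gene IDs, and degenerate inputs (empty files, zero-gap
book-ended genes, zero-variance regressors, windows of 0 kb) are
defined behaviors covered by tests rather than edge-case crashes.
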