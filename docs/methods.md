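# Methods

This note records the model, the algorithms and the concrete numerical
and design choices behind `dtlrec`, in the order data flows through the
package.

## Conditional clade probabilities

A family's input is a sample of gene-tree topologies with a common leaf
set (branch lengths are discarded; multifurcating trees are rejected
rather than resolved, because conditional splits are defined on binary
nodes and silent resolution would bias the frequencies).  Clades are
identified by leaf-membership bitmasks under the lexicographic ordering
of the family's gene labels; the smaller mask of a split pair is stored
first.  For a rooted sample, every tree contributes one observation to
each clade it contains and to the split at each internal node; the
conditional clade probability q(c₁,c₂|c) is the split count divided by
the clade count.  Duplicate sample lines count with full weight — the
repeat frequency *is* the posterior signal.

Unrooted samples contribute one observation per *directed* clade of
every edge and one root split per edge.  This is equivalent to rooting
each tree uniformly on each of its 2n−3 edges: under uniform rooting a
clade of size k is counted a factor that depends only on k and n, so all
conditional ratios coincide; the equivalence is asserted by an
enumeration test on ≤6-leaf trees.  No pseudo-count or frequency floor
is applied to unobserved splits: a topology outside the amalgamatable
set has probability exactly zero.

## The undated DTL likelihood

Per species branch e the raw rates (δ, τ, λ) ≥ 0 become event
probabilities (p_S, p_D, p_T, p_L) = (1, δ, τ, λ)/(1+δ+τ+λ) — a proper
per-branch distribution with speciation as the reference event.  At a
leaf branch "speciation" means the gene is sampled.

Extinction probabilities solve

    E(e) = p_L + p_D E(e)² + p_T E(e) Ē + [e internal] p_S E(f) E(g)

by synchronous fixed-point iteration from E ≡ 0 (tolerance 1e-13, at
most 10 000 iterations, non-convergence flagged).  Starting at zero
selects the minimal fixed point, the probabilistically meaningful root
of the quadratic.  Ē is the branch average; transfers draw their
recipient uniformly over all N branches, the donor's own branch
included — the simplest convention consistent with an undated model, and
the forward simulator and enumeration oracle use the identical
convention so all three agree term by term.

The clade probability P(c,e) — one lineage entering branch e generates
exactly the observed clade c — is assembled from: the leaf observation
term; per registered split, speciation (internal e), duplication and
transfer terms weighted by q; and the single-survivor chain terms
speciation-loss, duplication-loss and transfer-loss.  Clades are
processed in order of increasing size.  The self-referential terms
(p_D·2E(e) + p_T·Ē)·P(c,e) are resolved analytically by dividing by
1 − b(e); the remaining coupling of a clade's own transfer average P̄(c)
is handled by refresh rounds (at most 4, early exit at relative change
1e-12; with τ = 0 there is no coupling and a single round is exact).  A
divergent solve (b ≥ 1, reachable only at extreme rates) raises rather
than silently continuing.

The family likelihood is Σ_e O(e) P(c_root, e) with uniform origination
O(e) = 1/N, conditioned by default on the family being observed at all
(division by 1 − Ē); both choices are exposed as options.  Conditioning
on survival of a single originating copy (not both root copies) is used
throughout.  The joint likelihood sums per-family logs in sorted
family-id order, so the total is bitwise reproducible regardless of
input order or scheduling.

Two implementations of the recursion exist: a numba-compiled kernel over
flattened clade/split index arrays (the default) and a pure-Python
scalar path that serves as the reference, as the fallback when numba is
unavailable, and as the template for the extended-precision variant.
Tests assert their bitwise-level agreement.

## Precision policy

The per-family watermark is the smallest positive DP cell.  If it drops
below 1e-280 — close enough to the 1e-308 double floor that sums of
products can no longer be trusted — the family is recomputed with
`decimal.Decimal` arithmetic (40 significant digits, exponent range
±10⁹).  Deep multi-copy families are the realistic trigger: a 64-species
family with four gene copies per species at δ = 0.01 has log-likelihood
≈ −899, far outside double range, yet the extended path returns it
exactly where the float path would report zero.  The decimal variant
reuses the scalar recursion verbatim; on instances small enough for both
paths the two agree to better than 1e-6 relative.

## The truncated-enumeration oracle

The DP's correctness anchor is an independent evaluation that groups
reconciled histories by their exact count of non-speciation events
(duplications, transfers and losses, in surviving and extinct
sub-lineages alike) and enumerates all histories with at most K events:
arrays indexed by event count, convolution over independent
sub-lineages, no fixed-point solve and no self-reference division.  The
truncated sum is non-decreasing in K and bounded by the DP value; on
event-sparse instances (≤4 species, ≤4 genes, rates ≤ 0.1, simulated
families redrawn until their true history has ≤1 event) it reaches the
DP value within 5% at K = 3.  The relative truncation error of a cell
whose cheapest history needs k₀ events scales as rate^(4−k₀), which is
why the per-cell comparison uses tiny rates and why the 5% figure
requires event-sparse instances.

## Stochastic backtracking

Sampling retraces the finalized DP table: origination ∝ O(e)·P(c_root,e),
then at each state (c,e) one additive term of the recursion is drawn
proportional to its contribution, recursing into the chosen sub-states.
Chain terms (SL, DL, TL) extend the current gene-tree edge's event list;
bifurcating terms (S, D, T) close the node.  TL events record donor,
recipient and which copy survived; the dead copy's branch carries the
implied loss.  Sampled (topology, origination) frequencies are tested
against the exact posterior, computed by running the DP on the CCP table
restricted to each amalgamatable topology (restriction is exact by
linearity of the recursion in the split weights).

Randomness: one master seed; the per-family stream is
`SeedSequence(master, spawn_key=(family_index,))`, so per-family results
are independent of evaluation order.

Summary conventions: SL counts one speciation on the branch and one loss
on the extinct child; a duplication with a dead copy counts D + L on the
same branch; TL counts on the donor with a loss wherever the dead copy
sat; transfers are tabulated donor → recipient, sorted by sampled count
with ties broken by donor then recipient label.  Ancestral copies on a
branch = number of gene lineages whose event chain visits it.  The
majority-rule consensus uses strict > 50% (clades at exactly one half are
dropped, so polytomies can appear).

## Rate optimization

Projected gradient ascent in log-rate space with an ε = 1e-9 floor keeps
rates positive without a constrained solver.  Gradients are central
finite differences (relative step 1e-6); each iteration takes one
backtracking line search that halves the step until the log-likelihood
strictly improves or the floor (1e-7) is reached, so the accepted trace
is monotone by construction.  Convergence: |ΔlogL| < 1e-4 (default) or
no improving step.  Rates fixed by the caller (e.g. τ ≡ 0) bypass the
log transform and stay at their initial value exactly.  In per-family
mode the product likelihood separates, so families are optimized
independently and exactly — not coordinate-wise across a shared
objective.  Per-species groupings live on the leaves; an internal branch
inherits the grouping of the majority of its descendant species (ties to
the lexicographically smallest grouping id).

## Species-tree search

The search is over rooted topologies; regrafting onto the edge above the
root is part of the move set, so the root is estimated jointly.  Each
round enumerates the SPR neighborhood in a deterministic order (prune
nodes by index, regraft targets by index, duplicates removed by
canonical form) and accepts the *first* strictly improving neighbor
(ΔlogL > 1e-9; ties rejected).  After a round with an acceptance the DTL
rates are re-optimized; the search stops when a full sweep finds no
improvement.  First-improvement with deterministic order gives bounded
work per round and reproducible trajectories.

Starting trees: uniformly random rooted topologies (sequential leaf
insertion with a uniform edge choice, which is exactly uniform over
rooted shapes); a validated user tree; or neighbor joining on average
normalized topological leaf distances pooled over each family's
majority-rule consensus trees, with multi-copy families contributing the
minimum distance over gene-copy pairs per species pair, normalized per
family by its largest entry, and species pairs never co-observed set to
the normalized maximum.  The NJ tree is midpoint-rooted; a midpoint that
lands exactly on a node (leaving a leaf label on the root) is repaired
by re-attaching the label as a basal child before rooting.  This
distance start fills the role of a duplication-aware distance method:
starting-tree quality affects search speed, not the correctness of the
hill climb.  The SPR radius is unlimited up to 12 species and defaults
to 5 beyond.

## Synthetic data

The forward simulator draws one originating lineage on a uniform branch
and applies the generative counterpart of the likelihood model, with the
same transfer convention.  Families with no surviving gene are redrawn,
mirroring the likelihood's survival conditioning — recovery tests are
therefore calibrated against the conditioned likelihood.  A runaway
guard aborts at 10 000 lineages.  Pseudo-posterior samples replicate the
true topology m times and, with probability p per tree, apply a
geometric (mean 1.5) number of random NNI moves; p is the single knob
for gene-tree uncertainty.  What this does *not* emulate: alignment-level
noise, systematically biased posteriors, rate heterogeneity across
branches of the gene tree, or incomplete lineage sorting — so passing
recovery tests demonstrate correctness of the inference machinery under
the model's own assumptions, not robustness to model violation on real
data.

Validation study sizes (chosen once, desk-scale): rate recovery uses 50
families on 20 species with m = 100 and p = 0.1 at (δ, τ, λ) =
(0.2, 0, 0.1); species-tree recovery uses 100 event-free single-copy
families on 6 species with m = 50 and p = 0.1 over 20 seeds; the sampler
check uses 10 000 draws on a 3-species mixture fixture.

## Known limitations

* Transfers are undated: no time-consistency constraint links donor and
  recipient, and recipients are uniform rather than distance-weighted.
* Incomplete lineage sorting is not modelled.
* The likelihood conditions on single-copy survival at origination; the
  alternative (survival in both root copies) is not implemented, only
  the conditioning flag itself is exposed.
* The consensus tree is topology-only (no branch lengths), and species
  trees carry no support values.
* CCP tables serialize to a documented JSON text format; binary formats
  of other implementations are not read.
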