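# Methods

This note documents the models, conventions and numerical choices behind
`chromnest`, module by module, including the choices made where the design
was genuinely open.

## Contact matrices and balancing

A `ContactMatrix` is a symmetric nonnegative bin×bin count matrix with a
fixed bin size (100 kb by default — community scales here sit above TADs).
Matrices are symmetrized on load, the diagonal is zeroed (self-contacts
never enter the modularity sum), and all-zero rows (centromeres, gaps) are
masked out of every computation. Coordinates are 0-based, half-open bin
intervals throughout. Inter-chromosomal contacts are out of scope: their
signal-to-noise is poor and the distance-decay null is intra-chromosomal by
construction.

Balancing finds a diagonal rescaling `W = diag(x) A diag(x)` whose valid
rows each sum to **1**. The unit target (rather than, e.g., the mean row
sum) makes the resolution parameter γ comparable across chromosomes of
different lengths and depths. The solver is the symmetric Sinkhorn
fixed-point iteration `x ← x / sqrt(x ∘ (A x))` with convergence measured as
the maximum row-sum deviation (tolerance 1e-6, cap 3000 iterations — a
warning, not an error, on non-convergence). For symmetric nonnegative
matrices with support this converges to the same scaling as Newton-based
Knight–Ruiz; Newton acceleration is unnecessary at chromosome scale (a few
thousand bins). An optional pre-filter masks bins whose row sum falls below
the 5th percentile of nonzero row sums (standard Hi-C practice protecting
convergence on sparse rows); it is off by default because the synthetic
inputs are dense.

Balancing is scale-invariant (`c·A` gives the same balanced matrix) and
preserves symmetry exactly.

## Community detection

Communities maximize the generalized modularity
`M = (1/2m) Σ_{i≠j} (A_ij − γ P_ij) δ(g_i, g_j)` with the fractal-globule
null `P_ij = 2m · k_i k_j |i−j|^(−α) / Σ_{i'≠j'} k_i' k_j' |i'−j'|^(−α)`,
α = 1 by default. The exponent is configurable (0 recovers a degree-product
null; ≈0.75 suits sub-TAD scales) but 1 matches the contact decay at the
community scales targeted here. The null is normalized so its off-diagonal
total equals the network strength 2m, which forces two exact identities used
as self-checks: M(all-singletons) = 0 and M(one community) = 1 − γ.

The optimizer is Louvain-style greedy maximization operating on the dense
matrix B = A − γP. The FG null breaks the sparse degree-product shortcut of
classic Louvain, but B is additive under community coarsening, so local
moves and the aggregation phase are block sums; dense linear algebra is
comfortable at chromosome scale. Per restart, node sweep order is
randomized; move gains tie-break toward the lowest community id; the best of
`restarts` runs (default 10, since single runs are a random process) is
returned. All randomness derives from `numpy` SeedSequences, so results are
bit-reproducible given a seed; γ-sweeps derive per-γ subseeds
deterministically from the master seed. Because optimization starts from
singletons (M = 0) and only accepts improving moves, returned modularity is
never negative. On planted matrices up to 8 bins, best-of-20 restarts
attains the exhaustive maximum over all set partitions (verified in tests).

The default sweep grid is 16 evenly spaced γ in [0.1, 1.0]. The lower edge
keeps the trivial one-community limit out; the upper edge stops before the
regime where every bin becomes its own community.

## Irreducible domains and folding pathways

Domain borders are the union, over all γ, of positions where adjacent valid
bins differ in community id, plus mask edges (masked stretches always
terminate domains). Domains are the segments between consecutive borders,
1-based and sequential along the chromosome. This makes "never splits over
the given grid" exact by construction; border sets are monotone under grid
refinement, so refining γ can only split domains, never merge them.

Folding pathways connect (γ, community) nodes between adjacent γ levels with
edges weighted by the number of domains making each transition. A perfect
hierarchy yields out-degree 1 everywhere; split-and-reunite motifs
(out-degree ≥ 2) diagnose broken hierarchy. Only the edge list is produced;
circular-tree rendering is out of scope.

## Nestedness

For communities *i*, *j* at different resolutions, sharing S of the n
domains, the null overlap distribution is hypergeometric:
`P(S=k) = C(n,k) C(n−k, d_j−k) C(n−d_j, d_i−k) / (C(n,d_j) C(n,d_i))`,
evaluated with log-factorial (lgamma) arithmetic so that n in the hundreds
poses no overflow or underflow risk. The expected overlap μ is computed as
the explicit first-moment sum (analytically d_i·d_j/n, asserted in tests).

The score `N = (S − μ) / (Ω · min(d_i,d_j))` uses the direction-dependent
normalization: headroom to full nesting when S > μ; headroom to the
feasible minimum when S < μ, which depends on whether the pair could be
disjoint (d_i + d_j ≤ n) or must intersect. p-values are one-tailed exact
tail sums (lower tail for S ≤ μ, including the S = μ tie by convention;
upper tail above), with significance at p ≤ 0.025 per tail.

Degenerate pairs — Ω·min(d) = 0, e.g. a community holding all n domains, so
μ already equals the maximum overlap — carry no nesting information; they
get N = 0 and a `degenerate` flag, and are excluded from model fitting.
`n` is the total domain count of the sweep for empirical tables; for
folding-model tables domains not yet assigned to any superstructure are
excluded (see below). Histogram summaries keep the exact ±1 values out of
the interior bins so the two peaks remain separable from near-extreme
values.

## Folding model

`domain_interaction` scores each domain pair by its mean contact count over
all bin pairs. `agglomerate` greedily merges the strongest pair and replaces
it in the interaction list; the merged structure's interaction with any
other is the size-weighted mean of its constituents' interactions (average
linkage, weights = bin counts — with unit weights this is exactly classic
average-linkage clustering, which serves as the independent oracle in
tests). The linkage rule is a design choice: it is the unique rule
consistent with the "mean contact frequency" definition of the initial
strengths, and the Q = 0 ⇒ N ∈ {−1, +1} structure holds for any monotone
linkage. Ties break toward the lexicographically smallest structure-id
pair, making the tree deterministic.

Rings are top cuts of the dendrogram: ring r (innermost = 1) holds the
structures present after undoing the final r−1 merges, so ring r has exactly
r structures; domains still alone at a ring are *unassigned*. The display
default of 5 rings + domain rim follows the model's usual presentation.

Reshuffling at parameter Q: per ring independently, assigned domains are
paired uniformly at random without replacement; each pair swaps memberships
with probability Q; an odd leftover keeps its membership. Structure sizes
per ring are preserved exactly, and the tree backbone never changes — only
memberships delocalize.

`model_nestedness` scores all cross-ring structure pairs (never same-ring).
For each ring pair, n counts the domains assigned in **at least one** of the
two rings; the union convention guarantees d_i, d_j ≤ n while honouring the
exclusion of membership-free domains.

`fit_q` minimizes the mean two-sample KS distance (over replicates, default
20) between model and empirical nestedness values, both with exact ±1 values
and degenerate records removed; ties on the grid resolve to the smaller Q; a
model replicate with no interior values scores the maximal distance 1.
Recovery experiments use 200-domain trees cut into 8 rings rather than the
display default of 5: more cross-ring pairs mirror an empirical
all-resolution-pairs table and give the KS statistic usable sample sizes.
Under those conditions the fit recovers planted Q ∈ {0.1, 0.3, 0.5, 0.7}
within ±0.1.

## Chromatin-state enrichment

Peaks are counted by their start coordinate only, so a peak crossing a
community border has exactly one owner. The test universe is per-chromosome:
a community with n peaks is compared against K state-X peaks among N total
on the chromosome, expected count nK/N, exact hypergeometric two-sided
p-value computed as twice the smaller tail capped at 1 (simple, conservative
and exactly reproducible). BH correction (statsmodels step-up) runs across
the 15 states within each community by default; chromosome-wide correction
across all community×state tests is available as an option. Communities with
zero peaks are flagged and skipped. Enriched states map to groups A–D;
S8 (insulator) maps to none; a community may carry several groups.

Group-wise nestedness classifies a community pair into class XY when one
side carries X and the other carries Y (either may carry both); within the
class, `intersection` holds pairs where both sides carry both labels and
`difference` the rest, so intersection + difference = union exactly.

Per-community modularity `M_c` sums the B-matrix within one community; the
M = Σ_c M_c decomposition is exact and asserted. Because M_c grows roughly
linearly with community size, group comparisons use M_c divided by the
community's domain count, and report group medians.

## Synthetic data

The generator emulates the statistical features the analysis assumes:
expected counts `E_ij = base_count · |i−j|^(−α) · boost^(shared levels)`
with α = 1, a planted `branching^depth` hierarchy of contiguous blocks,
optional scattering (size-preserving swaps between siblings, producing
non-contiguous communities), optional folding-model reshuffling per level
(planted semi-nestedness), and Poisson counts. Defaults: 256 bins, depth 3,
branching 2, boost 3, base count 100, noise on. The boost default is chosen
so the planted scales unfold across the default γ grid — each level becomes
the optimal partition within γ ∈ [0.1, 1], mirroring a multi-scale sweep on
real data. Poisson (not negative-binomial) noise models shot noise at desk
scale; overdispersion would be a configuration extension. Chromatin tracks
lay peaks left-to-right with geometric lengths (mean 3 bins) and states
drawn from the owning deepest-level branch's weight vector.

What the generator does **not** emulate: polymer-physics constraints,
replicate variability, translocations, copy-number effects, mappability
structure, or the empirical overdispersion of real Hi-C counts. Passing
tests therefore demonstrate correctness of the machinery and detectability
under the planted conditions, not performance guarantees on real data.

## Problem sizes and determinism

Tests and examples run on 64–512-bin matrices, sweeps of 3–16 γ values and
40–200-domain trees; these sizes keep full runs fast on a single CPU while
leaving every statistical check well-powered. All stochastic components
(Louvain restarts, reshuffling, generators, fits) consume seeds derived from
`numpy.random.SeedSequence`, so identical configurations reproduce
byte-identical outputs — asserted end-to-end in the pipeline tests.

## Known limitations

- The Louvain scheme is a local optimizer; only for tiny inputs is global
  optimality verified. Restarts mitigate, not eliminate, run-to-run
  variability at large n.
- Dense O(n²) memory bounds single-chromosome resolution (~25k bins is the
  practical ceiling at 8 GB).
- The KS fit of Q assumes the agglomeration backbone is a good summary of
  the data's hierarchy; at large Q the model distribution saturates, so the
  fit is most informative for Q ≲ 0.5.
- The cooler reader handles single-resolution files only (no multi-cooler
  groups), reading raw counts.
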