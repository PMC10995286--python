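# Methods

## Model overview

`mirsea` treats miRNA function as network proximity: miRNAs similar under
several independent evidence sources (shared disease associations, GO
annotation of targets, target closeness on a PPI network) are assumed to act
together, so a user's miRNA list can be enlarged with its network
neighbourhood before set-level over-representation testing. The pipeline is a
chain of pure functions over labelled symmetric matrices; every stage is
deterministic given its inputs.

## Disease semantic similarity (miRSN-DA)

A disease on a MeSH-like DAG is represented by its ancestor closure. The
contribution of ancestor *t* to disease *d* is computed bottom-up,
D_d(d) = 1 and D_d(t) = max over children t′ of t inside the closure of
Δ·D_d(t′), which equals Δ^(minimum hop count from d up to t). Children
outside the closure cannot contribute — D_d is undefined there — so the
recursion is restricted to the closure; this is the only reading under which
the recursion is well-defined. Δ (the semantic contribution decay factor)
defaults to 0.5, the conventional value for this family of measures, and is
exposed in the config. Multiple roots are allowed; a disease's closure only
contains ancestors it actually reaches.

MiRNA-level similarity is the symmetric mean-of-best-matches over the two
disease sets. Associations naming diseases absent from the ontology are
dropped with a log message; a miRNA losing all its diseases is excluded from
the network, because the best-match similarity over an empty set is
undefined. Disease-level similarity is computed once per disease pair and
reused for all miRNA pairs.

This network is recomputed from raw association tables rather than imported
from a precomputed similarity service, so the pipeline has no external data
dependency.

## GO-annotation similarity (miRSN-GOA)

Gene sets per GO term are closed over descendants (true-path rule) before
anything else; this is what makes IC monotone from parent to child and is
standard GO semantics. Terms annotated to zero genes are pruned. IC uses the
natural logarithm (the base is a free convention; nats are used everywhere in
the package for consistency with the hypergeometric weights).

Term–term similarity combines the most informative lowest common ancestor
and, when one exists, the most informative highest common descendant:
Sim(x,y) = min(1, (IC_L + IC_H)/(IC(x)+IC(y))). This form is symmetric,
equals 1 on identical non-root terms, reduces to a Lin-style ratio when the
pair has no common descendant, and is capped at 1 since a shared descendant
can be more informative than either term. When both terms are roots
(IC sum 0) the similarity is defined as 1 for identity and 0 otherwise.
Where an LCA or HCD set has several members the maximum IC is used; the
choice is a design decision, switchable in principle, made because the most
informative shared term is the tightest evidence of relatedness.

Per-miRNA term weights are w_x = −ln P(X ≥ k) with X hypergeometric over
(N background genes, M genes under the term, n targets); k = 0 gives w = 0
and such terms are dropped from the profile. When the tail underflows double
precision the log point mass at k is used instead. Profile comparison is the
weighted normalized Euclidean aggregation of best-match term similarities,
s(q→t) = sqrt(Σ (Sim(x,B_t)·w_x)² / Σ w_x²), averaged over both directions;
this is bounded in [0,1] and equals 1 exactly on identical profiles.

## PPI-distance similarity (miRSN-PPI)

Edges are undirected and unweighted; duplicate and reversed edges collapse
and self-loops are dropped. The score for a miRNA pair is
(number of reachable ordered target pairs) / (sum of their BFS distances),
i.e. the reciprocal mean distance. Unreachable pairs are excluded from both
numerator and denominator rather than given a penalty distance — absence of
a path is treated as absence of evidence, not as infinite dissimilarity.
Two conventions close the degenerate cases: a score above 1 (mean distance
below 1, possible when targets are shared or adjacent) is capped at 1 so all
three networks share the [0,1] scale required by averaging fusion, and a
pair set whose distances are all zero (identical single targets) scores 1.

## Fusion

Fusion is a single simultaneous per-unordered-pair mean over the networks
containing both miRNAs, on the union of all ids. A pair known to only one
network keeps that network's value; a pair bridging two networks' private
ids gets 0 (no network ever compared those two miRNAs). Simultaneous
averaging was chosen over sequential pairwise averaging because the latter
is order-dependent (((A+B)/2+C)/2 ≠ mean(A,B,C)); the simultaneous mean is
the order-free generalization of the described pairwise procedure. The
pipeline default fuses miRSN-DA with miRSN-GOA, the combination that
performs best as the input network; any subset is selectable.

## Random walk with restart and list expansion

The fused matrix is sparsified at the similarity coefficient τ (default
0.6): off-diagonal entries below τ are deleted, entries equal to τ are
retained (the boundary case is unspecified in the source descriptions of
this step; keeping it is the permissive choice), and the diagonal is zeroed.
Surviving entries keep their similarity as edge weight, so the walk is
biased toward stronger edges rather than run on a binarized graph.

Columns are normalized to sum 1; all-zero (isolated) columns are left zero,
which leaks walk mass out of the system but cannot create spurious scores.
The update r ← c·W·r + (1−c)·e starts at e, uniform over the seeds present
in the network. c is the coefficient on the walk term (restart mass 1−c),
default 0.85; its value is a free parameter of the method and is exposed in
the config. For c < 1 the update is a contraction with factor ≤ c, so
convergence to the unique fixed point (1−c)(I−cW)⁻¹e is guaranteed; the L1
tolerance is 1e−10 with a 10,000-iteration cap (hit only if misconfigured).

Non-seed nodes with positive score are ranked (score descending, ties by
lexicographic ID for reproducibility) and the top floor(keep_fraction·count)
are added; keep_fraction defaults to 0.5, the ratio that performs best for
this procedure. The fraction is taken over non-seed candidates, since seeds
are already in the list. Input miRNAs absent from the network pass through
to the expanded list untouched — they cannot seed walks but must not be
silently dropped.

## Over-representation analysis

The universe N is the knowledge base's member union; input miRNAs outside it
are removed from n (a sample must be drawn from the population it is tested
against). The p-value is the inclusive upper hypergeometric tail computed
via `scipy.stats.hypergeom.sf`; BH-FDR uses `statsmodels` and is applied
jointly across all sets of all categories (per-category correction is
switchable by filtering the knowledge base first). Significance is FDR
< 0.05. Hit rates are rounded half-up to 2 decimals, matching the reporting
convention of the case studies.

## Synthetic data

Generators are pure functions of (parameters, seed); each draws from its own
named stream derived from the seed so adding a generator never perturbs
another's draws. `gen_ontology` builds a single-root DAG by topological
insertion; `gen_associations` is Bernoulli with a guarantee of ≥1 annotation
per miRNA; `gen_ppin` keeps the largest component of an Erdős–Rényi graph;
`gen_go_annotations` emits true-path-closed gene–term tables.

The planted scenario is the end-to-end harness: 60 miRNAs, a 20-member
module with within-module similarity drawn from [0.8, 0.95] in the DA and
GOA networks and background [0.05, 0.3] everywhere else (and throughout the
PPI network), a knowledge base of the module plus 24 random decoy sets
covering every miRNA, and an input list of half the module. The effect
sizes live in `PlantedConfig`, not hard-coded: they are chosen so that after
two-network fusion the within-module edges (≥0.8) survive τ = 0.6 and
background edges (≤0.3) do not, making module recovery a structural
consequence of the pipeline rather than a statistical accident. What the
scenario does **not** emulate: real miRNA similarity distributions are
heavy-tailed and block-structured rather than uniform, real knowledge-base
sets overlap heavily, and real networks only partially share miRNAs. Passing
tests therefore demonstrate the mechanics of the chain — thresholding,
diffusion, ranked selection, testing — not performance on real data.

Problem sizes used in tests and in the acceptance script (60 miRNAs, 20-node
module, ≤12-node oracle fixtures, 200 random walk networks) were chosen so
the full suite runs in seconds while keeping every oracle exact.

## Numerical choices and degenerate inputs

- Similarity matrices reject asymmetry above 1e−9 and repair below it by
  averaging; diagonals must be 1 within the same tolerance and are snapped
  exactly. Matrix TSVs carry 12 significant digits, enough for bit-stable
  round trips of doubles at these magnitudes.
- Exact-rational enumeration (`fractions.Fraction`) is the oracle for all
  hypergeometric tails at N ≤ 12; the implementation uses scipy.
- The BH step-up is cross-checked against an independent hand implementation.
- The iterative walk is cross-checked against the closed-form linear solve.
- Empty association lookups yield empty sets; empty candidate sets make
  expansion the identity; an input list disjoint from the KB universe is an
  error rather than a silent p = 1 table.

## Known limitations

- All-pairs network construction is O(k²) in the number of miRNAs with
  non-trivial per-pair work (GO best-match especially); the implementation
  caches term-pair similarities but is designed for the
  hundreds-to-low-thousands of miRNAs typical of curated resources, not for
  tens of thousands.
- Mature-to-precursor miRNA ID conversion is an upstream curation step; the
  package only offers a user-supplied mapping hook (`apply_id_mapping`).
- PPI edges are unweighted; confidence scores, if present, are ignored.
- The walk supports only a uniform restart vector over seeds.
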