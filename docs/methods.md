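# Methods

This note documents the models and procedures implemented in `ffasc`,
the defaults chosen where the design was genuinely open, and what the
synthetic fixtures do and do not establish about real screening runs.

## Screening model

A strain is represented by its row of the species × OG hit-count matrix
`C`. Entry `(i, j)` is `hitN`: the number of retained homology hits of
OG `j`'s member proteins against species `i`'s proteome. Two filters
precede counting:

* **E-value filter.** Hits with e-value ≤ 10⁻⁴ are retained. The
  boundary is inclusive, matching common BLAST practice.
* **Domain-completeness filter.** A hit is retained only when the target
  protein's trusted-cutoff-passing Pfam annotations form a superset of
  the domains required for the query member protein. Members with no
  recorded requirement bypass the filter (their hits pass vacuously).
  The filter is what keeps weak, partial homologs (e.g. single-domain
  matches to a two-domain enzyme) out of the counts.

The two filters commute and are idempotent; the pipeline applies the
e-value filter first only for efficiency.

**Counting unit.** `hitN` counts distinct (query member, target protein)
pairs; multiple HSPs for one pair collapse to one. The alternative —
distinct target proteins per OG regardless of which member matched — is
available as `count_unit="distinct_targets"`. The pair convention was
adopted because an OG with several members is meant to accumulate
evidence from each of them; with single-member OGs the two conventions
coincide.

**Quantification.** Per category: `nOG → −hitN`, `rOG → hitN`,
`pOG → hitN` with a penalty of `−1` when `hitN = 0`. The penalty encodes
that a missing enhancer is actively unfavourable rather than neutral, and
it makes the pOG criterion discontinuous at zero: raising a pOG from 0 to
1 copy raises the weighted score by `2wⱼ`.

**Scores and ranking.** `score(i) = wᵀxᵢ`; unit weights give the plain
criteria sum. Ranking is by descending score, rank 1 best, ties broken by
ascending species id (any deterministic tie-break works; the id is the
only one that needs no extra state). Reported scores are min–max
normalized over the ranked set so the top strain prints 1.000000; the
transform is monotone and therefore rank-preserving. Normalization
refuses an all-equal score vector rather than inventing a convention.
Genome size is deliberately **not** normalized for: the object of
interest is the organism's natural complement of relevant proteins, not
its density per megabase.

## Weight optimization

Weights are fitted against a single positive/negative reference pair by
maximizing `wᵀ|x₊ − x₋| + p·rank_gap` subject to `0.001 ≤ wⱼ ≤ 1`,
`Σwⱼ = 12` and the strict separation constraint `wᵀ|x₊ − x₋| > 0.001`.
`rank_gap = rank(neg) − rank(pos)` over the full weighted ranking, so a
better-placed positive reference increases the objective; `p = 0.010241`
converts one rank position into score units.

The optimizer is a generalized pattern search written for this package:

* poll the `2m` signed coordinate directions scaled by the current mesh;
* project every poll point onto the feasible set (exact Euclidean
  projection onto box ∩ hyperplane, computed by bisection on the clip
  shift — all evaluated points are feasible, and the equality constraint
  holds to 1e-9);
* reject candidates violating the strict separation floor;
* accept the first candidate that improves the objective by more than
  the forcing function `c·Δ²` (c = 10⁻³, Δ = mesh size), expanding the
  mesh ×2 on success (capped at 2, beyond which polls only get clipped
  back) and contracting ×0.5 on a full unsuccessful poll;
* stop when the mesh falls below 10⁻⁶ or after 2000 iterations.

Defaults: initial point uniform (`12/m` each), initial mesh 0.25. The
sufficient-increase forcing function matters in practice: because the
projection couples all coordinates, plain first-improvement polling can
chase rounding-level gains at large mesh sizes and starve the genuinely
informative direction; requiring the gain to scale with the squared mesh
restores the standard convergence behaviour. Accepted-iterate objectives
are non-decreasing by construction, and a fixture whose reference pair
differs in exactly one criterion drives that criterion's weight to the
upper bound — the analytic optimum under the constraints.

Fitting to one reference pair is a deliberate mirror of the data-poor
setting the method targets; the weights are therefore anchored to those
two strains, not globally optimal, and multi-reference fitting is out of
scope.

## Cluster validation

* **k-means**: Lloyd's algorithm under squared Euclidean distance on raw
  criteria values, best of 25 restarts, each initialised with k distinct
  rows drawn uniformly at random; deterministic per seed. Within-cluster
  sum of squares is non-increasing across iterations; empty clusters are
  refilled with the farthest point that is not a sole cluster member.
* **Silhouette**: per point `(b − a)/max(a, b)` with Euclidean distances;
  singleton clusters and the 0/0 case contribute 0 (the common
  convention, matching scikit-learn, which the tests use as an
  independent cross-check alongside a brute-force oracle).
* **Calinski–Harabasz**: `[B/(k−1)]/[W/(n−k)]`; `W = 0` returns an
  infinite-separation sentinel rather than raising.
* **Natural-k heuristic**: known outgroup species anchor the scan. Status
  per k: `mixed` (outgroup shares a cluster with in-group species),
  `exclusive_together` (own cluster), `split` (spread over >1 cluster).
  The candidate range runs from the first `exclusive_together` through
  the first subsequent `split` (inclusive; to the scan end if no split
  occurs), and the candidate with the highest average silhouette is
  selected, with CH reported alongside. The rationale: too few clusters
  force the outgroup into artificial fusions, too many shatter it, and
  the window in between reflects the data's own granularity.
* **Heatmap layout**: the matrix is first stabilised with elementwise
  uniform(−0.5, 0.5)·10⁻¹⁰ noise (breaking exact ties and singular
  structure while staying below any meaningful signal), rows then columns
  are z-standardised, distances are 1 − Spearman rank correlation, and
  average-linkage agglomerative clustering supplies both leaf orders.
  Undefined correlations from constant rows/columns map to the maximal
  distance 2 with a warning.

## Annotation comparison

Two binary presence/absence matrices over the same strains and OGs are
compared by row-wise subtraction `a − b`. Per OG the signed difference
sum lies in [−n, n]; the class is `identical` when all strains agree,
`a_only`/`b_only` when every disagreement points the same way, and
`mixed` otherwise — the mixed case is tracked explicitly because a
three-way account would silently misfile OGs whose disagreements go both
ways. Positive differences mean "present in the first matrix only"; this
is the mathematically consistent reading of the subtraction order.

## Synthetic fixtures

The generators produce every input format the pipeline consumes, with
stored ground truth:

* **Catalogs** with requested category fractions (largest-remainder
  rounding), member counts, and per-member Pfam requirements, including
  members with none (exercising the filter bypass).
* **Search payloads**: planted hit counts are Poisson with per-category
  means (nOG 0.5, pOG 1.5, rOG 1.0 — low enough that the pOG absence
  penalty is exercised, high enough for multi-hit counting), serialised
  as syntactically valid outfmt-6 and domtblout text. Decoys defeat
  exactly one filter each: e-value decoys are domain-complete with
  e-value > 10⁻⁴; domain decoys have good e-values but one required
  domain withheld.
* **Reference pairs**: positive and negative rows straddle a common
  midpoint so their difference equals the planted delta exactly; the
  remaining species scatter around the midpoint (σ = 0.05) so the
  reference ranks stay pinned while the optimizer moves weights.
* **Clustered layouts**: k unit-variance Gaussian blobs around centers an
  expected `separation = 25` apart in 49 dimensions, plus a small
  outgroup centered at 1.2 × separation with spread 2.5. The geometry is
  chosen so the outgroup behaves like the real outgroup does across a
  k-scan: absorbed into in-group clusters at small k, granted its own
  cluster once every blob has one, and split only at larger k. Closer
  outgroups never become exclusive; far-off ones grab a cluster at k = 2
  and dominate the silhouette.

What passing on these fixtures shows: the parsers, filters, counting,
scoring, optimization and index computations are each other's exact
inverses/oracles under the stated conventions. What it does not show:
robustness to real annotation noise — paralog inflation, fragmented gene
models, HMMER/BLAST version drift, or catalog curation error. Real
screens inherit whatever biases the upstream annotation pipeline has.

## Problem sizes and numerics

The test suite and the acceptance script run at deliberately small sizes
— 3–6 species bundles over 6–12 OG catalogs for round-trips (100 seeds),
a 125-species screen at the full 49-OG shape, 12-species reference pairs,
and a 128-point cluster scan — sizes at which the brute-force oracles
remain exact and the whole suite completes in seconds. Score equalities
are asserted to 1e-12, index oracles to 1e-9, and the weight-sum
constraint to 1e-9. Scores are printed to 6 decimals in output files.

## Known limitations

* The shipped catalog carries the 49 OG ids, categories and action
  labels, but the per-member Pfam domain requirements are left empty
  (user-suppliable): the original curation's per-protein domain table is
  not redistributed, and the split of the 64 members across OGs beyond
  one representative gene per OG is a synthetic reconstruction.
* Weights fitted to one reference pair are not transferable across
  catalogs or organisms without re-fitting.
* Whether the original analyses counted HSPs, query–target pairs, or
  distinct targets is not documented; the config switch covers the
  plausible readings but defaults affect absolute hitNs.
* The optimizer's solution is trajectory-dependent (as any pattern
  search's is); only the constraint set, monotonicity, and the
  single-criterion recovery case are guaranteed, not a unique global
  optimum.
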