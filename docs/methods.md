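# Methods

## Study design being modeled

The pipeline analyses a two-subject longitudinal design: a graft-losing
subject (S1) and a graft-stable control (S2), each with whole-blood
expression profiles at four timepoints — t1 before transplantation, t2
during stable graft function, t3 immediately after the first sign of graft
failure, t4 after overt failure. Two contrasts carry the signal of the
graft-losing period: t3 vs t2 within S1 (what changed in the failing
subject as the graft was being lost) and S1 vs S2 at t3 (what
distinguishes the failing from the stable subject at that moment). All
downstream stages are built on these two contrasts.

## Pathway activation test

For a contrast (case sample, control sample), genes with abundance below
`min_expression` (default 1.0, in the matrix's TPM-like units) in *either*
sample are discarded — ratios between near-zero abundances are dominated
by measurement noise — and the remaining genes get `log2(case/control)`.

Per pathway, the statistic is the mean log2FC over its surviving member
genes, and significance comes from a one-sided *competitive* permutation
test: `n_permutations` (default 1000) random gene sets of the same size
are drawn from the filtered universe, and

    p = (1 + #{ permuted mean >= observed }) / (n_permutations + 1).

The +1 pseudocount keeps the p-value a valid test level (it can never be
zero); a pathway whose genes all fail the filter is flagged untestable and
excluded from selection rather than raising. When scoring a whole
database, permutation draws are shared between pathways of equal size —
each pathway's marginal null is unchanged; only cross-pathway dependence
is introduced, which the selection rule does not use. This transparent
statistic deliberately stands in for time-series pathway-impact tools that
the surrounding analysis treats as black boxes: every downstream stage
consumes only the (statistic, direction, one-sided p) contract.

## GLPAP selection and category enrichment

A pathway is a *graft-loss-period-related activated pathway* (GLPAP) when
it is up-regulated (statistic > 0) with p strictly below `alpha` (default
0.05) in **both** contrasts. Strictness follows the rule's "under 0.05"
reading; a p of exactly 0.05 does not qualify.

Categories are treated as a partition (each pathway carries exactly one
category label). Per category the 2×2 table (GLPAP / non-GLPAP ×
in-category / not) is scored with the one-sided Fisher's exact test — the
hypergeometric upper tail P(X ≥ a) with fixed margins, computed via
`scipy.stats.hypergeom.sf` and cross-checked in the tests against a
factorial enumeration oracle. Raw p-values are reported in ascending
order with no multiplicity correction: the stage ranks categories rather
than making a calibrated family-wise claim, and the tests verify that the
minimum p over categories is (conservatively) Bonferroni-calibrated under
random selection.

## Crosstalk network and central pathways

Nodes are GLPAPs. The crosstalk weight of a pathway pair (P, Q) is

    |genes(P) ∩ genes(Q)|  +  |{ PPI edges with one endpoint in P∖Q and the other in Q∖P }|,

i.e. shared membership plus physical interactions bridging the exclusive
parts; an edge requires weight ≥ `min_crosstalk` (default 1), and
pathways left without any edge are omitted from the graph. The rule is a
documented, configurable stand-in for proprietary pathway-interaction
constructions: it preserves the contract the rest of the analysis needs —
a pathway graph on which closeness and degree are meaningful.

Closeness uses the Wasserman–Faust component-aware normalization
`((r−1)/(n−1)) · ((r−1)/Σd)` (r = reachable nodes, n = graph size), which
reduces to `(n−1)/Σd` on a connected graph and keeps values comparable
when some GLPAPs fall in a separate component. A pathway is *central*
when its closeness **and** degree strictly exceed the arithmetic means
over all nodes in the graph (not over all GLPAPs); the selection can be
restricted to one category — typically the most enriched — without
changing the cutoffs.

## Hypothesis evaluation by network propagation

Each etiological hypothesis is a seed-gene set. Influence is spread by
random walk with restart:

    s ← (1 − r)·W·s + r·s0,

with restart probability `r` (default 0.5 — the common middle ground in
the propagation literature; unweighted evidence either way), `s0` uniform
over the seeds, and `W` the degree-normalized adjacency. The default
normalization is symmetric, `W = D^{-1/2} A D^{-1/2}`; a column-stochastic
variant (`A D^{-1}`, which conserves Σs = 1 exactly) is available. The
iteration stops when the L1 change falls below `tol` (default 1e-10) and
is verified in the tests against the closed form
`s = r·(I − (1−r)W)^{-1}·s0`; convergence is geometric at rate (1−r)
because the spectral radius of the normalized adjacency is ≤ 1.

The *DEG profile* is the log2FC ranking of the S1-vs-S2 contrast at t3
after the same abundance-< 1 filter; ties get mid-ranks. The default
ranking key is signed log2FC (rank 1 = most up-regulated), matching the
analysis's up-regulation framing; ranking by |log2FC| is exposed for
symmetric designs. The hypothesis's coefficient is the Pearson
correlation of the propagation rank vector and the DEG rank vector,
restricted to genes present in both and re-ranked within that
intersection — identically Spearman's rho on the scores — with the
parametric p from the t-distribution. A top-k variant (default k = 100)
repeats this on the k most-propagated genes (ties at the boundary broken
by gene id).

Significance is assessed against `n_sim` (default 1000) random seed sets
of the same size, by default uniform over network genes (a degree-matched
sampler with log2-degree bins is available):

    p = (1/N) · #{ j : c_j > c_ref }   —

literally the strict-inequality, no-pseudocount form; a Phipson–Smyth
corrected variant `(1+b)/(N+1)` sits behind `corrected=True`. The
empirical p therefore lives on the lattice {0, 1/N, …, 1} and can be
exactly 0. Each hypothesis draws its null from an independent child RNG
stream, so results are invariant to evaluation order.

## Synthetic-data generator

The generator emulates the study conditions: 2 subjects × 4 timepoints;
2,000 genes; 50 pathways of 10–40 genes in 10 categories; 5 activated
pathways at fold 4; a preferential-attachment PPI (Barabási–Albert,
5 edges per new node → scale-free degrees over ~2,000 nodes); five
hypothesis seed sets of sizes 10/9/8/10/9 with "chronic graft rejection"
causal.

* **Expression** — per-gene log-normal baseline (natural-log mean 3.0,
  SD 1.0 → median ≈ 20 abundance units, a plausible detected-gene level)
  shared across samples, plus per-sample log-noise (SD 0.3 → null log2FC
  SD ≈ 0.6, in the range typical of between-sample biological+technical
  scatter). Under the null the log2FC of any contrast is zero-centered,
  which is what the activation statistic assumes.
* **Activation** — members of the planted pathways are multiplied by
  `activation_fold` in exactly one (subject, timepoint) cell — (S1, t3) —
  so both contrasts see the signal. `activation_fold = 1` produces a null
  dataset with the manifest still recorded. When the planted pathways are
  given as a count they are all drawn from the generator's first category,
  making the activation biologically coherent (one functional theme, as
  in an immune response) and the enrichment stage's recovery testable.
* **Seeds** — the causal hypothesis's seeds are sampled uniformly among
  direct PPI neighbors of the perturbed (DE) genes — mimicking
  literature-derived seed genes: functionally adjacent, ordinary
  connectivity — and a few seed→DE edges are wired in when the sampled
  topology leaves less than half of the DE genes adjacent to the seed
  set, so propagation must genuinely spread influence for the causal
  hypothesis to win. Non-causal seed sets are sampled uniformly outside
  the DE genes' one-hop neighborhood.

What the generator does **not** model: sequencing-depth/library-size
effects, batch structure, isoform complexity, correlated co-expression
modules beyond the planted pathways, and biologically structured PPI
modularity. Passing recovery tests therefore show that the statistics
behave as designed under their own assumptions — not that the pipeline is
robust to real-data artifacts such as normalization error or annotation
incompleteness.

## Numerical and design choices

* Permutation subsets are drawn via per-row random keys + argpartition
  (uniform without replacement); determinism comes from
  `numpy.random.default_rng` seeding everywhere, and per-hypothesis
  streams from `SeedSequence.spawn`.
* Expression TSVs are written at `%.17g`, which round-trips IEEE doubles
  exactly; result tables use `%.10g` for stable, readable output.
* Degenerate inputs: empty GLPAP set → empty graph and all-1 enrichment
  p-values with warnings; pathway with no filtered genes → untestable
  flag; seeds missing from the network → dropped with a warning, error
  only when none remain; constant rank vectors → explicit error
  (correlation undefined).
* Problem sizes in the test suite (replicate counts, permutation counts,
  toy-graph sizes) are chosen to exercise each statistical claim at
  Monte-Carlo resolution appropriate to its tolerance while keeping the
  default run in the minutes range.

## Known limitations

The activation test and the crosstalk rule are deliberate, documented
substitutes for external black-box tools, so numbers produced on real
data will differ from pipelines built on those tools even at identical
thresholds. The empirical p with strict `>` and no pseudocount can return
0 and is slightly anti-conservative for very small N; use
`corrected=True` when a strictly valid level matters. With only two
subjects the contrasts have no biological replication — as in the design
this emulates — so all p-values condition on the observed pair and speak
to gene- and pathway-level exchangeability, not population-level effects.
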