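# Methods

## Model

Steady-state expression is modelled by a linear-Gaussian structural equation
model (SEM) on a directed graph over p genes:

    X_j = Σ_{i ∈ Pa(j)} θ_ij X_i + ε_j ,   ε_j ~ N(0, σ²),

with coefficient matrix Θ (entry (i, j) = effect of gene i on gene j; zero
diagonal). For acyclic graphs this is the usual recursive SEM; for cyclic
graphs the stationary solution X = (I − Θᵀ)⁻¹ε exists whenever the spectral
radius of |Θ| is below 1, with covariance σ²(I − Θᵀ)⁻¹(I − Θ)⁻¹.

A single-gene perturbation screen measures, for every knocked-out gene i,
which genes j respond — in the error-free limit exactly the *descendants* of
i. The binary influence matrix B therefore estimates the ancestor closure of
the regulatory graph, not the graph itself: B identifies causal order but
not structure. The expression data supply the missing structural
information, which is the premise of the whole method.

## The three stages

**Influence matrix.** Each knockout condition (r replicates) is compared
gene-by-gene against the wild-type baseline (r0 replicates) with a
two-sample test; Welch's t is the default, with pooled and
variance-floored ("moderated": the per-gene pooled variance is floored at
the median pooled variance across all genes) variants for the
small-replicate regime. Thresholding the p-value matrix at a cutoff gives B;
self-comparisons are fixed at p = 1. A diagnostic table (edge count and
largest connected component of the undirected skeleton over a cutoff grid)
supports cutoff selection: in a modular network, the largest component drops
sharply once bridging noise edges fall below the cutoff. Raw cutoffs are the
default; Benjamini–Hochberg adjustment is available.

**Causal orderings.** A causal ordering is the node listing by descending
DFS post-visit time — a topological sort when the graph is acyclic. The
influence graph is condensed by strongly connected components (SCCs),
deterministically topologically ordered by descending maximum post-visit
time of a DFS run in node-label order. Orderings are produced per SCC:

* components with ≤ 10 nodes (configurable) are enumerated *exhaustively*
  by backtracking over every free choice a DFS can make (start node and
  next-neighbour choices). The enumeration provably equals the universe of
  orderings induced by all node relabelings: given any DFS execution, the
  labeling that ranks nodes by the execution's discovery times reproduces
  it. This equivalence is asserted against an independent
  all-label-permutation oracle on every strongly connected digraph with ≤ 4
  nodes.
* larger components are sampled by MC-DFS: uniform random relabelings
  followed by deterministic DFS, de-duplicated (O(M(p+e)) for M draws).

Per-SCC orderings are concatenated in the fixed condensation order and
combined across SCCs by Cartesian product; when the product exceeds the
requested budget, combinations are sampled uniformly without replacement.
Per-SCC generation (rather than whole-graph MC-DFS, which is available
behind a flag) is the default for two reasons: predictor sets in the
estimation stage depend only on precedence *across influence edges*, which
per-SCC concatenation preserves; and testing revealed that whole-graph DFS
does not even keep SCC blocks contiguous, so its extra ordering diversity
is irrelevant to the downstream fits.

**Per-ordering estimation.** For ordering π, gene j's candidate parents are
C_j = { i : i precedes j in π and B[i, j] = 1 } — its influence-graph
parents consistent with π, i.e. candidate ancestors in the regulatory
graph. Each gene with C_j ≠ ∅ is fit by the lasso problem

    min_θ  (2n)⁻¹ ‖X_j − X_{C_j} θ‖² + λ_j ‖θ‖₁ ,
    λ_j = 2 n^{-1/2} Z*_{α/(2 p (j−1))} ,

solved by coordinate descent (scikit-learn; tolerance 1e-6, ≤ 10⁴
iterations; its native objective matches this parameterization with
`alpha = λ_j` exactly, no rescaling). Data are column-centered (optional
unit-SD scaling for heterogeneous real data; the λ formula assumes
unit-variance innovations). Two deliberate choices:

* **Loss scale.** λ_j above is calibrated for the n-averaged loss
  (2n)⁻¹RSS; pairing it with an unnormalized ½RSS loss would under-penalize
  by a factor n and select essentially every candidate. The fit and the
  score both use the (2n)⁻¹ scale.
* **Bonferroni count.** The (j − 1) in λ_j is evaluated at the *effective*
  regression size |C_j| (+1), not the raw ordering position. With a complete
  influence matrix the two coincide; with a restricted candidate set this
  makes the fit of every gene depend only on the precedence relation over
  influence edges, so two orderings that differ by permuting incomparable
  genes give *identical* estimates and scores (asserted exactly in tests).
  It also means fits are cacheable by (gene, candidate-set) across
  orderings, which dominates the cost of multi-ordering runs.

The per-ordering score (penalized negative log-likelihood, pnll) is the sum
over all genes of the fitted objective, with non-regressed genes
contributing their null-model RSS/(2n) so that scores are comparable across
orderings. The likelihood formula is isolated in one function
(`pnll_score`) and can be swapped.

**Consensus.** DAGs with pnll in the lower q-th empirical quantile (ties
included, at least one always selected) are averaged: Λ_ij is the fraction
containing edge i→j; the edge set is {Λ_ij > τ}. Sign and magnitude are the
sign and absolute value of the mean coefficient over the *selected* set,
with absent edges counted as zeros in the mean. Defaults q = 0.2, τ = 0.3
sit in the middle of the plateau where results are insensitive to both; a
sweep mode reports edge counts over a (q, τ) grid.

**Two-layer mode (k < p).** When only k genes (e.g. transcription factors)
were perturbed, orderings are generated over the perturbed genes only and
extended with all unperturbed genes at the end (fixed arbitrary internal
order). Unperturbed genes are regressed solely on their perturbed
influencers, so no edge ever leaves an unperturbed gene; with k = p the
mode reduces exactly to the standard fit.

## Synthetic data

The generator reproduces the benchmark conditions:

* `random_dag`: nodes in a random causal order, forward edges with
  probability 2·density/(p−1) (density = expected edges per node), n_hubs
  high-out-degree regulators each wired to ~20% of their downstream nodes,
  and ≥ 2 unregulated source genes. All weights equal `edge_weight`
  (default 1.0); n defaults to 100 samples — the unit-weight, n = 100
  regime of the reference benchmarks.
* `random_cyclic`: back-edges added to a random DAG (≥ 1 guaranteed), then
  weights rescaled so the spectral radius of |Θ| ≤ 0.9 by default,
  guaranteeing a stationary SEM.
* `sem_sample`: exact sampling via X = (I − Θᵀ)⁻¹ε.
* `simulate_screen`: knockouts as do-interventions — incoming edges cut,
  the gene clamped at `knockout_level` (default −5σ, a strong repression) —
  with r replicates per condition plus r0 wild-type replicates (default 5
  each, the realistic screen regime of 2–5).
* `corrupt_influence`: direction reversals (fraction of edges), false
  negatives (fraction of edges deleted), false positives (per-pair Bernoulli
  with a given expected count; FP *levels* are fractions of the p(p−1)/2
  gene pairs, so 1.5% on p = 100 is ~74 expected spurious edges).

What the generator does **not** emulate: microarray normalization and batch
structure, non-Gaussian or heteroscedastic noise, kinetic/ODE dynamics,
partial or off-target knockouts, and dependence between screen and
steady-state data. Passing benchmarks therefore demonstrate correctness of
the method under its own model assumptions, not robustness to the
real-data artefacts upstream preprocessing must handle.

## Benchmark harness and problem sizes

`benchmark()` reproduces three protocols (always the inference column only):
a p = 50 hub DAG with reversed/added influence edges ("table3"), a p = 100
DAG under FP/FN corruption levels ("table5", density calibrated once so the
ancestor closure carries ≈ 200 influence edges), and a reduced-scale cyclic
protocol ("table6-style", p = 200). Every replication regenerates the full
condition — truth graph, corruption draw, expression data — so the reported
mean is an ensemble average and the SD covers graph realization, corruption
and expression noise rather than expression noise alone; with a single
fixed instance the mean would be hostage to instance luck. Default scale is
25 replications with 100–200 sampled orderings; accuracy is flat in the
ordering budget well below these values (asserted in tests at budgets
50 vs 200), so the reduced scale does not change the means. Full-scale
settings remain available through the function arguments.

## Numerical choices and edge cases

* Zero variance in both test groups: p = 1 if means are equal, else p = 0.
* Quantile selection always keeps ≥ 1 DAG; pnll ties are all included.
* Lasso weights (adaptive penalties) are folded in by column scaling;
  default is the unweighted lasso.
* Degenerate/singular design columns are handled by the solver's
  convergence tolerance, never silently dropped.
* The random-graph significance test (Erdős–Rényi with the estimate's edge
  count, no self-loops) uses the plus-one correction
  (1 + #{TP_rand ≥ TP_obs}) / (n_rand + 1), so it never returns 0.
* All randomness flows through seeded `numpy` generators; every pipeline
  stage derives its seed from the run seed, and reruns are reproducible.

## Known limitations

* The influence matrix must be trusted as *ancestry* information; systematic
  screen biases (e.g. compensatory feedback masking a response) violate the
  candidate-superset assumption and show up as false negatives that the
  expression data cannot repair.
* Edge confidences Λ are selection frequencies over the retained orderings,
  not calibrated posterior probabilities.
* The moderated test is a variance-floored pooled t, not a full
  empirical-Bayes moderation.
* Exhaustive enumeration is exponential; components beyond ~15 nodes are
  only accessible through MC-DFS sampling, whose coverage of the ordering
  universe is unquantified (though downstream accuracy plateaus quickly in
  the number of orderings).
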