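# Methods

## Model and assumptions

The package models gene expression as a linear structural equation model
(SEM) over a directed acyclic graph: X = XW + E, where X is the n × d
samples-by-genes matrix, W[i, j] is the direct linear effect of gene i on
gene j (so the support of W is the causal graph, "row causes column"), and
the noise columns E are mutually independent with finite variance. The
working assumptions are the standard ones for observational causal
discovery: causal sufficiency (no unmeasured common causes), faithfulness
(conditional independences in the data reflect d-separations in the graph,
with no exact cancellation of paths), i.i.d. samples, and — for the Fisher-z
conditional-independence test — approximately Gaussian joint distributions.
Under Gaussian noise only the Markov equivalence class (the CPDAG) is
identifiable, not a unique DAG; everything downstream is designed around
that limit.

### PC stage

The skeleton search is PC-stable: at each conditioning-set size ℓ the
neighbor sets are frozen before any removal, which makes the output
invariant to gene ordering. The conditional-independence test is the Fisher
z-transform of the partial correlation r of (i, j) given S (computed from
the inverse of the corresponding correlation submatrix): the statistic
√(n − |S| − 3)·|atanh r| is compared with the standard normal two-sided
tail. Degenerate |r| ≥ 1 is clamped to 1 − 1e−12 and treated as dependence;
a test with n ≤ |S| + 3 is skipped with a warning and the edge kept
(conservative). Defaults: test level alpha = 0.05, maximum conditioning-set
size 3; both configurable. The data are standardized per gene before
testing; Fisher-z is scale-invariant so this only stabilizes the numerics
and matches the preprocessing of the optimization stage.

Unshielded colliders are oriented by the max-p rule: for each non-adjacent
pair the conditioning set with the *largest* test p-value (over subsets of
either endpoint's neighbors, up to the conditioning cap) is taken as the
separating set, and i → k ← j is oriented when k lies outside it.
Compared with using the first separating set found during skeleton search,
this is much more robust on hub-heavy graphs, where two targets of the same
regulators can appear "independent" given a spurious small set whenever
their parent effects nearly cancel; the first-found rule then orients false
colliders into the regulators. The first-sepset rule remains available
(`orient_v_structures(rule="sepset")`). Conflicting orientations of one
edge from different triples leave the edge undirected — the conservative
choice never asserts an unsupported direction. Meek rules R1–R4 are applied
to a fixed point to complete the CPDAG.

### NOTEARS stage

The least-squares score (1/2n)‖X − XW‖²_F with L1 penalty λ₁‖W‖₁ is
minimized subject to h(W) = tr(exp(W∘W)) − d = 0, the smooth acyclicity
function whose gradient is exp(W∘W)ᵀ∘2W. The equality constraint is handled
by an augmented Lagrangian: starting from ρ = 1, α = 0, each subproblem
minimizes score + (ρ/2)h² + αh over W = W⁺ − W⁻ with non-negativity bounds
(L-BFGS-B, warm-started from the previous iterate, iteration cap 1000); if
the new h exceeds 0.25 of the previous one, ρ is multiplied by 10 and the
subproblem re-solved, otherwise α ← α + ρh. The loop stops at h ≤ 1e−8
(converged) or ρ ≥ 1e16 (best iterate returned with a warning flag).
Internally the score is evaluated in Gram form ((1/2)[tr S − 2tr(SW) +
tr(WᵀSW)] with S = XᵀX/n), which makes each evaluation O(d³) rather than
O(nd²). Overflow in exp(W∘W) during a line-search trial step is mapped to a
huge finite penalty so the step is rejected cleanly.

Defaults: λ₁ = 0.1, h_tol = 1e−8, ρ_max = 1e16, w_threshold = 0.05. The
final threshold is deliberately far below the 0.3 customary for raw NOTEARS
output because the benchmarking protocol performs its real sparsification by
top-k edge selection afterwards; the threshold only clears numerical dust.
A converged solution can still contain *long* cycles of near-threshold
weights — a k-cycle of weights w contributes roughly (w²)ᵏ/(k−1)! to h,
which for five edges of 0.1 is ~1e−12, far below h_tol — so after
thresholding the weakest edge inside any strongly connected component is
removed (ties by row then column) until the support is a DAG. This touches
only edges the optimizer already drove near zero and restores the acyclic
output contract deterministically.

Initialization is W = 0. On per-gene standardized data this makes the
two-variable case a symmetric saddle (both orientations fit equally; the
acyclicity penalty then shrinks both), which is one concrete mechanism
behind unconstrained NOTEARS's orientation errors once variance ordering is
removed — and part of why the PC mask helps.

### The hybrid (PCnt)

`build_constraint_mask` maps the CPDAG to hard permissions: a directed edge
i → j permits only (i, j); an undirected edge permits both (i, j) and
(j, i), leaving the optimizer (acyclicity + L1 + fit) to commit to one
member of the equivalence class; a non-adjacent pair permits neither.
Forbidden entries are excluded from the optimization by zero bounds, so
constraint satisfaction is exact by construction, not approximate. An empty
CPDAG short-circuits to the zero graph with a warning. Masking also shrinks
the effective problem, so the constrained fit is never slower than the
unconstrained one at realistic sizes.

Reported coefficients are on the per-gene standardized scale (the model is
fitted after standardization). This rescales each column of W by
sd(parent)/sd(child) relative to the raw-scale effects — a positive,
gene-wise scaling that perturbs but does not destroy the correlation between
estimated and generating weights.

### Bootstrap aggregation and edge selection

`fit_bootstrap` resamples rows (samples) with replacement — never genes —
re-runs the full algorithm per replicate (PCnt re-runs PC inside every
replicate), and aggregates: edge-presence frequency in [0, 1] for the
binary-output PC, mean signed weight (absent edges contributing 0) for
weighted methods. Replicate b uses seed `seed + b`, so runs are independent
but exactly reproducible; failed replicates are logged and skipped with the
denominator adjusted, and only all replicates failing is an error. Mean
aggregates of weighted methods are passed through the same weakest-edge
cycle resolution as the solver output: a pair whose orientation flips across
replicates otherwise retains weight in both directions, and for a 2-cycle
the rule reduces to keeping the dominant direction (the per-replicate
majority). Finally `select_top_k_edges` keeps the k largest-|w| entries with
ties at the k-th rank broken by (row, column) order; defaults follow the
benchmarking protocol (10 replicates, top 40).

## Evaluation metrics

* **SHD** — minimal number of edge insertions, deletions and reversals
  between the supports; a reversal costs 1. Computed per unordered pair from
  the patterns {none, i→j, j→i, both}; verified in tests against
  breadth-first minimal-edit search over all 3-node digraph pairs.
* **Oriented precision/recall/F1** — exact directed-edge matches; 0/0 → 0.
* **Orientation accuracy** — among unordered pairs adjacent in *both*
  graphs, the fraction oriented identically; a pair predicted in both
  directions counts as wrong; undefined (NaN, excluded from aggregation)
  when no adjacency is shared. By construction insensitive to false-positive
  edges and to edges missing from an incomplete ground truth.
* **Regulator prediction** — score[i] = Σⱼ |W[i, j]| compared with the
  binary regulator labels via AUROC (rank form, ties at ½) and AUPRC
  (step-wise average precision); undefined for single-class labels.
* **Coefficient correlation** — Pearson r between predicted and true signed
  weights over orientation-matched shared edges; undefined below 3 true
  positives or for constant vectors.
* **Ground-truth subsampling** — 5 regulators + 25 targets drawn uniformly
  without replacement, induced subgraph, connectivity not required,
  20 repeats, seeded; regulator labels are preserved from the full graph
  (a regulator keeps its label even if its sampled out-degree is 0).

## Synthetic benchmark

`generate_star_dag` emulates the assumed structure of perturbation- and
eQTL-derived regulatory ground truths: a small regulator block wired
acyclically among itself (edge probability 0.1 on an upper-triangular
order) and star-like regulator → target edges (marginal probability 0.2);
targets have no outgoing edges. Weight magnitudes are uniform on
[0.5, 1.5] — bounded away from zero so edges are detectable at n ≈ 1000 —
with random signs. A **co-regulation rule** (default on) gives any target
that drew exactly one parent a second, randomly chosen regulator parent.
Regulatory programs overlap in real networks, and this overlap is precisely
what makes directions identifiable: every regulated target is then an
unshielded collider, so ~92% of edges are compelled (directed in the true
CPDAG; the test suite checks ≥ 90% on average) while the expected edge count
(~35 on 5 + 25 genes) stays compatible with top-40 selection. Without the
rule, single-parent star edges are Markov-equivalent to their reversals and
*no* method could orient them from observational data.

`simulate_linear_sem` fills columns in topological order with Gaussian
(default) or Gumbel noise of sd 1.0; the empirical covariance converges to
the analytic (I−W)⁻ᵀΣ(I−W)⁻¹ (tested). Data are simulated from the induced
subgraph itself — the favorable, causally sufficient case. A
`latent_confounding` toggle can hide regulator columns to probe violations,
but it is off by default. What passing benchmarks therefore demonstrate:
correct recovery under linear effects, additive noise and causal
sufficiency at the stated n. What they do not demonstrate: robustness to
single-cell count noise, batch effects, nonlinear regulation, or hidden
confounders — real-data performance claims need real ground truths.

Known limitation of the generator: random ± weights occasionally make two
co-regulated targets' covariance cancel almost exactly (an approximate
faithfulness violation); any separating-set rule can then orient a false
collider. Benchmark-level statistics absorb these few-percent events; unit
tests of exact orientation use sign-fixed weights instead.

## Problem sizes and numerical choices

The shipped benchmark and acceptance computations use d = 30 genes
(5 regulators + 25 targets), n = 1000 samples, 10 bootstrap replicates,
top-40 edges and 10 seeded replicates — sizes at which the full three-method
comparison completes in minutes on a single core while the metric means are
stable to a few percent across seeds. All randomness flows from explicit
integer seeds (replicate seeds derived by fixed offsets, kept below 2³¹);
identical seeds give bit-identical graphs, tables and CLI output files.
Degenerate inputs are defined rather than accidental: constant genes
standardize to zero, an all-false mask returns the zero graph, empty edge
lists round-trip over their declared gene set, and single-class regulator
labels yield NaN AUCs flagged to the caller.
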