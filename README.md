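# pcnt — hybrid PC + constrained-NOTEARS causal discovery for gene networks

`pcnt` infers weighted causal gene-regulatory networks from purely
observational expression data (bulk or pseudo-bulk samples × genes tables).
It is aimed at computational biologists who want both a causal *structure*
(which gene regulates which, with direction) and causal *effect sizes*
(signed linear coefficients) from a single analysis, together with the
benchmarking machinery to judge how much of either can be trusted at a given
sample size.

## The method

Two classical ideas are combined:

**PC** (constraint-based search) starts from a complete undirected graph and
removes the edge between genes *i* and *j* whenever a conditional-independence
test accepts X_i ⊥ X_j | X_S for some small conditioning set S (Gaussian
partial correlations, Fisher z-transform: the statistic
√(n−|S|−3)·|atanh r| is standard normal under independence). Unshielded
colliders i → k ← j are then oriented (k outside the separating set of
(i, j); decided here by the max-p rule for robustness) and Meek rules R1–R4
propagate the remaining forced orientations, yielding a CPDAG — the Markov
equivalence class of the data-generating DAG. PC recovers structure and
direction well, but outputs no effect sizes.

**NOTEARS** (continuous optimization) fits the linear structural equation
model X = XW + E by minimizing

    (1/2n) ‖X − XW‖²_F + λ₁‖W‖₁   subject to   h(W) = tr(exp(W∘W)) − d = 0,

where the smooth acyclicity function h vanishes exactly on DAGs; the
constraint is handled by an augmented Lagrangian with L-BFGS-B subproblems
on the split W = W⁺ − W⁻. NOTEARS produces signed coefficients but makes
more orientation mistakes than PC.

**PCnt**, the hybrid, turns the PC CPDAG into a hard edge mask — a directed
CPDAG edge permits only that orientation, an undirected edge leaves both
directions free, a non-adjacent pair is forced to zero — and solves the
NOTEARS program restricted to that mask (masked entries are excluded from
the optimization variables, so the constraints hold exactly). The result is
a weighted DAG with PC's structure and orientation quality and regression-
quality effect estimates, at a fraction of unconstrained NOTEARS's cost.

The package also ships the evaluation suite used to benchmark such methods
(structural Hamming distance with unit reversal cost, oriented-edge
precision/recall/F1, orientation accuracy over shared adjacencies, regulator
prediction by total outgoing weight scored with AUROC/AUPRC, Pearson
correlation of signed effects on true-positive edges), a bootstrap
aggregation protocol (10 resamples; edge frequency for the binary-output PC,
mean signed weight for weighted methods), a 5-regulator + 25-target
ground-truth subsampling scheme, and a synthetic generator of star-like,
co-regulated ground-truth graphs with linear-SEM sampling — so the whole
pipeline is testable without any external dataset.

## Worked example

```python
from pcnt import SimConfig, generate_star_dag, simulate_linear_sem, evaluate
from pcnt.model import PCNT

sim = SimConfig(n_regulators=3, n_targets=8, p_edge_reg_to_target=0.4,
                n_samples=2000, seed=7)
truth = generate_star_dag(sim)           # star-like ground-truth DAG
data = simulate_linear_sem(truth, sim)   # 2000 observational samples

results = PCNT(data, alpha=0.05).fit()
print(results.summary(max_edges=8))

report = evaluate(results.graph, truth)
print(f"oriented F1: {report.f1:.3f}   orientation accuracy: {report.orientation_accuracy:.3f}")
```

prints

```
PCNTResults
==========================================================
method: pcnt    genes: 11    samples: 2000
edges (nonzero weights): 11
PC mask: 13 permitted directed entries
converged: True    h(W): 5.13e-09    dual iterations: 12
----------------------------------------------------------
source          target                weight
REG0            TGT2                  0.6510
REG1            TGT1                  0.6142
REG1            TGT6                  0.5267
REG2            TGT4                 -0.4437
REG1            TGT3                  0.3887
REG2            TGT6                  0.3810
REG0            TGT4                 -0.3728
REG2            TGT3                  0.3640
... 3 more edges
==========================================================
oriented F1: 1.000   orientation accuracy: 1.000
```

The edge table lists inferred regulator → target effects on the
standardized scale (sign = activation/repression, magnitude = strength);
`h(W)` near zero confirms the returned graph is a DAG. Here all 11 true
edges are recovered with the correct orientation, and the estimated
coefficients correlate at 0.994 with the generating weights.

The same pipeline is available from the shell:

```bash
pcnt run expression.tsv --algorithm pcnt --bootstrap 10 --top-k 40 --seed 1 --output-dir out/
pcnt evaluate --pred out/edges.tsv --truth truth_edges.tsv
pcnt simulate --config sim.yaml
pcnt benchmark --config bench.yaml
```

Every run writes a `manifest.json` (config, seed, input checksums, version)
and is byte-reproducible given the same seed.

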