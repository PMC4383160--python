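# Methods

## Scope and model

`signet` extracts maximal-scoring connected subnetworks ("active modules")
from case/control expression data overlaid on an undirected PPI graph, and
compares modules across conditions (here called *regions*, after the
multi-brain-region setting the defaults were written for).

Per-gene evidence enters through two-sided t-test p-values. The p-value
vector is modelled as a beta-uniform mixture (BUM)
f(x) = λ + (1−λ)·a·x^(a−1) on (0, 1]: the β(a, 1) component (a < 1)
represents signal concentrated near zero, the uniform component noise. The
node score (a−1)(log x − log τ) is a likelihood-ratio-style transform that
is positive exactly below the significance threshold τ. Its key property is
*sign-calibration*: however τ is chosen, the positive/negative split of the
network is exactly the p < τ split, and magnitudes grow with distance from
τ on the log scale.

Interactions are scored by the sample covariance of the two member
expression profiles, corr(X,Y)·std(X)·std(Y), computed over **all** samples
(both conditions pooled; pooling maximizes n and reads the score as overall
co-variation — a per-condition variant would halve the sample size without
changing the pipeline's structure). A subnetwork's edge total standardizes
each member edge against the mean and standard deviation of **the full
matched network's** edge scores, frozen at scoring time, so modules of
different sizes are compared against one background.

## Parameter summary

| parameter | default | meaning |
|---|---|---|
| `fdr` | calibrated | false-discovery rate that sets τ via the BUM inversion |
| `target_positive_fraction` | 0.15 | calibration target: fraction of genes scoring positive |
| `test` | `welch` | per-gene two-group test (`student` pools variances) |
| `AnnealConfig.threshold` | 0.8 | strong/weak cut on the absolute standardized edge score \|z\| |
| `AnnealConfig.t_initial/t_final/cooling/steps_per_temp` | 1.0 / 1e−3 / 0.95 / 100 | geometric annealing schedule (≈13 500 proposals) |
| `quantile` | 0.9 | within-module degree quantile for the common-gene rule (strict >) |
| `min_regions` | all | regions a candidate common gene must appear in |
| `exclude_shared` | off | also remove cross-region shared genes before specific re-extraction |

FDR calibration picks τ* halfway between the k-th and (k+1)-th smallest
p-value, k = ⌈target·n⌉, so exactly k genes score positive on tie-free
input; the matching FDR is read off the model curve π_UB·τ/F(τ). For real
data the six-region Alzheimer analysis the defaults descend from fixed the
FDR per region at 0.008/0.004/0.0007/0.01/0.06/0.09 (HIP/EC/MTG/PC/SFG/VCX),
values chosen there to leave roughly 15% of nodes positive; these ship as
`REGION_FDR_DEFAULTS` for documentation, while calibration automates the
same criterion.

## Extraction heuristic

Maximum node-weight connected subgraph is NP-hard (a prize-collecting
Steiner relative), so extraction is heuristic:

1. node scores as above;
2. edge weights w(u,v) = −(s(u)+s(v)) — the MST then prefers high-scoring
   corridors;
3. Kruskal MST per connected component (hand-rolled ~15-line Kruskal purely
   to guarantee lexicographic tie-breaking, hence bit-reproducible trees);
4. the minimal subtree spanning all positive nodes (union of pairwise tree
   paths, collecting the negative connectors);
5. re-span the induced subgraph on that candidate set and take the **exact
   maximum-score subtree** by rooted dynamic programming (children
   contribute only when strictly positive).

Step 5 deliberately strengthens plain negative-leaf pruning: pruning alone
cannot discard an expensive interior bridge (on the path +2 / −5 / +2 it
returns a module of total −1), while the tree DP guarantees the output never
scores below the best single node. `prune_negative_leaves` is retained as a
public operation for the weaker rule. With no positive node anywhere, the
single best-scoring node is returned (flagged). All ties — MST edges, DP
roots, component choice — resolve lexicographically on gene id:
reproducibility is preferred over optimality. A brute-force enumeration
oracle (`oracle_max_subnetwork`, ≤14 nodes) provides exact optima for
validation; on random ≤12-node instances the heuristic averages well above
80% of the optimum and can never exceed it.

## Annealing and the strong/weak threshold

The annealer performs Metropolis search over connected subnetworks around
the extracted module: moves add a one-hop network neighbor or remove a
non-articulation member; the objective is node-score total plus the
standardized edge total of the induced edges; acceptance min(1, exp(Δ/T))
with geometric cooling; the best state seen is returned, so the reported
objective never falls below the start. Removal proposals hitting an
articulation point are rejected outright, keeping connectivity invariant
cheap. The schedule defaults are conventional; all knobs sit in
`AnnealConfig`, and runs are exactly reproducible from `seed`.

The final filter applies the 0.8 threshold to |z| = |(score_e −
mean)/sd| — the raw covariance scale is data-dependent, so the cut is made
on the background-standardized scale (a raw-scale variant would simply
change the threshold's units; the configurable threshold value itself is
kept at the published 0.8). Strong member–member network edges are added;
weak ones are removed weakest-first unless removal would disconnect the
module, in which case they are kept and flagged `weak_bridge`. The rule is
idempotent and never changes the node set.

## Common and specific modules

Common genes are candidates present in (by default) every region's module
whose within-module degree **strictly exceeds** that region's empirical 90%
degree quantile (type-1 order statistic, ⌈q·n⌉-th smallest). Specific
modules re-run extract → anneal → filter after deleting the common genes
(optionally also all cross-region shared members; off by default because
with modules of the size this pipeline produces, many genuinely
region-specific genes appear in other regions' modules as background
members and would be deleted with them). If no positive node survives the
deletion, the region's specific result is an empty module flagged
`no_specific_module` — the expected outcome for a region whose entire
signal is shared. Regulation calls (up/down/unchanged) use a Welch test at
α = 0.05 on the case−control mean difference.

A structural note on the degree rule: at most ⌊(1−q)·n⌋ of an n-node
module's members can strictly exceed its q-quantile of degrees, so the rule
can return at most ~10% of each module's size. It is a *hub selector*, not
a general membership test; recovering a planted common core of size c
requires every region module to exceed ~10·c nodes with the core occupying
the top-degree slots.

## Synthetic data: what it emulates, and what it does not

The generator builds a connected preferential-attachment (Barabási–Albert)
gene network (default 300 genes, mean degree ≈4), plants one common module
(default 10 genes) and one specific module per region (default 8), and
simulates genes × samples matrices (default 10 control + 10 case):

- background genes are i.i.d. N(0, 1) in every sample, so their Welch
  p-values are Uniform(0, 1) — the BUM noise component;
- signal genes (common ∪ region's specific) get case means shifted by
  `effect_delta` (default 2), concentrating p-values near 0 — the β-like
  signal component;
- each active module shares a per-sample latent factor with loading
  `coexpr_rho` (default 0.7), inducing positive co-expression along planted
  edges — strong standardized edge scores.

Module node sets grow by seeded random walks with rejection for
disjointness; the induced subgraphs are then *densified* (common to ≥5
intra-module partners per member, specific to ≥3), because a random walk on
a sparse scale-free graph traces a tree, and a tree-shaped "module" carries
no connectivity signal for the degree-based common-gene rule to detect —
real functional modules (complexes, pathway cores) are densely
interconnected, which is what the densification emulates. Everything is
exactly regenerable from (parameters, seed); per-region streams derive from
the master seed.

Not emulated: probe-level artifacts, heavy-tailed expression noise,
condition-dependent covariance beyond the planted factors, degree-dependent
expression effects, or realistic (HPRD-scale) network size. Passing the
planted-module benchmark therefore demonstrates correct mechanics of the
chain under its own model assumptions, not performance on real microarray
data.

## Benchmark behaviour and known limitations

On the default generator the chain recovers planted *membership* well
(planted genes are almost always inside the extracted modules, and
common-gene precision is ≈1), but two quantitative limits follow from the
design itself and show up in the recovery benchmark:

- **Calibration/signal mismatch.** Calibrating to 15% positive nodes when
  only 6% of genes carry planted signal leaves ~27 background genes per
  region with genuinely positive scores. A score-maximizing extractor —
  the exact oracle included — profitably absorbs nearby background
  positives, so specific modules carry roughly as many background genes as
  planted ones (measured median specific-module F1 ≈ 0.28 at the default
  effect size; F1 rises monotonically with `effect_delta`).
- **Quantile cap.** By the arithmetic above, the 90%-quantile rule cannot
  return more than ~⌊0.1·n⌋ genes from an n-node module; with ~35–70-node
  modules this caps common-gene recall near 0.3–0.5 (measured median
  common-gene F1 ≈ 0.33) even though precision is ≈1. Larger modules would
  raise the cap but dilute specific modules further — the two effects pull
  in opposite directions.

Both are properties of the published scoring/selection rules under these
study conditions, not of the implementation: the heuristic tracks the exact
small-instance oracle, the mixture MLE recovers (a, λ) to ±0.05 at
n = 5000, and calibration hits its target fraction to 1/n. Users targeting
sharper module recovery should either calibrate the positive fraction to
their expected signal fraction or lower the common-gene quantile.

## Numerical choices

- Natural logarithm in the node score (sign and ranking are base-invariant).
- BUM fitting: bounded L-BFGS-B on (a, λ) ∈ (0,1)×[0,1) from five fixed
  starts; the pure-uniform boundary (log-likelihood 0) is enforced as a
  lower bound, so the fit never reports worse than the nested null.
  Deterministic given the input.
- Zero-variance profiles score 0 on edges (never NaN); genes flat in both
  groups get p = 1, hence negative scores.
- p-values are clipped into (0, 1] at the smallest positive double.
- Welch tests with unequal group sizes require ≥2 samples per condition and
  are computed vectorized over genes.
- Empty subnetworks are legal flagged values, not exceptions, everywhere
  downstream of extraction.
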