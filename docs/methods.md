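# Methods

## The composite network

Three node layers — genes, phenotypes, metabolites — are joined by six
weighted sub-networks: undirected within-layer association networks
(gene–gene, phenotype–phenotype, metabolite–metabolite) and bipartite
cross-layer networks (gene–metabolite, phenotype–gene,
phenotype–metabolite). Weights are non-negative confidence scores; the
package accepts any non-negative scale and performs no rescaling, because
the transition matrix normalizes per block anyway. The noise model (below)
does assume weights in [0, 1] and warns otherwise.

Edge lists are canonicalized on load: zero-weight edges dropped, undirected
pairs stored once with the smaller id first, self-loops rejected in
within-layer lists, and duplicate pairs merged keeping the **maximum**
weight — the natural reading for confidence scores, where a repeated
observation should not dilute the stronger evidence. Node indices are the
union of all ids seen per layer, so a node referenced only by a cross-layer
list is registered (isolated within its own layer) and remains a legal
candidate; ids are layer-scoped, so the same string in two layers denotes
two distinct nodes.

## The walk

The steady state of

    p_{k+1} = (1 − α) W p_k + α p_0

scores every node's proximity to the seed set. Iteration stops when the L1
change drops below `tol` (default 1e-10, the usual convention for
restart-walk gene prioritization; the walk contracts at rate 1 − α, so the
distance to the fixed point at stopping is about `tol/α`). A direct sparse
solve of `p = (1 − α)Wp + αp_0` is provided as an independent oracle and is
guarded to 20,000 nodes.

### Transition matrix

`W` is column-stochastic: column `j` holds the distribution of moves out of
node `j`, and `W` left-multiplies the probability vector (entry `(i, j)` is
the probability of stepping `j → i`) — stated explicitly because transpose
bugs are the classic failure mode here. Outgoing mass is budgeted per block
with the jumping probabilities: from a gene, `x` to phenotypes and `y` to
metabolites; from a phenotype, `x` to genes and `z` to metabolites; from a
metabolite, `y` to genes and `z` to phenotypes; the remainder stays within
the layer. Budgets must satisfy `x + y ≤ 1`, `x + z ≤ 1`, `y + z ≤ 1`.
Within each destination block mass is proportional to edge weight, which
makes the transition invariant to rescaling any single sub-network.

Two fallback rules keep columns stochastic when a node lacks edges in a
budgeted block:

* **R1** — mass budgeted for a cross block with no edges is reassigned to
  the within-layer block (the standard two-network heterogeneous-RWR
  convention, extended here to three layers).
* **R2** — if the within-layer block is also empty, the within-layer mass
  is split among the present cross blocks proportionally to their nominal
  budgets (equally when those budgets are all zero).

These rules are a reconstruction: the published description of this scheme
renders its transition equations as unreadable figure placeholders, so the
block-normalized form above was rebuilt from the standard
heterogeneous-walk convention it extends. Users comparing against other
implementations should check this choice first.

A node with no edges anywhere gets an all-zero column ("dangling"), keeps
only its restart mass `α·p_0`, and is listed in the transition's dangling
report. Iterates then sum to slightly less than 1 if a dangling node
carries seed mass; no renormalization is applied, since ranking is
unaffected.

### Initial vector

Gene seeds share mass `a`, phenotype seeds `b`, metabolite seeds
`1 − a − b`, equally within each layer. Mass budgeted for a layer with no
seeds is redistributed proportionally to the seeded layers (equally if the
seeded layers' nominal weights are all zero), so `p_0` always sums to 1.

### Parameters

| parameter | meaning | default |
|---|---|---|
| α | restart probability (locality of propagation) | 0.7 |
| x, y, z | cross-layer jumping probabilities | 1/3 each |
| a, b | seed-layer weights (gene, phenotype) | 1/3 each |
| tol | L1 stopping threshold | 1e-10 |
| max_iter | iteration cap (non-convergence warns, never silent) | 1e6 |

The defaults follow the published configuration of this method (α = 0.7
with equal thirds elsewhere). α between 0.5 and 0.9 is reported there as a
stable plateau; `parameter_sweep` reproduces that protocol on any dataset.

## Ranking and significance

Candidates are the metabolome minus the metabolite seeds (or an explicit
list, or `k − 1` random non-seeds plus a designated metabolite). Ranks are
descending by score, exact ties broken lexicographically by id and flagged.

Permutation p-values rewire each of the six sub-networks independently by
double-edge swaps — within-layer swaps preserve the within-layer degree
sequence, bipartite swaps preserve both sides' sequences, weights travel
with their edges — then draw a random seed set with the observed per-layer
seed counts and re-run the walk. Default 10 attempted swaps per edge
(capped retries; sub-networks with fewer than two edges are left
unchanged); the exact swap count is a convention and is exposed as a flag.
The add-one estimator `p = (1 + #{null ≥ obs}) / (1 + n_perm)` never
returns 0 and puts p on the grid `[1/(n_perm+1), 1]`; 1000 permutations is
the conventional default. Null seeds are drawn per layer with the observed
per-layer counts, preserving the layer composition of the seed signal.

## Validation

Leave-one-out cross-validation hides one known phenotype–metabolite link
per fold (asserted gone from the fold's network), rebuilds seeds from the
remaining knowledge, and records the held-out metabolite's rank among the
candidates. Three seed-ablation modes: `full` (phenotype + genes + other
known metabolites; phenotype + genes when no other metabolite is known),
`metabolite_seed_only_baseline` (metabolite sub-network and metabolite
seeds only — the single-network comparator; folds with no remaining
metabolite seed are skipped), and `no_known_metabolites` (all of the target
phenotype's metabolite links removed; phenotype + genes as seeds).

Scores from folds run on different networks are not comparable, so folds
are pooled on per-fold normalized ranks, and

    AUC = mean over folds of (n_candidates − rank)/(n_candidates − 1)

is the reference definition — the Mann–Whitney probability that the
held-out metabolite outranks a random negative. Ties enter with midranks,
so a degenerate ranking (e.g. α = 1, where the steady state is `p_0` and
all unseeded candidates tie) scores exactly 0.5. Per-fold networks are
cloned logically (the held-out entries zeroed in a copied sparse block),
observationally equivalent to a fresh network. Class-stratified AUC
recomputes the same statistic per disease-class label and reports the
across-class mean ± SE.

The noise protocol mixes every weight with uniform noise,
`w' = (1 − σ)w + σ·U(0,1)`, perturbing each undirected edge once. Within
one sweep all σ values share the same uniform draws (common random
numbers), so the AUC-versus-σ curve varies smoothly with the noise
proportion rather than with stream-to-stream chatter; replicates change the
stream seed.

## The synthetic generator

Background layers are Erdős–Rényi at densities gene 0.015 / phenotype
0.05 / metabolite 0.04 with Beta(2, 5) weights (skewed toward low
confidence, as in thresholded confidence-score networks); cross-layer
background links at density 0.002. Each of 10 diseases gets a phenotype
wired to 5 true genes and to the known subset (80%) of 8 true metabolites;
true genes interconnect at density 0.4, true metabolites at 0.12, and
genes-to-metabolites at 0.3, with module weights `min(1, 5·w)` — the
multiplier is the `signal_strength` knob, clipped so weights stay on the
[0, 1] scale the noise model assumes. Default layer sizes 300/30/200.

Two deliberate design points. First, the metabolite module is much sparser
than the gene module: curated metabolite associations are the most
incomplete of the three layers, and this is exactly what makes the
integrated walk outperform the metabolite-only baseline — a generator with
a near-clique metabolite module saturates both modes at AUC ≈ 0.99 and
shows no integration benefit. Second, a substantial share of the planted
signal is carried by the up-weighted confidence scores rather than by
topology alone, so the weight-noise protocol has something to destroy; with
purely topological signal the noise sweep is flat. With
`signal_strength = 1` and module densities set equal to the background the
generator is an exact null (module weights reduce to `min(1, w) = w`), used
for calibration checks.

What the generator does **not** emulate: heavy-tailed degree distributions
(real interactomes are scale-free; the within-layer model is Erdős–Rényi
with a hook for alternatives), database-specific weight scales (0–1000
STRING-style scores are accepted by the I/O but not generated), near-dense
phenotype similarity matrices, and correlated errors between layers
(false-positive edges in real data are not independent). Passing the
planted-recovery tests therefore shows the machinery is correct and the
comparative ordering of the ablation modes holds under the stated
conditions — not that the absolute AUC values transfer to any real
composite network.

## Problem sizes and numerical choices

The validation and robustness protocols run at the generator's default
scale (530 nodes, ~2,000 edges, 60 LOOCV folds; 5 generator replicates for
the headline AUCs, 10 noise replicates, 150–200 permutations), which gives
standard errors of roughly 0.01 on an AUC while keeping a full run in tens
of seconds. Degenerate inputs are handled explicitly: empty networks warn
on construction and are rejected by the transition builder; folds with
fewer than two candidates are skipped with a warning; an α of exactly 1
short-circuits both the iteration (one step) and the closed form (`p_0`).

Known limitations: monotone "closer-to-seed means higher score" intuition
holds only when restart is non-negligible — as α → 0 the steady state
approaches the degree-biased stationary distribution and a high-degree
interior node can outrank a seed's direct neighbor (observable already on a
4-node path at α ≤ 0.15). The double-edge-swap sampler is the standard
approximate-uniform rewiring, not an exact uniform sampler over the degree
sequence's graph space; and permutation p-values inherit the granularity
`1/(n_perm + 1)`.
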