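# Methods

This note documents the model, the algorithmic and numerical choices,
and what the synthetic benchmarks do and do not demonstrate.

## Differential co-expression networks

One weighted, undirected network is built per disease condition over a
common ordered gene set. Edge presence is decided on the condition's
expression matrix alone: a gene pair (i, j) qualifies when its absolute
Pearson correlation reaches the threshold δ **and** the minimum, over
conditioning genes z, of the absolute first-order partial correlation

    r_ij·z = (r_ij − r_iz r_jz) / sqrt((1 − r_iz²)(1 − r_jz²))

also reaches δ. Taking the minimum over all z is the conservative
reading of "first-order partial correlation screening": an edge
survives only if no single third gene can explain it. Conditioning
genes whose denominator falls below 1e−12 (numerically collinear) are
skipped and counted. Above 2000 genes the conditioning set is capped at
the 200 genes most correlated with either endpoint, because exhaustive
first-order screening is cubic in the gene count.

Edge weights encode differential expression of the endpoints:

    w_ij = sqrt(−log p_i − log p_j) / sqrt(2 · max_l |log p_l|)

with natural logarithms and p_i the differential-expression p-value of
gene i versus baseline (produced by any DE tool; the package consumes a
table and ships a Welch-t fallback in the generator). Weights lie in
(0, 1], reaching 1 exactly when both endpoints attain the global
minimum p-value. p-values below 1e−300 are clamped at load time so the
logarithm stays finite. δ defaults to 0.8 and can be chosen from a grid
as the largest value maximizing the number of genes connected in every
network simultaneously.

## Module discovery

**Seed ranking.** In each network, gene importance is the principal
eigenvector of the symmetrically degree-normalized weighted adjacency
A′ = D^−1/2 A D^−1/2 — the fixed point of the propagation g = A′g, in
which a gene is important when it has many strong neighbors that are
themselves important. On a fragmented network the eigenproblem is
degenerate (every component has eigenvalue 1), so the eigenvector is
computed per connected component and each component's block is scaled
by its share of total edge weight; this reduces to the global
eigenvector on a connected network and lets every strong component
contribute seeds on a fragmented one. Components up to 500 nodes are
solved densely (LAPACK `eigh`); larger ones by power iteration on
(A′ + I)/2, whose shift removes the −1 eigenvalue of bipartite
components that would otherwise make the iteration oscillate.
Importances are z-scored per network over the active genes (degree ≥ 1
somewhere), averaged across the networks searched, and the top 10%
become seeds.

**Graph entropy.** For a gene set C, network k and member i, let
p_ik be the fraction of i's weighted degree that stays inside C
(0 for an isolated gene). The module score is

    H(C) = Σ_k Σ_{i∈C} h(p_ik) / |C|,   h(p) = −p ln p − (1−p) ln(1−p).

H is 0 when every member's weight is entirely inside (or entirely
outside) the module in every network and is maximal when memberships
are maximally ambiguous (p = 1/2).

**Greedy expansion.** Each seed is expanded by strict steepest descent
on H: among genes adjacent to the current module in at least one
network, add the one decreasing H most; stop when no addition decreases
it. Two consequences of the entropy's shape dictate the remaining
choices:

- *Initialization.* h peaks at p = 1/2, so from a two-gene start inside
  a densely interconnected group every addition raises H (each member's
  in-fraction climbs toward 1/2 from below) and strict descent could
  never grow the module. Expansion therefore starts from the seed's
  closed neighborhood, which lies on the far side of the entropy
  barrier; descent then sharpens the boundary.
- *Scale bound.* H(C) is exactly 0 for any union of whole connected
  components (including the whole graph), so an unbounded search on a
  randomized network simply absorbs everything reachable and reports a
  "perfect" module. Module size is therefore bounded by half the active
  gene set (configurable), applied identically to real and null
  searches. A gene set spanning most of the network is not a module.

All ties (seed order, candidate additions, merges) break by
lexicographic gene or candidate identifier, making the whole search
deterministic.

**Refinement.** Candidates below 5 genes are dropped; overlapping
candidates merge greedily by Jaccard index at threshold 0.5, with the
union's entropy recomputed.

**Multi-network catalog.** Every non-empty subset S of the M networks
is searched (guarded at M ≤ 6). A candidate counts as present in S only
if its induced subgraph has at least one edge in *every* network of S —
without this membership rule, the p = 0 convention for isolated genes
would let any single-condition module score identically on every
superset of its true subset and inflate its level. After significance
filtering, each module is assigned its maximal subset: a module
significant for S is discarded when a module significant for a strict
superset of S matches it at Jaccard ≥ 0.5. Modules surviving with
|S| = m are the level-m catalog.

## Significance

Each subset's candidates are tested against modules found on
randomized networks: every network of S is rewired by double-edge swaps
(10 attempted swaps per edge), which conserves each gene's unweighted
degree exactly; the edge-weight multiset is then randomly permuted over
the rewired edges. The full search reruns with identical parameters on
each of the (default 100) randomizations, and the entropy scores of all
expanded candidates are pooled — before the minimum-size drop and the
merging step, because at the problem sizes of the shipped benchmarks a
randomized network almost never yields a ≥ 5-gene candidate and the
null pool would otherwise be empty. The empirical p-value is the
add-one estimate

    p = (1 + #{null scores ≤ H_observed}) / (1 + #null scores),

low entropy being the extreme direction. Benjamini–Hochberg correction
is applied jointly across all subsets' modules (the conservative choice
of family) and modules pass at adjusted p ≤ 0.05.

## Connectivity dynamics

A module shared by ≥ 2 networks has one induced weighted adjacency
matrix per network (canonical gene order). Its connectivity-dynamics
score averages, over network pairs, the spectral norm (largest singular
value) of the matrix difference divided by the module size; a Frobenius
variant and an adjacent-pairs pairing (input network order) are
available, the latter coinciding with all-pairs for two networks. The
score is 0 exactly for identical matrices and scales linearly with a
global rescaling of the weights.

Significance uses size-matched random gene sets drawn uniformly from
the genes connected in at least one of the module's networks (default
100 draws), one-sided toward large scores; BH correction across shared
modules; "dynamic" at adjusted p ≤ 0.05 (the cutoff is a flag, 0.01
being a common stricter choice). A desk-scale limitation: random gene
sets carry few internal edges, so they absorb none of the edge-weight
estimation noise that a coherent module accumulates from finite
replicates; a tightly connected but genuinely static module shared by
three networks can therefore sit near the 0.05 boundary.

## Module statistics

- *Mean edge weight* averages a module's present internal edges
  (absent pairs carry structural zeros and would conflate sparsity with
  differential activity; a dense variant including them is a flag).
- *Module activity* is the mean over members of per-gene z-scored
  expression (z across all samples), averaged within each
  (condition, time) cell.
- *Regulation calls* test, per (condition, time), the per-gene mean
  differences versus baseline with a two-sided one-sample t-test (genes
  as units; replicate-level Welch pooling is a flag), calling up/down at
  p < 0.01.
- *Phenotype correlation* is Pearson across matched (condition, time)
  cells, restricted to the module's own conditions; fraction-type
  measures with inverted clinical polarity can be replaced by 1 − value
  and z-scored per measure before correlating.
- *Enrichment* is the upper-tail hypergeometric overlap against
  reference gene sets with BH at 0.05; specificity = fraction of
  modules hitting ≥ 1 set, sensitivity = fraction of sets hit by ≥ 1
  module; catalog-level comparisons use one-sided Fisher tests on
  significant/total counts.

## Synthetic ground truth

The generator plants modules with a rank-2 latent structure: member g
of a module active in condition c takes
baseline_g + β(cos θ_g f1 + sin θ_g f2) + effect_c(t) + σ ε, with
factors drawn fresh per sample. Pairwise member correlation is then
≈ cos(θ_i − θ_j), so a compact angular arc plants a near-clique at
δ = 0.8. Two latent dimensions are essential, not cosmetic: genes
driven by one shared factor are conditionally independent given any
other member (the first-order partial of an equicorrelated pair is
ρ/(1+ρ) ≤ 1/2), so the screen would — correctly — delete every edge of
a single-factor module. With two factors the first-order partial stays
near ±1 whatever single gene is conditioned on. The within-module noise
σ defaults to 0.002 because a conditioning gene nearly collinear with
an endpoint otherwise drags the sampled partial below δ; planted
modules are therefore near-deterministically co-regulated, which is the
regime in which a min-over-z first-order screen can retain them at all.

Rewired ("dynamic") modules consist of two tight-arc halves that are
well separated in one condition and merge into one evenly spaced band
in the other: the within-half edges persist everywhere while the dense
cross-block between halves appears and disappears — sub-pathways that
split and merge. Static modules keep one arc everywhere. The phenotype
is a noisy weighted sum of the *dynamic* modules' per-cell activity, so
the dynamic-versus-static correlation contrast is planted by
construction; the dynamics fixture uses a 6-point time course because
with fewer than ~12 matched cells the magnitude of a pure-noise
correlation (≈ 0.8/√n) would swamp the contrast.

Fixtures additionally carry many 4-gene DE-less "decoy" co-expression
clusters. They emulate the fact that real co-expression networks keep
hundreds of genes connected outside the disease modules, and they
matter mechanically: the seed count is 10% of the *active* genes, and
with only the planted modules active the handful of seeds all land in
the single strongest module — an artifact of desk scale, not of the
method. Planted module sizes are distinct per condition subset so no
two network components tie in mass.

Shipped designs: `tiny` (60 genes, 3 disease conditions + baseline,
2 time points × 3 replicates), `small` (300 genes, 4 × 4 design; the
recovery benchmark), `large` (2000 genes, 3 × 4 × 4), and the
`rewiring` design (240 genes, two rewired + two static shared modules,
6 time points). β = 0 switches any design into its no-co-expression
null. Expression values are Gaussian on a normalized-abundance-like
scale (baselines uniform in [30, 60]), not counts; DE p-values come
from per-gene Welch t-tests of all condition samples against baseline.

**What passing means.** The benchmarks show that the implementation
recovers planted structure of the assumed form (near-noiseless rank-2
co-regulation, clean condition-subset membership, structured rewiring)
and that its permutation machinery is calibrated on pure-noise
networks. They do not show robustness to the noise levels, correlation
structure, count distributions, or batch effects of real RNA-Seq data,
nor do they validate the min-over-z partial screen as a good edge
detector at realistic noise — at moderate noise that screen is severely
conservative by design.

## Numerical and determinism details

- All randomness flows from one configured seed, split per stage with
  `numpy.random.SeedSequence`; module tables are byte-identical across
  reruns of the same configuration.
- Strict descent uses a 1e−12 margin; empirical-p tie comparison adds
  the same epsilon on the observed score (ties count against the
  module).
- Benchmark problem sizes (300-gene recovery study, 100 permutations,
  100 null draws, three calibration repeats at 100 genes) were chosen
  so the full suite runs comfortably on a laptop-class single core.
- Degenerate inputs: all-ones p-value tables, edgeless networks, and
  modules without internal edges are rejected or reported as missing
  values rather than silently scored; subsets containing an edgeless
  network are skipped with a warning.
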