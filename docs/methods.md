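# Methods

## Model

`bimod` scores and detects *paired* community structure in directed
graphs.  A configuration of K sending communities C_out,k mapped onto K
receiving communities C_in,k is scored by the bimodularity index

    Q_bi = (1/m) Σ_k Σ_{i∈C_out,k, j∈C_in,k} (A_ij − k_out,i k_in,j / m),

the excess directed edge weight running from each sending set to its
paired receiving set relative to a directed configuration model that
preserves out- and in-strengths.  The inner term defines the directed
modularity matrix B; all of B's rows and columns sum to zero, so the
trivial whole-graph community always scores exactly zero, and on a
symmetric graph with coinciding partitions the index equals classical
Newman modularity (the directed m counts each undirected edge twice,
which absorbs the usual factor-of-two difference).

Two modelling assumptions follow from the null: (i) edge placement is
explained entirely by out-/in-strength products — no degree correction
beyond that, no spatial or metadata priors; (ii) for weighted graphs
"fraction of edges" is read as *fraction of total edge weight*.  The
weighted reading degenerates exactly to the binary case on 0/1 matrices,
which is the primary intended input.  Self-loops are accepted (with a
warning) and enter degrees and m; the synthetic generators never emit
them.

## Optimization

For two communities the index is the bilinear form (1/2m) s_outᵀ B s_in
over ±1 vectors.  Relaxing both vectors to the unit sphere makes the
stationary points the singular vector pairs of B, so the top-N SVD
components are the N best relaxed bipartitions, with
Q_bi(u_k, v_k) = σ_k / 2m.  The implementation uses one route only — the
SVD of B (LAPACK, dense) for n ≤ 2000 and a seeded truncated Lanczos
solver (`scipy.sparse.linalg.svds`) above that; the mathematically
equivalent eigendecompositions of BBᵀ/BᵀB are not implemented.

Sign conventions, because (u_k, v_k) → (−u_k, −v_k) leaves the SVD
invariant:

* **Orientation** (determinism): each pair is jointly flipped so that the
  entry of u_k with the largest absolute value is positive (ties resolved
  to the lowest index).  Repeated runs on identical input give bitwise
  identical vectors.
* **Reported sign**: the component's signed value is
  sign(u_k·v_k) · σ_k — positive when sending and receiving profiles
  align (assortative structure), negative when they anti-align
  (disassortative).  |u_k·v_k| < 1e−10 is treated as positive (exact
  zero occurs in small structured examples).  The signed value is
  reporting metadata only; all downstream computation uses σ_k ≥ 0,
  and joint column sign flips are isometries for k-means, so the
  convention cannot alter detection.

## Detection

Each structural edge (i, j) — edges are enumerated in row-major order of
A, the canonical ordering shared with ground-truth labels — is embedded
as

    f(i, j) = (σ₁u₁[i], σ₁v₁[j], …, σ_N u_N[i], σ_N v_N[j]),

i.e. the source node's sending coordinates and the target node's
receiving coordinates, each scaled by its singular value.  The scaling
weights components by how much bimodularity they carry, which stabilizes
the result against the choice of N.  k-means (k-means++ initialization,
20 restarts, fixed seed) partitions the edges into K clusters; labels are
renumbered by descending cluster size so reports are deterministic.  By
default every structural edge contributes one unit row regardless of
weight (the intended inputs are binary); `weight_samples=True` switches
to weight-proportional k-means sample weights.

Each edge cluster yields one bicommunity: its sending set C_out is the
cluster's source nodes, its receiving set C_in the target nodes.  The
per-cluster index is the **full block sum** (1/m) Σ_{i∈C_out, j∈C_in}
B_ij — the cluster's blocks plugged into the index definition — rather
than a sum over only the cluster's own edges; when clusters' blocks are
edge-disjoint the per-cluster values add up to the Q_bi of the induced
K-community mapping, which the block sum preserves and the per-edge
variant would not.  (`extract_bicommunities` accepts any labelling, so
the per-edge variant can be computed by summing `B` over a cluster's edge
list if wanted for comparison.)  A cluster is classified `self`
(conventional community) when Jaccard(C_out, C_in) ≥ 0.5 and `directed`
otherwise; 0.5 is the natural midpoint between fully overlapping and
disjoint and is exposed as `bicommunity.SELF_JACCARD`.  Per node and
cluster, the send–receive score (w_out − w_in)/(w_out + w_in) over the
node's cluster-incident edge weight summarizes its role (+1 pure sender,
−1 pure receiver), with categorical roles sending / receiving / both.

N and K are free parameters, deliberately not auto-selected.  Defaults
N=2, K=8 match the benchmark below; real analyses should scan them.

## Synthetic benchmark generator

The directed stochastic-block generator emulates block-structured binary
directed graphs.  Within each block, every unordered node pair receives
an edge with probability `p_within` and a single direction (lower→higher
index with probability `p_dir`, default 0.5, where the convention is
immaterial).  Between blocks a and b, the unordered pair is drawn once
with probability P[a,b] + P[b,a] and oriented a→b with probability
P[a,b]/(P[a,b]+P[b,a]); for the usual one-sided case this is "draw with
p_con, orient along the prescribed structure".  Drawing unordered pairs
first guarantees no bidirectional pair and no self-loop ever occurs, and
makes the symmetrization A + Aᵀ a binary undirected SBM with exactly the
requested densities.  Source/sink-dominated blocks are obtained by
filling only a row (or column) of P for that block.

The benchmark configuration is the **block cycle**: 4 blocks of 50
nodes, `p_self = p_con = 0.3`, `p_dir = 0.5`, between-block edges
oriented around the cycle.  Expected edge count 4470 over 14 900
candidate pairs; ground truth has 8 edge classes (4 within-block, 4
cycle).  What the generator does *not* emulate about real directed
networks: reciprocated (bidirectional) connections, weight heterogeneity,
broad degree distributions, and overlapping ground-truth communities — so
passing the benchmark demonstrates correct recovery of planted
block-directional structure, not robustness to those features (the
C. elegans network, with 11% reciprocated connections, is the real-data
check of the first two).

## Numerical choices

* Floating-point identity checks are at 1e−9 relative to m.
* The brute-force bipartition oracle enumerates all ±1 vector pairs up to
  global sign (s_out[0] fixed to +1), refuses n > 12, and breaks ties to
  the lexicographically smallest pair (+1 ordered before −1); it exists
  as an independent check of the spectral route and satisfies
  Q_bi* ≤ n σ₁ / 2m (discrete vectors have norm √n).
* Degenerate spectra: when σ_k is (numerically) repeated, the SVD basis
  within the degenerate subspace is solver-dependent, and on symmetric
  inputs such subspaces can mix eigenvectors of opposite-sign
  eigenvalues, so per-column identities (u = ±v, signed value =
  eigenvalue) are only guaranteed for simple singular values.
* k-means ties and label symmetry are fixed by seed + size-ordered
  relabelling; all reported orderings (components by σ, bicommunities by
  per-cluster index, ties by cluster id) are total.
* Dense B throughout (target graphs are ≤ a few thousand nodes); a
  factored A-minus-rank-1 representation is a noted future optimization.

## Problem sizes used in the checks

The shipped test suite and `scripts/acceptance.py` run the benchmark at
its native size (200 nodes, ≈4500 edges) over 20 seeds, the algebraic
identity suites on 100 random graphs with n ≤ 20, and the exhaustive
oracle on 50 random graphs with n ≤ 8 — the full configuration completes
in well under a minute.  Median edge-label recovery (ARI) on the
benchmark is 1.0 at these settings; the acceptance script reports the
median count of detected directed bicommunities (4 when recovery is
complete).

## Known limitations

Inherited from modularity: a resolution limit (small communities below
it are absorbed), and dependence on the configuration-model null.  Added
by the pipeline: K and N must be chosen by the user; k-means imposes
convex clusters in feature space; per-cluster indices use node *sets*, so
two clusters sharing many nodes double-count block overlaps.  The loader
aggregates parallel edges (no multigraph support) and the package does
not parse GraphML/GEXF.
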