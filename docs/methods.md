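# Methods

## Model

`drugwalk` scores candidate drug indications with a random walk with restart
(RWR) on a three-layer heterogeneous network of diseases, proteins and
drugs. The layers are coupled by six adjacency matrices (S1–S6, see the
README table). The modelling assumptions are:

- **Guilt by proximity.** A disease is a plausible indication for a drug if
  the drug's targets sit close to the disease's genes in the combined
  interaction/similarity topology. The stationary distribution of a
  restarting walker quantifies that proximity.
- **Short protein paths carry the signal.** Against a dense interaction
  background, a walker rarely reaches a node through three or more
  intermediate proteins, so the protein layer is pruned to proteins on
  disease–drug paths with one or two protein nodes before any matrix is
  built. Diseases and drugs with no retained neighbour are dropped. We
  prune first and restrict the similarity matrices to the survivors.
- **Similarity as mobility.** Within-layer edges (chemical similarity for
  drugs, semantic similarity for diseases, scored interactions for
  proteins) let the walker generalize across similar entities.
  Self-similarity diagonals of S4/S5 are zeroed before normalization so a
  node cannot hoard probability on itself.

## Similarity kernels

**Tanimoto.** Drug fingerprints are fixed-length (1024) binary substructure
vectors; similarity is |A∩B|/|A∪B| over the set bits. The 0/0 case (two
empty fingerprints) is defined as 0 — no evidence of similarity — and
logged. Fingerprints are consumed precomputed from a TSV (binary or hex
encoded); generating them from structures is out of scope.

**Lin.** Disease descriptors live at dot-delimited tree positions of a
MeSH-style hierarchy. The information content of a position t is
IC(t) = −log(|descriptors at or below t| / |all descriptors|), and
sim(a, b) = 2·IC(lca) / (IC(a) + IC(b)) with the longest-common-prefix
ancestor. Descriptors with several tree numbers take the maximum over
position pairs — the most favourable placement, a common convention for
MeSH similarity. Two terms whose only shared ancestor is a root (IC = 0)
score 0; the assembled matrix forces the diagonal to 1. A precomputed
(id_a, id_b, value) table can replace either kernel.

## Transition matrix

The nine blocks are the source adjacencies row-normalized to sum 1 on
non-empty rows (M_dp from S1, M_pd from S1ᵀ, M_pg from S2, M_gp from S2ᵀ,
M_pp from S3, M_gg from S4, M_dd from S5, and M_gd/M_dg from S6/S6ᵀ only
under the `full` strategy). The layer weights (a, b, c) then split each
source node's outgoing mass between destination layers, restricted to
layers where the node has any transitions and renormalized over those, so
every non-dangling row of the assembled matrix sums to 1. This
row-normalized-blocks / weight-split construction is the canonical
heterogeneous-RWR recipe and is deliberately isolated behind
`transition.build_blocks` / `weight_and_assemble` so alternatives can be
swapped in.

The final min–max normalization takes the minimum as the structural zero of
the sparse matrix, so it reduces to division by the global maximum entry
(the factor is stored). It preserves sparsity and the ordering of all
transition probabilities and speeds convergence, but makes the matrix
generally non-stochastic: the iteration contracts only while
(1 − r)·σ(M) < 1. Whether to normalize globally or per block was an open
choice; global is implemented. Dangling rows are left zero — the restart
term keeps the walk well defined.

## Seeds and propagation

The seed profile is p₀ = [a·u₀; b·v₀; c·h₀]: h₀ puts unit mass on the query
drug, v₀ is uniform over its retained targets, u₀ is zero without prior
knowledge and uniform over the drug's known diseases under `full`.
Uniform-within-block seeding follows the usual heterogeneous-RWR
convention. After weighting, p₀ is renormalized to sum 1, which amounts to
renormalizing over the weights of the non-empty blocks (e.g. a target-less,
prior-less drug seeds the drug node alone, with a warning); this keeps
stationary magnitudes comparable across drugs. If every weighted block is
empty (c = 0 and nothing else seeded) the bare drug node is used.

`propagate` applies p_{t+1} = (1−r)Mᵀp_t + r·p₀ literally — no
re-normalization during iteration — until the L1 change drops below `tol`
(default 1e-10; `max_iter` 10 000). Divergence is detected when the L1
change grows for 50 consecutive iterations and raised as a
`ConvergenceError` with diagnostics rather than looping. Ranking ties are
broken lexicographically by disease ID (documented, since any rule is
defensible); ranks are also reported as top-percent of the list.

Defaults a = 0.5, b = 0.4, c = 0.1, r = 0.7 are the refined operating
point of the method; the constraint a + b + c = 1 is enforced at
construction.

## Evaluation protocol

Each validation pair's true disease is re-ranked among `n_decoys` decoys
drawn uniformly without replacement from the disease universe minus the
drug's known diseases, independently per pair and repetition. The rank is
1 + (#decoys strictly higher) with **midrank** tie handling (half the tied
decoys; `best`/`worst` available as flags; half-integral midranks round up
when an integer rank is required). The ranking-ROC curve sweeps thresholds
k = 0..n_decoys+1 with sensitivity the fraction of pairs ranked ≤ k and
the false-positive rate the mean fraction of decoys in the top k; the
trapezoid area equals mean((n_decoys+1 − rank)/n_decoys) exactly for
integer ranks. The reported AUC is the mean over repetitions (default 50).

`n_decoys` defaults to 99 (ranks 1..100); on toy networks with fewer
diseases than that, a smaller decoy count is used and the AUC formula
scales accordingly — a shortfall of eligible decoys is an error, never a
silent truncation. The decoy pool is the full disease universe minus known
links (whether the original protocol restricted the pool is unknowable; the
full universe is the neutral choice).

The random baseline replaces each pair's disease with a uniform draw from
the same pool and runs the identical pipeline; its expected AUC is 50%.
Cross-validation partitions the pairs into folds (shuffled, round-robin),
removes each fold's links from S6, rebuilds the transition matrix and seeds
on the reduced prior, and evaluates the held-out pairs; a drug whose prior
links all fall in the held-out fold falls back to no-prior seeding
(logged). An accuracy-style statistic (`top_half_accuracy`, the fraction of
pairs ranked in the top half of their list) and a two-sided t-test over
per-repetition AUCs (`compare_models`) are provided as secondary summaries;
neither is a headline metric, since no canonical threshold rule accompanies
accuracy in a ranking protocol.

## Synthetic data

The generator emulates the *structure* of the real inputs at desk scale:
Bernoulli-independent background edges (no degree heterogeneity), uniform
interaction scores in [0.15, 1], sparse random fingerprints, and a
two-level MeSH-style tree with diseases under random root categories.
Defaults: 20 diseases, 60 proteins, 15 drugs, densities 0.05, 5 planted
pairs, signal 0.8. Each planted (drug, disease) pair is wired with
⌈signal·min(|targets|, |genes|)⌉ shared proteins (at least one while
signal > 0) and a prior-knowledge link; planted drugs share a fingerprint
bit block proportional to the signal. At signal 0 nothing is wired and the
planted pairs are indistinguishable from background.

What passing tests on this generator do **not** show: robustness to the
heavy-tailed degree distributions, correlated annotation biases, and
score calibrations of real curated databases, nor performance at the scale
of thousands of nodes per layer. They do show that the pipeline recovers an
engineered topological signal and returns to the 50% null without one.

## Numerical choices and problem sizes

- Node order is lexicographic by ID everywhere, making all matrices and
  rankings reproducible; all randomness flows from explicit seeds.
- Duplicate edges collapse to the maximum weight; PPI pairs are
  canonicalised (unordered) before collapsing. No score threshold is
  applied to interaction confidences by default.
- The propagation oracle tests compare the iterate against the dense
  linear solve r(I − (1−r)Mᵀ)⁻¹p₀ on networks of ≤ 50 nodes, in the
  contractive regime (1−r)·σ(M) < 1; outside it the tests assert that
  divergence is detected.
- Test and example runs use the default synthetic spec with 10 decoys and
  10–20 repetitions — sizes chosen so the whole suite exercises every code
  path on a laptop in seconds while leaving the statistical assertions
  (paired signal-vs-baseline wins, CLT bounds on the null) well-powered.

## Limitations

- The exact block construction and seed composition of heterogeneous RWR
  vary across the literature; the row-normalized / weight-split / uniform
  seed variant implemented here is one canonical choice, isolated behind
  the `transition` and `propagation` interfaces.
- Identifier mapping (UniProt, MeSH), live database retrieval, and
  fingerprint generation from structures are out of scope; IDs are opaque
  strings.
- Reverse (disease-to-drug) queries and alternative normalizations
  (Laplacian, symmetric) are not implemented.
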