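# Methods

## Problem setting

Given a binary drug–target interaction (DTI) network — a D×T adjacency
matrix A with a_ij = 1 for each approved interaction — together with a
drug–drug similarity matrix (typically chemical-structure based) and a
target–target similarity matrix (typically normalized sequence
similarity), the package ranks the unapproved drug–target pairs (DTPs,
a_ij = 0) by their plausibility of being true interactions. The working
assumption is guilt by association: similar drugs tend to bind similar
targets. Both similarity matrices are consumed precomputed; computing
them from structures or sequences is out of scope.

## Topological similarity: the matching index

Besides the input ("primary") similarities, a topological similarity is
derived from the network itself. The matching index between two drugs is

    MI(d_i, d_j) = (T − |d_i| − |d_j| + 2·|d_i ∩ d_j|) / T,

where |d| is a drug's degree and |d_i ∩ d_j| the number of shared
targets; the target-side formula swaps the roles and divides by D. MI
counts shared neighbours *and* jointly-absent neighbours, so it is a
complete metric on [0, 1]: identical neighbourhoods give 1, complementary
neighbourhoods spanning the whole opposite set give 0. Note that in
sparse networks the jointly-absent term dominates, so the MI baseline
between unrelated nodes is high (≈ (n − deg_i − deg_j)/n); this matters
for the limitations discussed below.

## Degree-adaptive combination

Topological similarity is most informative around low-degree nodes,
chemical/sequence similarity around hubs. The combined similarity used
when scoring the neighbourhood of an anchoring node of degree g is
selected by two thresholds over the anchoring side's degree vector,

    u = 0.5 · max(degrees),    l = mean(degrees),

with branches evaluated in fixed order: primary similarity if g ≥ u,
elementwise maximum of primary and topological if l < g < u, topological
if g ≤ l. The fixed order resolves overlapping boundaries (whenever
u ≤ l the middle branch is empty and g may satisfy both outer tests; the
primary branch wins at g = u = l). The mean includes zero-degree nodes
when present. A linearly weighted combination α·primary +
(1−α)·topological is provided as a baseline, and `primary`/`topo`
pass-throughs for ablations.

Anchoring convention: for a pair (d_y, t_x), drug–drug similarity lookups
are gated by deg(t_x) against target-degree thresholds, and target–target
lookups by deg(d_y) against drug-degree thresholds, identically for
within- and between-scores. The gating rule is only well defined for
node pairs that share the anchor; extending the same selected matrix to
the complement set is this package's uniform choice, made once for
determinism and symmetry.

## Within-scores and between-scores

Each pair (d_y, t_x) is described by four similarity maxima:

- C_t^w = max similarity of t_x to the targets interacting with d_y;
- C_t^b = max similarity of t_x to the targets *not* interacting with d_y;
- C_d^w, C_d^b — the mirror images over drugs anchored on t_x.

Two conventions prevent trivial leakage: for a known interaction the
pair itself is removed from the interacting sets before the maxima
(otherwise C^w = 1 identically for every known pair), and the queried
node is excluded from the complement set (S(x, x) = 1 would saturate
between-scores). An empty set makes the score null; nulls are recorded
in a mask and then filled with the constant 1.0.

Known interactions fall into four local-topology motifs by their degrees
counted *including* the pair (deliberately different from the score
sets, which exclude it): multiple (both degrees > 1), drug-centered
(target degree 1), target-centered (drug degree 1), single (both 1).
With the self-exclusion rule the null pattern of a known pair is exactly
determined by its motif — drug-centered pairs lack C_d^w, target-centered
pairs lack C_t^w, single pairs lack both — which the test suite checks as
an internal consistency theorem. Per-motif score histograms (38 bins of
width 0.02 from 0.35 to 1.1, normalized per group, null-filled entries
excluded) can be exported to inspect how well each score separates known
from unapproved pairs.

## Pair space and confidence score

PCA is fitted on the 4-score vectors of *all* D×T pairs with mean
centering and no variance scaling (the scores share the [0, 1] scale, so
covariance PCA; recorded as a design choice). Component signs are fixed
by making the first non-negligible loading positive, so exported
coordinates are reproducible. A pair's confidence score is the Euclidean
norm of its projection on the retained components — its distance to the
pair-space origin, which is the centered mean of the cloud. Unapproved
pairs dominate the cloud and concentrate near the origin; known
interactions lie far from it, so larger distance means higher interaction
confidence. The default retains all k = 4 components, making the score
the exact distance to the feature mean (the closed form used as the test
oracle); k is a parameter so that scoring on the first three components,
as one would plot them, is reproducible. Candidate predictions are the
unapproved pairs sorted by descending score, ties broken
lexicographically on (drug_id, target_id).

## Evaluation

Cross-validation is leave-one-out over known interactions: each
interaction is zeroed in the adjacency matrix; MI similarities and degree
thresholds are recomputed from the masked network (masking changes
degrees); features for all pairs are rebuilt, the pair space refitted,
and the held-out pair's score recorded. Input similarities are
fold-independent. Negative scores (all unapproved pairs) are computed
once on the full network. This per-interaction granularity keeps runtime
O(#interactions × pipeline) and is leakage-safe: a masked fold is
bitwise identical to a network in which the edge never existed. A seeded
5-fold mode is available behind a flag.

Pooled positives and negatives give AUC in its Mann–Whitney form
(ties count one half) and AUPR by stepwise precision–recall summation —
tied scores enter as one block with precision evaluated after the block,
and no trapezoidal interpolation, which would be optimistic. Both are
implemented directly (a few lines each) so tie conventions are explicit;
the test suite cross-checks them against exhaustive enumeration and
against scikit-learn on tie-free inputs.

## Synthetic data generator

The generator plants the guilt-by-association structure the method
assumes: D drugs and T targets are assigned round-robin to K and L
clusters; drug cluster k is matched with target cluster k mod L; each
cell is Bernoulli(p_in) in matched blocks and Bernoulli(p_out) elsewhere.
Similarity entries are drawn from Gaussians truncated to [0, 1] with mean
s_in within a cluster and s_out across, sd `noise_sd`, symmetrized by
averaging, unit diagonal. A `hide_fraction` of the drawn interactions is
relabeled unapproved to form a held-out truth set; ranking those hidden
pairs against never-true pairs (`recovery_benchmark`'s `auc_hidden`)
measures exactly the intended use case. Everything is reproducible from
a single seed.

Defaults are D=60, T=40, K=L=4, p_in=0.6, p_out=0.02, s_in=0.8,
s_out=0.2, noise_sd=0.05, hide_fraction=0.1 — a sparse network (≈16%
density) with strong but noisy block signal, sized so that a full
leave-one-out run (≈380 folds, each rebuilding 2 400 feature vectors and
refitting the pair space) takes about a second on one core. Null
configurations (p_in = p_out, s_in = s_out) are expressible for
calibration checks; the config type allows equality for exactly that
reason.

What the generator does *not* emulate: power-law degree distributions
(degrees are near-uniform binomials within a block), isolated
subnetworks, and any correlation between a drug's chemistry and its
degree. Passing recovery tests therefore show the pipeline exploits
block-structured similarity; they do not certify performance on real
pharmacological networks, whose degree structure is heavier-tailed.

## Numerical choices and degenerate inputs

- Similarity files: entries may stray 1e-9 outside [0, 1] (clipped);
  asymmetries up to 1e-6 are repaired by averaging with the transpose,
  larger ones are errors; the unit diagonal is enforced to 1e-9.
- PCA uses `eigh` on the 4×4 covariance (sample convention, n−1);
  negative eigenvalues from roundoff are clipped to zero. All vectors
  identical gives zero variance and all-zero scores, not an error.
- Thresholds and branch selection use exact comparisons on integer
  degrees; LOOCV requires at least two known interactions.
- Null-filling uses exactly 1.0 even though 1 is the similarity maximum;
  this is deliberate (the filled value marks "no evidence against", and
  the mask keeps the information recoverable).

## Known limitations

The confidence score is a *distance*, not a monotone function of the
within-scores. It behaves well when unapproved pairs form one tight
cloud around the mean. When the four-score cloud becomes strongly
bimodal the mean lands between the modes and pairs with uniformly *low*
scores can be as far from the origin as known interactions, degrading
rankings. Two situations provoke this: (i) balanced geometries in which
matched and unmatched pairs are comparably numerous, and (ii) the
adaptive combiner under near-uniform degree distributions, where u =
0.5·max falls below the mean degree l, anchors split between the primary
branch (low cross-cluster similarity ≈ s_out) and the topological branch
(high MI baseline ≈ 0.7), and the two similarity scales mix across
anchors. On such inputs the linear or primary-only combiner is more
robust than the adaptive rule, and hidden-pair recovery can drop
substantially on individual draws. The degree-gated rule was designed
for sparse power-law networks, where half the maximum degree sits well
above the mean; its behaviour outside that regime should be checked
before trusting adaptive-combination rankings.

Separately, stray cross-block interactions (p_out > 0) are true positives
carrying no similarity support; no similarity-based method can rank them
above structured negatives, which bounds achievable LOOCV AUC away from 1
on synthetic data (≈0.89–0.90 at the defaults) independently of the
implementation.
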