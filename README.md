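# dtipair

Drug–target interaction (DTI) prediction from within-score/between-score
feature vectors in a PCA pair space.

## What it does

Experimentally mapping which drugs bind which protein targets is slow and
expensive, so computational ranking of *unapproved* drug–target pairs
(DTPs) is a standard step in drug repositioning. `dtipair` implements a
global, classifier-free approach for researchers who have a binary
interaction network plus precomputed drug–drug (chemical) and
target–target (sequence) similarity matrices:

1. **Matching-index (MI) topological similarity.** From the interaction
   matrix A (D drugs × T targets),
   `MI(d_i, d_j) = (T − |d_i| − |d_j| + 2|d_i ∩ d_j|) / T`
   counts shared *and* jointly-absent targets, giving a complete [0, 1]
   similarity even between drugs in disconnected subnetworks (target side
   symmetric, denominator D).
2. **Degree-adaptive combination.** With thresholds `u = 0.5·max(deg)` and
   `l = mean(deg)` over the anchoring side, the similarity used around an
   anchor of degree g is the chemical/sequence one if `g ≥ u`, the
   elementwise max if `l < g < u`, and the topological one if `g ≤ l`
   (first match wins). A linear blend `α·primary + (1−α)·topo` is the
   baseline.
3. **Four-score feature vectors.** Every pair (d_y, t_x) gets
   `[C_t^w, C_t^b, C_d^w, C_d^b]`: the maximal similarity of t_x to the
   targets interacting / not interacting with d_y, and of d_y to the drugs
   interacting / not interacting with t_x. Known pairs exclude themselves
   from the interacting sets; empty sets yield nulls filled with 1. The
   null pattern of a known pair is fixed by its local motif (multiple,
   drug-centered, target-centered, single).
4. **Pair space.** Covariance PCA over all D×T feature vectors; a pair's
   confidence score is its distance to the pair-space origin (the centered
   mean). Unapproved pairs crowd the origin, true interactions sit far
   out, and the top-ranked distant unapproved pairs are the interaction
   candidates.
5. **Evaluation.** Leave-one-out cross-validation over known interactions
   with per-fold recomputation of MI and degree thresholds, pooled AUC
   (Mann–Whitney) and AUPR (stepwise PR integration), plus a planted-block
   synthetic generator so the whole pipeline is testable without external
   data.

## Worked example

Generate a small synthetic dataset (24 drugs, 16 targets, 4 matched
drug/target clusters, 10% of the true interactions hidden), rank
candidates, and cross-validate:

```bash
dtipair simulate --out-dir data --drugs 24 --targets 16 \
    --drug-clusters 4 --target-clusters 4 \
    --p-in 0.7 --p-out 0.02 --hide-fraction 0.1 --seed 7

dtipair predict --interactions data/interactions.tsv \
    --drug-sim data/drug_similarity.tsv --target-sim data/target_similarity.tsv \
    --top-k 5 --out-dir pred

dtipair evaluate --interactions data/interactions.tsv \
    --drug-sim data/drug_similarity.tsv --target-sim data/target_similarity.tsv \
    --out report.tsv
```

`pred/top_predictions.tsv`:

```
rank	drug_id	target_id	score
1	d001	t001	0.784003
2	d005	t001	0.784003
3	d002	t006	0.757806
4	d000	t008	0.756041
5	d013	t009	0.745333
```

Every top-ranked candidate joins a drug and a target from matched
clusters (indices congruent mod 4) — exactly the pairs the planted model
makes plausible; the hidden true interaction d021–t001 sits in the same
block as the two leaders. `report.tsv` shows the leave-one-out result:

```
metric	value
auc	0.900213
aupr	0.569907
n_positives	63
n_negatives	321
```

so held-out true interactions outrank unapproved pairs with probability
0.90. The scores are distances: d001–t001 scoring 0.78 means its feature
vector lies 0.78 away from the unapproved cloud's center, where scores
hover near 0.1–0.3.

The same pipeline is callable as a library (`dtipair.generate`,
`dtipair.feature_matrix`, `dtipair.fit_pair_space`,
`dtipair.confidence_scores`, `dtipair.rank_candidates`, `dtipair.loocv`);
see `docs/methods.md` for the model, its parameters and its limitations.

## Using real benchmark data

The public chemogenomic benchmarks (enzyme, ion channel, GPCR, nuclear
receptor) ship as a drug×target adjacency with targets as rows plus
chemical and sequence similarity matrices. After downloading them as
TSV:

```bash
dtipair evaluate --interactions nr_admat.tsv --orientation targets_as_rows \
    --drug-sim nr_simmat_drugs.tsv --target-sim nr_simmat_targets.tsv \
    --combiner adaptive --out nr_report.tsv
```

Similarity matrices are passed through unchanged (no renormalization);
ids present in a similarity matrix but absent from the network are
dropped with a warning, missing ids are an error.
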