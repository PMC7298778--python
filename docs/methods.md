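# Methods

## Overview

`caskit` types CRISPR-Cas gene cassettes from protein evidence alone. The
model is a two-stage pipeline:

1. **Evidence extraction.** Each Cas protein family is represented not by a
   single profile but by a *collection* of subfamily profile HMMs, built by
   clustering the family's known members and deriving one profile per
   cluster. A cassette's protein sequences are scored against every profile
   of every family; the cassette becomes a vector `X_i ∈ [0,1]^m` whose j-th
   entry is the best normalized bit score family j attains on any protein of
   the cassette, and exactly 0 when nothing is detected. Stacking n
   cassettes gives the data matrix `X ∈ R₊^{n×m}`.
2. **Learning on the evidence matrix.** Subtype classification, signature
   detection, missing-protein regression and association rules are all
   ordinary supervised learning on `X`: zeros are treated as informative
   absences, not missing data, unless a regressor bank explicitly flags an
   entry as a candidate missing protein.

## Profile models and bit scores

A `ProfileModel` is a classic protein profile HMM (match/insert/delete
states, per-state emissions over the 20 amino acids, per-node transition
probabilities). Scoring is local-mode Viterbi: entry into any match state
and exit from any match state are free, and the score is

    bits = log2( P(best state path, emissions) / P(emissions | background) )

Insert states emit at background frequency by construction, so only match
emissions and transitions shape the score. Residues outside the 20-letter
alphabet emit at background odds (log-odds 0). This is a deterministic
stand-in for a full forward-algorithm scorer: for ranking hits and feeding a
bounded feature space it behaves like the best-domain score of standard
search tools, and the scorer is exercised against an exhaustive
state-path-enumeration oracle in the tests (agreement to 1e-9 bits on all
models of length ≤ 4 × sequences of length ≤ 6).

**Normalization.** Raw bit scores grow with model length and information
content, so they are not comparable across families. Each score is divided
by the model's *consensus self-score* (the model scored on its own consensus
sequence) and clipped to [0, 1]. The consensus thus scores exactly 1, and a
model whose self-score is not positive is flagged unusable. The normalizer
is a per-model constant and deliberately simple; it is injectable in the
sense that any other per-model constant could be substituted without
touching the scoring code. An evidence value of 0.5 is then meaningfully
"half the self-evidence of the model's own consensus", which is what the
imputation threshold (below) leans on.

**HMMER3 interoperability.** Profiles are read and written in HMMER3/f
ASCII. The format stores negative natural-log probabilities to five
decimals ('*' = probability zero); the node-0 insert emission line is used
as the background distribution (the HMMER convention of inserts emitting at
null frequencies). Files written by the package are verified in the tests
to re-read bit-identically and to parse with an independent HMMER3 reader.
An adapter for `hmmsearch --domtblout` tables lets an external scorer
replace the built-in one; both the full-sequence and best-domain bit-score
columns are exposed (full-sequence is the default).

## Subfamily construction

Per family: all-against-all Smith–Waterman local alignment (BLOSUM62, gap
open 11, extend 1, via Biopython's exact `PairwiseAligner`), link filtering,
Markov clustering, one profile per cluster.

A link between two proteins is accepted when (i) alignment score ≥
`min_score` (default 50), (ii) mutual coverage ≥ `min_cov` (default 0.5),
and (iii) the alignment midpoints, as fractions of each sequence length,
differ by at most `max_pos_shift` (default 0.3) — so a hit at the
N-terminus of one protein and the C-terminus of the other is rejected even
when score and coverage pass. These thresholds are conventional
homology-coverage heuristics; they are configurable because no single set
is canonical.

Clustering is classic MCL on the weighted link graph (self-loops added,
column-stochastic matrix, alternating expansion `e = 2` and inflation
`r = 2` with pruning at 1e-5, convergence at 1e-8). Clusters are the weakly
connected components of the converged matrix's nonzero structure, which
makes the partition total by construction. Inflation is the granularity
dial: the five shipped presets (`HMM_1` … `HMM_5`) vary (min_score,
min_cov, inflation) from strict/fine to permissive/coarse and are
illustrative defaults, not published values.

Profiles are built from a center-star multiple alignment (center = sequence
with the best summed pairwise score; "once a gap, always a gap" merging).
Columns with ≥ 50% residue occupancy become match states; emissions are
column frequencies plus a pseudocount of 0.01 per residue (avoiding -inf
log-odds for unseen residues); transitions come from observed column
occupancy with the same pseudocount; the consensus is the per-column
majority residue. The background is the Robinson–Robinson amino-acid
frequency vector. Center-star is self-contained and adequate for
column-frequency statistics; an external aligner could be slotted in where
higher-quality MSAs matter.

## Classification protocol

Three algorithm families, each with the fixed 20-point hyperparameter grid
used for model selection:

| algorithm | grid (4 × 5 = 20) |
|---|---|
| `decision_tree` (CART) | max depth {5, 10, 15, unbounded} × min leaf size {5, 6, 7, 8, 9} |
| `kernel_margin` (RBF SVM, one-vs-rest) | C {1, 10, 100, 1000} × γ {0.01, 0.1, 1, 10, 100} |
| `randomized_ensemble` (extremely randomized trees) | size {25, 50, 75, 100} × features per split {25%, 50%, 75%, 100%, √m} |

Features are already in [0, 1], so the kernel machine gets no extra
standardization.

Evaluation is nested cross-validation with stratified K1 = 10 outer and
K2 = 10 inner folds, repeated R = 50 times by default (tests and the
acceptance analysis use R = 5 on the synthetic data, where the variance
across repetitions is already far below the acceptance margins). Per outer
fold the inner grid search picks the hyperparameters with the best
*fold-aggregated* inner metric (ties: first grid point in documented order),
the winner is refit on the whole outer-training set, and the outer-test
predictions of all folds are pooled into one prediction vector per
repetition before the metric is computed once — this avoids the averaging
artifacts of per-fold scoring on imbalanced subtype distributions. The
inner selection metric is the same metric being reported (a symmetric
choice; it is configurable). Classes with fewer than 10 examples are
removed *before* fold construction so stratification can guarantee every
class in every outer fold; a class smaller than K1 is an error, not a
silent degradation. One master seed spawns per-repetition and per-fold
child seeds, all recorded in the report.

Metrics: **adjusted balanced accuracy** `(BA − 1/k)/(1 − 1/k)` with BA the
mean per-class recall (chance → 0, perfect → 1, for any number of classes
k ≥ 2); **macro F** (unweighted mean of per-class F1, zero-denominator F1
defined as 0); **MAE** for regression. All three are implemented directly
and checked against brute-force confusion-matrix oracles.

## Signature proteins and association rules

Signature detection is one-vs-rest: fit a binary tree-ensemble for one
subtype against the rest and rank families by mean impurity importance
(per-tree importances normalized to sum 1; mean and standard deviation
taken across trees that performed at least one split). A family that
dominates this ranking is a candidate signature protein of the subtype.
Note that extremely randomized trees spend some deep splits on
uninformative features, so even a perfectly discriminating family rarely
absorbs all importance mass; recovery is therefore asserted as rank-first,
not as an absolute importance value.

Association rules come from the regression side: for each target family,
the impurity importances of its regressor's inputs (normalized to sum 1)
rank which proteins carry the information about the target — co-occurring
functional modules show up as mutual top-ranked inputs.

## Missing-protein regression

For a scope (one subtype, or "global" = all rows) the *protein support* is
the set of l families with nonzero evidence in at least one cassette of the
scope. A `RegressorBank` trains l regressors, the j-th predicting family
j's normalized score from the other l − 1. Predictions are clipped to
[0, 1]. Each bank records per-target 5-fold cross-validated MAE on its
training rows as its own error estimate.

At prediction time the package must decide which zeros are "missing" rather
than genuinely absent: the default heuristic flags a zero entry as a
candidate missing protein when the global bank predicts evidence ≥ 0.5 for
it. Flagged entries can be imputed and the cassette then classified as if
the protein had been detected (`impute_then_classify`); the original vector
is always preserved alongside. Subtype-scoped re-imputation after a
provisional classification is available but not the default. The regressor
and classifier algorithms are freely combinable; the CLI defaults to a
tree-ensemble classifier with a CART regressor bank, while the library-level
bank default is the tree ensemble (required for association rules).
`MissingScoreImputer` wraps the global bank as a scikit-learn transformer
for pipeline composition.

## Synthetic data: what it emulates, what it does not

`generate_bitscore_dataset` plants the three structures the method assumes:
subtype-specific signature families (clipped Normal(0.85, 0.05) against a
zero background — clearly separated subtypes in a bounded score space),
correlated protein modules (a latent Uniform(0.3, 1) activity times
per-family loadings, the pattern behind association rules), and recorded
missingness. Default size is 3 subtypes × 100 cassettes × 12 families.
`generate_protein_families` plants subfamily structure at the sequence
level: per family one ancestor, subfamilies at 60% substitution distance,
members at 10% within-subfamily distance, length 120, substitutions only
(no indels, keeping the planted partition unambiguous).

The clipped-Gaussian score model is the simplest bounded model with tunable
separability; it is a stand-in, not a claim about real bit-score
distributions. Real cassette data additionally shows heavy class imbalance,
systematically incomplete subtypes, cross-family homology (e.g. large
multidomain effectors weakly hitting several models) and operon-order
information that the generator does not emulate. Passing tests on this data
therefore demonstrate that the machinery is correct and recovers planted
structure under the stated noise — not that real-data accuracies would
match.

## Numerical choices and degenerate inputs

- Viterbi uses a −1e30 sentinel for log(0) so the delete-chain prefix-scan
  never forms inf − inf.
- Emission/transition validity is enforced at 1e-9 (sums to 1); HMMER3
  round-trips are exact at the file level because probabilities are stored
  and re-emitted through the same −ln encoding at five decimals.
- Ties in `best_family_score` keep the maximum value; the winning model's
  identity is not part of the feature.
- An all-negative pairwise comparison yields score 0 with an empty span and
  coverage 0 (never a negative similarity).
- Grid-search ties take the first combination in documented grid order;
  all estimator randomness is seeded through `numpy.random.SeedSequence`
  children of the master seed.
- Degenerate inputs fail loudly: empty sequences, empty cassettes, empty
  clusters, unlabeled matrices where labels are required, classes smaller
  than the fold count, regression scopes with fewer than 2 supported
  families or fewer than 10 rows.

## Problem sizes used in tests and the acceptance analysis

Synthetic evaluations run at the generator defaults (n = 300, m = 12,
3 subtypes) with 5 nested-CV repetitions; recovery rates (signatures,
subfamily clustering) use 50 seeded runs; imputation quality uses n = 200
two-module matrices at noise sd 0.02; the impute-then-classify contrast
uses 180 cassettes with two redundant signature families per subtype and
one masked support entry per row. The sequence-level end-to-end check
(families → profiles → features → classification) runs on 3 families × 2
subfamilies × 4 members and 90 two-protein cassettes with a 5×5-fold
single-repetition protocol. These sizes were chosen so each planted effect
is estimated with comfortable margin over its acceptance threshold.

## Known limitations

- No E-values, bias composition filters, or forward/backward posterior
  scoring; Viterbi-only scoring can rank marginal hits differently from
  full HMMER.
- Center-star MSAs degrade on very gappy clusters; profiles built from them
  inherit that.
- The five collection presets are illustrative granularity settings, not a
  reproduction of any published collection.
- The missing-vs-absent decision is a threshold heuristic; cassettes with
  more than one genuinely missing protein are imputed greedily and
  independently per family.
- Short toy profiles (a handful of residues) can give small positive
  normalized scores to unrelated sequences sharing one high-scoring
  residue; at realistic model lengths this vanishes after normalization.
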