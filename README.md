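# caskit

Profile-HMM featurization and machine learning for typing CRISPR-Cas gene
cassettes from their Cas protein content.

## The problem

A CRISPR-Cas locus (a *cassette*) is classified into a subtype (I-A … I-U,
II-A … II-C, III-A … III-D, IV-A, V-A, VI-A/B) by which Cas proteins it
encodes and how diverged they are. Annotating a new cassette is hard
because Cas families are internally diverse — one profile per family misses
remote members — and because real cassettes are often *incomplete*: one or
more proteins of the subtype definition produce no detectable hit.

`caskit` addresses both. Each Cas family is represented by a **collection
of subfamily profile HMMs** (built by all-against-all alignment → link
filtering → Markov clustering → one profile per cluster). A cassette with
proteins P becomes a feature vector

    X_ij = max over models of family j, proteins of cassette i
           of clip(bits / consensus_self_bits, 0, 1),   and 0 if undetected,

giving a data matrix `X ∈ R₊^{n×m}` on which the package:

- **classifies** cassettes into subtypes (CART / RBF-SVM / extremely
  randomized trees, each model-selected over its 20-point hyperparameter
  grid inside nested 10×10-fold cross-validation with fold-aggregated
  scoring, adjusted balanced accuracy and macro F);
- **detects signature proteins** per subtype as the top-ranked families in
  one-vs-rest tree-ensemble impurity importance;
- **predicts missing Cas proteins**: per-subtype (or global) banks of l
  regressors, the j-th predicting family j's normalized score from the
  other l − 1; zeros with predicted evidence ≥ 0.5 are flagged, optionally
  imputed, and the cassette re-classified (`impute_then_classify`);
- **extracts association rules**: per regression target, the most
  important input families — putative functional modules.

Everything is testable without external downloads: a synthetic-data module
generates bit-score matrices with planted subtypes, signatures, correlated
modules and missingness, and protein families with planted subfamily
structure. See `docs/methods.md` for the model details and limitations.

Intended users: microbial genomics people annotating CRISPR-Cas systems,
and anyone who needs the generic pattern "profile-collection evidence
vectors + nested-CV classification + evidence imputation" for gene
cassettes.

## Worked example

Simulate a labeled bit-score matrix (3 subtypes × 40 cassettes, 10
families, one planted signature family per subtype), evaluate the
tree-ensemble classifier, and rank subtype S2's signature candidates:

```bash
caskit simulate --subtypes 3 --n-per-subtype 40 --families 10 --seed 4 \
       --out demo/matrix.csv
caskit evaluate --matrix demo/matrix.csv --algorithm randomized_ensemble \
       --repetitions 1 --outer-folds 5 --inner-folds 3 --seed 4 \
       --out demo/report.json
caskit signatures --matrix demo/matrix.csv --subtype S2 --top-k 3 --seed 4 \
       --out demo/sig.csv
```

which logs

```
caskit INFO simulated 120 x 10 matrix -> demo/matrix.csv
caskit INFO median adjusted_balanced_accuracy = 1.0000 over 1 repetitions
caskit INFO top-3 signatures of S2 -> demo/sig.csv
```

`demo/report.json` holds the per-repetition fold-aggregated scores
(`"scores": [1.0]` — the planted subtypes are cleanly separable, so the
nested-CV adjusted balanced accuracy is 1.0, where 0 is chance and 1 is
perfect), the selected hyperparameters per outer fold and all child seeds.
`demo/sig.csv` starts

```
family,importance,std
cas2,0.6073013339316671,0.3894059394748722
cas1,0.18945476042170384,0.22117408005946096
```

`cas2` is exactly the signature family planted for S2: it carries ~0.61 of
the ensemble's impurity importance (mean over trees; `std` is the spread
across trees), several-fold more than any other family.

The sequence-level half of the pipeline works the same way from the shell:
`caskit simulate-families` → `caskit build-models` (writes HMMER3 ASCII
profiles) → `caskit featurize` → `caskit train` / `classify` / `impute` /
`rules`. The library API mirrors the CLI; the estimators
(`CassetteClassifier`, `CasScoreRegressor`, `MissingScoreImputer`) follow
scikit-learn's fit/predict/transform conventions and compose with sklearn
model selection.

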