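# kacestack

Stacked ensemble prediction of prokaryotic lysine acetylation (Kace)
sites from peptide sequence alone.

Lysine acetylation is a reversible post-translational modification in
which an acetyl group is transferred to the ε-amino group of a lysine
residue.  Experimentally mapping which lysines in a proteome are
acetylated is slow and expensive, so sequence-based classifiers are used
to triage candidate sites.  `kacestack` is a library and command-line
tool for building such classifiers: it encodes lysine-centred peptide
fragments with eleven complementary feature schemes, selects an optimal
feature subset per classifier, and combines five tree-ensemble models
through a stacking strategy.  It is aimed at computational biologists
who want a transparent, fully seeded implementation of this pipeline, or
who want to audit parts of it (for example the label-leakage behavior of
KNN-style encodings).

## The method

A candidate site is a 21-residue fragment `s = s₋₁₀ … s₀ … s₊₁₀` with
the lysine at the centre (`s₀ = K`); window positions beyond a protein
terminus hold the dummy symbol `O`, giving a 21-letter alphabet.  Each
fragment is mapped to a 2616-dimensional hybrid vector, the ordered
concatenation of AAI (525), AAC (21), DPC (441), CKSAAGP (150), CTF
(343), Z-scale (105), BINA (441), BLOSUM62 rows (420), GTPC (125), GDPC
(25) and NRF (20) blocks.

Features are ranked three ways: the two-class Fisher score

    F(i) = [(x̄ᵢ⁺ − x̄ᵢ)² + (x̄ᵢ⁻ − x̄ᵢ)²] / [s²ᵢ⁺ + s²ᵢ⁻],

random-forest importances (RFIS) and gradient-boosted-tree importances
(XFIS).  F-score and RFIS lists keep their top 2000 features; XFIS keeps
only non-zero scores.  A sequential forward search then grows each list
in blocks (step 5; step 2 for XFIS), scoring every prefix by stratified
5-fold cross-validated Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FN)(TP+FP)(TN+FP)(TN+FN)),

and keeps the best prefix.  For each of the five baseline families (RF,
ERT, GB, AdaBoost, XGBoost) the best ranking wins, hyperparameters are
grid-searched on the chosen subset, and each fitted baseline contributes
its predicted probability and 0.5-thresholded label to a 10-D
meta-feature vector (out-of-fold by default, so no sample's own label
reaches its meta-features).  Six candidate meta-classifiers (the five
families plus an RBF-kernel SVM) are compared over ten randomized 5-fold
cross-validations; the winner is refit with per-parameter median
hyperparameters.

A separate KNN encoding (fraction of positive training fragments among
the X = 2, 4, …, 128 nearest neighbours under a min-max-normalized
BLOSUM62 distance) is implemented *outside* the stack, together with an
audit that quantifies why: because the features are computed from
training labels, naive cross-validation overestimates performance.

## Worked example

Train on 396 synthetic motif-planted fragments, then score a
held-out imbalanced set of 200:

```
kacestack simulate --out train.tsv --n-pos 198 --n-neg 198 --p-signal 0.8 --seed 11
kacestack simulate --out test.tsv  --n-pos 50  --n-neg 150 --p-signal 0.8 --seed 12
kacestack stack    --in train.tsv --out model.joblib --seed 11 --meta-repeats 5
kacestack predict  --model model.joblib --in test.tsv --out pred.tsv
kacestack evaluate --pred pred.tsv --truth test.tsv --out report.json
```

which prints

```
stacked model: meta=SVM, CV MCC=0.919, saved to model.joblib
MCC=0.791 AUC=0.920
```

The training-set cross-validated MCC (0.919) is the pooled out-of-fold
score of the final stacked model; the independent-set MCC (0.791) and
AUC (0.920) measure generalization to fragments the model never saw —
lower than the CV score, as expected, but far above chance (MCC 0).
`report.json` holds the full metric set (here Sn 0.92, Sp 0.913, ACC
0.915, BACC 0.917, with confusion counts TP 46 / FN 4 / TN 137 / FP 13).
Fragments are plain TSV (`fragment TAB label`); real data can be
prepared from protein FASTA plus a site table with
`kacestack.fragments.extract_dataset`.

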