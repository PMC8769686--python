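# Methods

## Fragments and alphabet

A candidate acetylation site is a window of length L (default 21, odd)
centred on a lysine.  Externally, site annotations use 1-based residue
positions; internally everything is 0-based with centre index
(L−1)/2.  Window positions past a protein terminus hold the dummy
symbol `O`, giving the 21-letter alphabet
`A C D E F G H I K L M N P Q R S T V W Y O` (20 standard residues in
alphabetical order, dummy last).  Non-standard residue codes
(B, J, U, X, Z) encountered during extraction are mapped to `O` with a
warning: the dummy is the alphabet's only non-informative symbol, so
folding unknowns into it neither invents chemistry nor widens the
alphabet.

## Feature encodings

Eleven encoders map fragments to numeric blocks; their fixed-order
concatenation is the 2616-column hybrid matrix.

* **Composition blocks** (AAC /L, DPC /(L−1), CTF /(L−2), GDPC /(L−1),
  GTPC /(L−2), CKSAAGP /(L−k−1) per gap k = 0..5).  Denominators are the
  per-window pair/triad counts, so every block is a probability vector
  per fragment; this is asserted by property tests.  CTF uses the seven
  side-chain volume/dipole classes `{VGAO} {PFLI} {STMY} {WQNH} {RK}
  {ED} {C}` (dummy in the first class); the grouped encodings use the
  five physicochemical groups aliphatic `IMLVAG`, aromatic `WYF`,
  positively charged `HRK`, negatively charged `ED`, uncharged
  `QNPCTSO` (dummy uncharged).
* **Positional blocks**: BINA (21-D one-hot per position, dummy at the
  last slot), Z-scale (five Sandberg descriptors per position), BLOSUM62
  (the residue's 20 substitution scores per position).  Where the
  source tables define nothing for `O`, it contributes zeros —
  the dummy carries no information by construction.
* **NRF** drops the (constant) central K and maps each flank residue to
  its alphabetical rank × 0.1 over the 21-symbol rank order
  (`O` interleaved at its alphabetical position), i.e. the grid
  0.0–2.0 in steps of 0.1.
* **AAI** averages per-residue physicochemical index values over the
  fragment's non-dummy residues, one column per index.  The packaged
  default table is a deterministic, fixed-seed **synthetic** stand-in
  with exactly 525 indices: the real AAindex database is not
  redistributable with this package, and nothing in the pipeline
  depends on the actual values — only on the per-residue table layout.
  Substitute genuine AAindex vectors through
  `EncodingConfig.aai_table` for biological interpretability.

The KNN encoding is implemented but deliberately excluded from the
hybrid.  Distance between two fragments is one minus the positionally
averaged similarity `Sim(m, n) = (B62(m, n) − min) / (max − min)`
(min = −4, max = 11 over the 20×20 BLOSUM62; any pair involving `O`
scores 0).  For each neighbour-set size X ∈ {2, 4, 8, 16, 32, 64, 128}
the feature is the positive fraction among the X nearest labeled pool
fragments, ties broken by pool order.  Because a query that sits in its
own pool is its own nearest neighbour at distance 0, the encoding leaks
the query's label into its features; `leave_one_out=True` removes the
self-match.  The audit in `evaluation.knn_leakage_audit` trains a
classifier on KNN features alone and reports training-CV AUC,
independent-set AUC and their gap for both modes.

## Selection and model building

F-score is the standard two-class Fisher score with ddof-1 within-class
variances; a zero denominator with separated means is treated as +inf
and ranks first, and 0/0 scores 0.  RFIS/XFIS rankers use fixed default
hyperparameters (100 trees) — only the classifiers under selection are
grid-searched, keeping the ranking cheap and deterministic.  Ranked
lists are sorted descending with ties broken by lower column index;
F-score/RFIS lists truncate to 2000, XFIS keeps strictly positive
scores.

The sequential forward search evaluates prefixes of the ranked list in
steps of 5 (2 for XFIS) until the list is exhausted; each prefix is
scored by stratified 5-fold cross-validation, pooling the out-of-fold
predictions into a single report (one MCC per prefix — cheaper than
fold-mean aggregation and equally seeded).  Ties prefer the smaller
subset.  During the search the classifier runs with fixed parameters;
the winning subset is then grid-searched (exhaustive, MCC objective,
ties keep grid order) and refit.  Default grids: tree families
n_estimators ∈ {100, 300, 500} × depth ∈ {4, 8, ∞}; boosting adds
learning rate ∈ {0.01, 0.1, 0.3}; SVM C ∈ 2⁻⁵..2⁵, γ ∈ 2⁻⁷..2¹.  All
grids are configuration, not code.

Stacking: the five baselines contribute (probability, label) pairs in
the fixed order RF, ERT, GB, AB, XGB — 10 meta-features.  Labels
threshold at 0.5 (scores exactly at the threshold count positive;
the convention for balanced training data).  Meta-features are
generated out-of-fold by default so that no sample's label can reach
its own meta-features through a baseline fit; resubstitution mode is
retained for side-by-side comparison because it reproduces the naive
behaviour the KNN audit warns about.  Six meta-candidates are compared
over ten randomized 5-fold CVs (seeds base+0..9); the best mean MCC
wins, ties resolving in the fixed candidate order.  The winner's final
hyperparameters take the per-parameter median of its ten repeat-level
optima — lower median for even counts, mode (first-seen on ties) for
categorical values.  The median rule is applied uniformly to all
candidates' numeric hyperparameters, not only the SVM's C and γ, since
a single rule must cover every family.

Every stochastic step draws its seed from the run configuration; a
fit's manifest (config hash, seeds, stage settings) is sufficient to
reproduce its predictions bit-for-bit, which the test suite checks by
refitting.

## Metrics

Sn = TP/(TP+FN), Sp = TN/(TN+FP), ACC, BACC = (Sn+Sp)/2 and MCC are
computed by direct formula substitution from confusion counts; MCC
returns 0 when its denominator vanishes (the standard convention for
the undefined case).  AUC is the rank-based area (midrank tie
handling), equivalent to the probability that a random positive
outranks a random negative.  Tests cross-check both against independent
implementations (scikit-learn and brute-force pair enumeration).

## Synthetic data

The generator emulates the *statistical shape* of a site-prediction
dataset, not acetylation biology: negatives draw every flank position
i.i.d. from a background distribution (default uniform over the 20
standard residues; real proteome frequencies can be supplied);
positives additionally draw enriched residues at a few fixed offsets
with probability `p_signal` (default motif: D/E at −2, E at −1, R at
+1, `p_signal` 0.8 — an acidic-patch-plus-basic-flank pattern of
realistic strength that mid-size encoders can detect but not saturate).
10% of fragments have a random-length terminal truncation dummy-filled
with `O`, exercising the padding code paths.  `generate_species_suite`
emits six balanced-train/imbalanced-test pairs at the sizes of the six
prokaryotic benchmark species (from 198/198 up to 6592/6592 training
pairs).  Passing tests on these data demonstrate that the machinery
recovers planted signal and respects its contracts; they say nothing
about accuracy on real acetylomes, where signal is weaker, positions
are correlated and homology structure exists.

## Benchmark protocols and problem sizes

`kacestack.benchmarks` fixes the package's standing desk-scale
experiments, shared by the acceptance tests and
`scripts/acceptance.py`:

* *Selection recovery*: 400 samples, 200 standard-normal noise features
  plus one label-copy feature; all three rankers must place the planted
  feature in their first SFS block and the forward search must recover
  it with CV MCC ≥ 0.95.
* *Stacking benchmark*: 400 fragments (p_signal 0.7), reduced encoder
  set CKSAAGP+Zscale+GDPC+NRF (exactly 300 columns), F-score ranking,
  SFS step 10, all five baseline families with reduced tree counts
  (25–30 estimators, singleton grids), three meta-selection repeats.
  The comparison value is the best per-block RF/XGBoost CV MCC.  The
  generalization property (stacked ≥ best block − 0.05 in mean MCC) is
  asserted over 10 seeds in the tests; the script reports a 4-seed
  mean.
* *KNN leakage*: 400 signal-free training fragments, 200 held out;
  naive-mode training-CV AUC minus independent AUC averages well above
  0.1 across 10 seeds, while leave-one-out mode stays within ±0.1.

These sizes are the package's chosen benchmark conditions: large enough
for stable statistics, small enough to run in minutes on one CPU.

## Known limitations

* The default AAI table is synthetic (see above); results on its block
  are structural, not physicochemical.
* No cross-set homology filtering is performed between training and
  independent fragments; redundancy reduction (e.g. CD-HIT at 30%
  identity) is an upstream responsibility.
* Grid defaults are compact stand-ins for a full production sweep.
* The stacked model's independent-set calibration is whatever the
  meta-classifier natively provides; no recalibration is applied.
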