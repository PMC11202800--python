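# Methods

`ecpdh` predicts hot-spot residues at protein–DNA binding interfaces: a
mutation site is a *hot spot* when mutating it to alanine changes the
binding free energy by ΔΔG ≥ 1.0 kcal/mol (the boundary is included).
The package takes per-residue tables of conventional structural
descriptors, expands them with signal-derived features, rebalances the
classes, selects a compact feature subset and fits a gradient-boosted
classifier. This note documents the model, the defaults, and the design
choices made where more than one reasonable convention exists.

## Input data and feature layout

Each residue carries four short "signals" — ordered blocks of related
descriptors treated as discrete sequences:

| group   | length | content                                                    |
|---------|--------|------------------------------------------------------------|
| `ASA`   | 8      | absolute + relative solvent accessibility over 4 atom classes, bound state |
| `u_ASA` | 8      | the same, unbound state                                    |
| `d_ASA` | 8      | bound − unbound difference                                 |
| `dssp`  | 6      | secondary-structure descriptors (angles, water count)      |

Together with 12 depth/protrusion (DPX/CX) values and the hydrogen-bond
count these form the 43 conventional features. The literature gives
these blocks in prose, not as named columns, so the canonical column
order is fixed in a shipped JSON registry
(`src/ecpdh/schemas/default_schema.json`); `schema.build_default_schema`
regenerates it and a test asserts the two agree. The exact composition
of the 8 ASA values per state is not enumerated anywhere authoritative;
the registry documents the chosen order (abs/rel × atom class).

The full vector is 218-dimensional: 43 conventional + 132 wavelet + 43
EMD, concatenated in that order.

## Empirical mode decomposition (43 features)

Sifting: find interior extrema (strict; a plateau counts once at its
floor-midpoint index), build upper/lower cubic-spline envelopes, and
subtract the envelope mean repeatedly until the candidate satisfies
both IMF conditions — |#extrema − #zero-crossings| ≤ 1 and a small
envelope mean — or a Cauchy-style criterion (normalised squared change
< 0.2) fires. Iterations per mode are capped at 10.

Decisions that matter on 6–8-sample signals:

* **Boundary handling.** Up to two extrema of each kind are mirrored
  across each endpoint before spline fitting. With so few samples the
  boundary policy dominates the envelopes, so it is fixed rather than
  configurable.
* **Certified modes only.** A candidate that still violates the IMF
  conditions when the iteration cap is reached is *not* emitted; the
  decomposition stops and the material stays in the residual. This
  makes "every returned IMF is a valid IMF" true by construction (on
  white noise about 0.5 % of candidate modes are rejected). IMFs +
  residual always reconstruct the input exactly because the residual is
  defined by subtraction.
* **`is_imf` tolerance.** The envelope mean is compared against
  0.25 × half-range of the sequence.

Per IMF four statistics are taken: mean, unbiased variance (N−1
denominator), energy Σx², and lag-m autocorrelation
Σ_{i=0}^{N−1−m} x_i·x_{i+m} with m = 1 (the lag and summation limits are
conventions; signals are real so conjugation is the identity). The
block layout is 3 IMFs × 4 statistics for each of the three ASA groups
(36) plus, for the shorter secondary-structure signal, all four
statistics of IMF 1 and mean/variance/energy of IMF 2 (7), totalling
43. Slots for modes the signal did not yield are filled with 0 so rows
keep a fixed width. (Four groups × 3 IMFs × 4 statistics would give 48;
the 36 + 7 split is the convention adopted to match the published
43-dimension count, and the layout is data-driven in
`emd.EMD_BLOCK_LAYOUT`.)

## Wavelet features (132 = 4 × 33)

All transforms use the orthonormal Haar (db1) filter. Per signal group:

* DWT cascade to level 3: approximation energies Ea(1..3), their
  standard deviation (population) and mean, and the level-3 detail
  energy Ed;
* five entropies of the concatenated DWT coefficients (final
  approximation then details, coarse→fine);
* level-3 wavelet-packet transform: full binary tree, both branches
  recursed, leaves in natural (filter-bank) order, inputs zero-padded to
  a multiple of 8 — total leaf energy, 8 absolute leaf energies, five
  entropies of the concatenated leaves, 8 relative leaf energies.

The entropy family follows the classical wentropy definitions —
shannon −Σs²ln s², SURE N − #{|s|≤p} + Σmin(s²,p²), threshold #{|s|>p},
norm Σ|s|^1.5, log-energy Σln s² — with p = 0.2 by default. Relative
leaf energies are defined as 0 (not NaN) when the signal is all-zero;
otherwise they form a probability vector. Haar orthonormality gives
Parseval conservation at every split, which the tests check at 1e−10
relative and which is also cross-checked against PyWavelets' db1 packet
tree.

## Class rebalancing

Hot spots are the minority (roughly 102 vs 179 in a training split).
Default strategy SMOTE-Tomek, random seed 74:

1. **SMOTE** synthesises minority rows until the classes are 1:1. Each
   synthetic row is x + (x_n − x)·u with u ~ U(0,1), x a random minority
   row and x_n one of its k = 5 nearest minority neighbours. The
   alternative sign x + (x − x_n)·u, which extrapolates away from the
   neighbour, is available as `sign="printed"` for comparison; the
   interpolating form is the default because it is the defined SMOTE
   behaviour and keeps synthetic rows inside the minority hull.
2. **Tomek cleaning** removes the majority-class member of every Tomek
   link (opposite-class mutual nearest neighbours) found in the
   expanded data, sharpening the class boundary. The 1:1 ratio is
   therefore exact after step 1 and approximate after step 2; both
   counts are observable on the returned object.

Neighbour searches use Euclidean distance on z-scored copies of the
features (computed within the data being balanced); synthesis happens in
the original feature space. Comparators: ADASYN (synthesis effort per
minority point proportional to the local majority fraction among its k
neighbours) and plain random duplication. All samplers are deterministic
per seed, never mutate original rows, and tag every row with
original/synthetic provenance. Balancing belongs inside training folds
only; `repeated_cv` enforces this.

## Feature selection

Two-step mRMR-SFS:

* **mRMR** (difference form, MID): rank features greedily by
  I(f;y) − mean I(f;s) over the already-selected set s. Mutual
  information is the plug-in contingency estimate (nats) on
  quantile-discretised columns, 3 bins, rank-based with ties broken by
  value order. MID rather than the quotient form is the original
  authors' common default.
* **SFS**, order-restricted: walk the mRMR ranking and keep a candidate
  only if it improves the cross-validated objective (mean stratified-CV
  AUC by default; F1/ACC configurable); stop after 5 consecutive
  non-improvements. The published subset size (11) depends on the
  undeposited curated dataset and is not a target here.

Because the CV objective is an unbiased but noisy estimate, a pure-noise
candidate list can still grow the subset occasionally (record
statistics, ~ln k acceptances over k candidates); tests bound this
rather than assert zero growth. Ties in every ranking break by column
order, so all selections are deterministic. Baselines: random-forest
impurity ranking and linear-SVM RFE via scikit-learn.

## Classifier and evaluation

The reference configuration is a gradient-boosted decision-tree
classifier: 150 iterations, learning rate 0.03, depth 6, seed 42
(scikit-learn `GradientBoostingClassifier`; LightGBM, XGBoost, logistic
regression, RBF-SVM and random-forest backends sit behind the same
contract, so classifier comparisons are a configuration sweep).

Metrics from the confusion table at probability threshold 0.5 (hot spot
= positive): SEN, SPE, PRE, F1, ACC, MCC; a zero denominator makes the
metric 0, matching common tooling. AUC is the normalised Mann–Whitney U
computed from midranks (ties count ½), which equals ROC-trapezoid AUC.
`repeated_cv` runs stratified k-fold CV (default 10 folds) `repeats`
times; balancing and selection are re-fitted inside each training fold.
The critical hygiene property — label-permuted data scoring AUC
0.5 ± 0.05 with balancing + selection + training all enabled — is
asserted in the test suite at n = 500, 5 × 10 folds.

## Synthetic data generator

`synthgen.generate` emulates a curated mutation table: 117 complexes of
2–5 residues, hot fraction 131/339 ≈ 0.386, ΔΔG drawn conditional on
class from truncated normals (hot: N(2.0, 0.8²) truncated to ≥ 1.0;
non-hot: N(0.2, 0.4²) truncated to < 1.0) so stored labels always agree
with the threshold rule. Signal blocks are a slow plus a fast sinusoid
with random phase/amplitude plus N(0,1) noise, chosen so 6–8-sample
signals genuinely yield 1–3 IMFs and exercise the zero-fill rules. Five
conventional slots (one per block type, indices 0/9/17/26/34) are
shifted by `effect_size` (default 1 SD) in the hot class;
`ground_truth` names them for recovery experiments.

What the generator does **not** emulate: correlations between
descriptors of real structures, per-complex effects, measurement error
in ΔΔG, or realistic ASA/DSSP value ranges. Passing tests therefore
demonstrate algorithmic correctness and pipeline hygiene, not predictive
performance on real interfaces.

## Problem sizes in the test suite

Oracle and conservation suites use 1,000 random instances each;
selection recovery uses 10 tables of n = 300 × 50 features; the
leakage-null CV uses n = 500 with 5 repeats × 10 folds; pipeline smoke
runs use 30–117 synthetic complexes. The SFS wrapper inside the
orchestrated pipeline uses a logistic-regression evaluator — the
wrapper's objective only steers subset growth, while the final model is
always the boosted classifier.

## Known limitations

* Published test-set figures (AUC 0.847, MCC 0.543, F1 0.772) rest on a
  manually curated, undeposited dataset and licence-restricted
  structural tools (NACCESS, DSSP, PSAIA, HBPLUS); they cannot be
  recomputed here and are not asserted anywhere.
* Computing the conventional descriptors from PDB structures is out of
  scope; the package consumes precomputed tables.
* EMD on 6–8-sample signals is boundary-dominated; a different mirror
  policy would change the EMD block numerically (not structurally).
* The wavelet entropy blocks ("characterization" vs "features") are
  assigned to DWT coefficients and WPT leaves respectively by
  convention; the distinction is not recoverable from the available
  descriptions.
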