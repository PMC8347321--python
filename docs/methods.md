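# Methods

## Problem and model

`cypclass` builds one binary classifier per human CYP isozyme (1A2, 2A6,
2B6, 2C8, 2C9, 2C19, 2D6, 2E1, 3A4) that labels a small organic molecule as
a substrate or non-substrate of that enzyme, plus consensus committees over
those classifiers that may abstain, and a nearest-neighbor applicability
domain that marks which predictions deserve trust. The modeling assumptions
are standard QSAR ones: activity is a function of the 2D structure alone
(no stereochemistry, no conformers), structures can be reduced to a single
neutral parent component, and a labeled compound collection is
representative enough of query space that similarity to the training set
predicts accuracy.

## Curation

Raw structures (SMILES or SDF blocks) pass through, in order:

1. parse; unparsable or empty inputs are rejected with a reason code and
   counted, never silently dropped;
2. ChEMBL-style standardization via RDKit `rdMolStandardize`: normalization
   of frequent drawing variants, fragment-parent extraction (salts,
   solvents, and duplicate fragments stripped), neutralization, isotope
   removal, stereo removal;
3. an element whitelist (H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I) —
   anything else (metals, As, Sn, ...) is discarded;
4. tautomer canonicalization with RDKit's `TautomerEnumerator`, so any two
   tautomeric drawings collapse to one string. The canonical, stereo-free
   SMILES after this step is the duplicate-identity key.

Duplicate records then merge per structure. Per isozyme: consistent labels
merge as-is, a defined label beats MISSING, and a substrate vs
non-substrate conflict blanks the cell to MISSING for that isozyme only —
conflicts are treated as evidence of annotation error, not resolved by
majority. The processing log records counts removed per stage (missing
structure, unparsable, element filter, duplicates) plus the number of
blanked conflict cells, and a dataset's completeness is the fraction of
non-MISSING cells in its records × 9 matrix.

Standardization is deliberately delegated to the maintained RDKit
implementation of these normalization rules rather than re-coded; the test
suite asserts the behavioral contract (examples above), not bit-level
identity of any particular normalizer version.

## Feature families

| id | content | type | width |
|----|---------|------|-------|
| MACCS | 166 public structural keys | binary | 166 |
| MORGAN2 | circular fingerprint, radius 2 | binary | 2048 |
| PHYSCHEM2D | all RDKit 2D descriptors | continuous/int | toolkit-dependent (~210) |
| EMBED300 | substructure embedding | continuous | 300 |

The PHYSCHEM2D column count is not hard-coded anywhere because it varies
with the RDKit release. The Ipc information-content descriptor is computed
in its averaged form (`avg=1`); the raw index grows super-exponentially
with molecule size and overflows single precision for large molecules.

EMBED300 follows the mol2vec construction: a molecule's vector is the
*sum* (not mean) of the vectors of its radius-0 and radius-1 Morgan
atom-environment identifiers, with multiplicity as reported by RDKit's
`bitInfo` (symmetric duplicate environments are deduplicated by RDKit
itself). Two tables are available: a loader for an externally trained
plain-text embedding table (one row per identifier, optional `UNK` row for
unknown tokens, gzip allowed), and a deterministic hash-seeded pseudo-
embedding table used by default in tests. The hashed table gives every
identifier a reproducible 300-dim Gaussian vector; its geometry is
synthetic, so EMBED300 results with it demonstrate pipeline mechanics, not
the value of a learned embedding.

## Single classifiers

Per isozyme, rows with MISSING labels are dropped, then an 80/20 stratified
shuffled split (seed-deterministic) separates a held-out test set.
Preprocessing is a pipeline of: zero-variance column removal → ANOVA-F
`SelectPercentile` (percentile ∈ {10, 40, 70, 100}) → for the SVM path
only, z-scoring of non-binary columns using training statistics.

Learners are a 500-tree random forest (`min_samples_split` ∈ {2, 4, 8, 16,
32, 64, 128}, `max_features` ∈ {0.05, 0.1, 0.2, 0.4, 0.8, sqrt}) and an
RBF SVM (C ∈ 10^−2…10^3, γ ∈ 10^0…10^−5), both with balanced class
weights to counter imbalance (up to 1:16 substrate:non-substrate in real
collections). SVM probabilities come from the internal cross-validated
sigmoid (Platt) fit, seeded.

Hyperparameters (including the selection percentile) are chosen by grid
search inside stratified, shuffled five-fold CV, scored by the **median**
fold MCC; ties go to the earlier grid point in the declared iteration
order. The preprocessor is refit inside every fold on the fold's training
portion only — fold-wise refitting is a design choice to rule out feature-
selection leakage, and a test asserts that fold-wise selected feature sets
do in fact differ. After selection the winning configuration is refit on
the full training split for test-set evaluation (the refit is this
package's choice of evaluation protocol). Model selection across the eight
(algorithm, feature set) candidates is the argmax of median CV MCC with a
deterministic tie-break (RF before SVM; MACCS, MORGAN2, PHYSCHEM2D,
EMBED300).

A single pipeline seed (default 42) drives splitting, fold shuffling,
forest bootstrapping, and calibration. Determinism is promised per
installation; bit-identity of splits across library versions is not.

## Consensus models

Committees of 2–4 members with pairwise-distinct feature sets combine
predictions by:

- **soft voting** — arithmetic mean of member substrate probabilities;
- **max voting** — the single largest class probability across members and
  both classes wins; cross-member ties resolve in member order;
- **hard voting** — the class reached by ≥ `min_consensus` binary member
  votes; otherwise the committee abstains and emits no probability. Two-
  and three-member committees require unanimity; four-member committees
  also allow a 3-of-4 threshold.

The decision threshold for soft/max is strictly greater than 0.5, with a
tie at exactly 0.5 resolving to non-substrate; hard-vote members contribute
their calibrated binary label (probability > 0.5). Enumerating all subset
sizes, per-member algorithm assignments, and voting modes gives
C(4,2)·2²·3 = 72, C(4,3)·2³·3 = 96, and C(4,4)·2⁴·4 = 64 committees — 232
combined models. Abstention is monotone in `min_consensus`, and per true
class, covered + abstained = total.

## Evaluation and applicability domain

MCC is the primary metric (0 by convention when a denominator factor is
zero — the package treats a degenerate confusion matrix as "no signal");
Jaccard is reported on the substrate class and AUC only for probability-
emitting models. Abstaining models additionally report coverage separately
for substrates and non-substrates, since the cost of abstention differs by
class.

The applicability domain of a model is defined by the maximum Tanimoto
similarity (Morgan2 fingerprints) between a query and the model's training
compounds; the reliability flag is inclusive at 0.7. Similarity-binned
performance uses width-0.1 bins over [0, 1] by default (the binning is a
package choice), reports per-bin MCC with degenerate bins marked undefined,
and summarizes the similarity–accuracy relationship as Spearman's rho over
defined bins (average ranks for ties; absent with fewer than two defined
bins or constant input). The fingerprint behind the domain is a
configuration option; Morgan2 is the default.

Feature importances for random-forest models are the impurity-decrease
(Gini) attributions averaged over trees, normalized to sum to 1, reported
over the features that survived preprocessing. SVM models raise an
unsupported-operation error.

## Chemical space

PCA runs on 44 interpretable 2D descriptors — a documented fixed subset of
the PHYSCHEM2D family covering size, lipophilicity, polarity, flexibility,
ring composition, topology, charge extremes, and common functional groups —
z-scored on the pooled data with constant columns dropped. The original
analysis this mirrors used a commercial descriptor package; the open
substitute reproduces the projection in spirit, not coordinate-for-
coordinate. Similarity threshold curves report, per threshold t, the
fraction of reference compounds whose nearest core-set neighbor has
Tanimoto ≥ t; curves are non-increasing by construction and start at 1.

## Synthetic fixtures

The generator assembles molecules from 10 two-site scaffold templates
(benzene, pyridine, naphthalene, thiophene, cycloalkanes, piperidine,
chains) × 24 substituent fragments, standardizes and tautomer-canonicalizes
each, and deduplicates — roughly 4200 valid unique structures, all passing
the element filter by construction. Labels follow a planted rule (default:
substrate ⇔ aromatic ring AND ≥ 1 oxygen atom), so class membership is
decidable from structure and the exact configured class ratio is met by
construction, not sampling. Per-isozyme labels are then independently
flipped with the configured noise probability and masked MISSING with the
configured missing fraction; everything is deterministic per seed. Default
conditions for pipeline-level checks: 1000 compounds, 1:4
substrate:non-substrate ratio (the skew of typical CYP collections; 1:16
for the extreme-imbalance test), 5% label noise.

What the fixtures do *not* emulate: real CYP structure–activity
relationships, the size and scaffold diversity of medicinal-chemistry
collections, correlated label errors between isozymes, or assay-dependent
label definitions. Passing the pipeline-recovery tests therefore shows the
machinery is correct and leak-free — a planted, noise-bounded rule is
recovered at MCC ≥ 0.8 and unanimous hard voting does not underperform the
best member on covered compounds — but says nothing about accuracy on real
CYP data, which depends on the curated training collections.

## Numerical choices and degenerate inputs

- MCC with a zero denominator → 0; Jaccard with TP+FP+FN = 0 → 0.
- Tanimoto of two all-zero fingerprints → 0; length mismatch is an error.
- Grid-search ties → earlier grid point; model-selection ties → fixed
  (algorithm, feature set) order; max-vote ties → earlier member.
- Stratified CV requires ≥ 5 minority-class members; smaller inputs raise
  immediately rather than producing folds without both classes.
- All-constant feature matrices, empty datasets, single-class label
  vectors, and empty training fingerprint sets raise `ValueError`s at the
  operation that detects them.
- An infinite ANOVA F score from a perfectly separating feature is treated
  as "select first", not an error.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run on synthetic fixtures of
60–1000 compounds with forests of 40–500 trees and one- or two-point
hyperparameter grids; these sizes were chosen so a full verification pass
completes in minutes on a single CPU while still exercising every stage,
including the 500-tree default forest in the pipeline-recovery check.
Exhaustive oracles cover every confusion matrix with ≤ 40 outcomes, every
voting pattern for 2–4 members (probabilities on a 0.05 grid), and 100
randomized duplicate-merge scenarios.

## Known limitations

- The hashed pseudo-embedding is not a trained mol2vec model; EMBED300
  accuracy with it on real data would be meaningless.
- Reproduction of published per-isozyme performance numbers requires the
  original curated collections, which are external inputs to `prepare`.
- No stereochemistry-aware modeling, no 3D descriptors, no learners beyond
  RF and RBF-SVM, no weighted voting or stacking.
- Whether grid-search scoring should use the median or mean fold MCC is
  ambiguous in the field; this package uses the median consistently for
  both scoring and reporting.
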