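# Methods

This note documents the models, defaults and numerical choices behind
`phytonox`, and what the synthetic-data generators do and do not
emulate.

## Data model

An **intensity matrix** is a samples × metabolites table of strictly
positive LC-MS peak intensities, indexed by (tissue, day, replicate).
Replicate counts must be balanced across the days of a tissue — the
design the generators produce and the univariate analyses assume.
(The ANOVA/Tukey layer itself handles unbalanced groups through the
Tukey–Kramer form, but such data can only enter through external
construction, not through the validated container.)

**Metabolite annotations** carry the tentative identity, compound
class, molecular weight, deprotonated precursor m/z ([M−H]⁻), fragment
ion list, retention time and fruit/leaf presence flags. The bundled
36-row table is a verbatim transcription of a published annotation
table; its internal inconsistencies (a skipped row number, presence
flags giving 11 shared metabolites where the running text says 10, two
approximate molecular weights) are preserved deliberately — the package
reads tables as printed and treats MW–precursor inconsistency as a
warning, not an error.

## Tentative identification

An observed feature matches a reference annotation when

* |observed precursor − reference precursor| ≤ `ms_tol` (default 0.1 Da), and
* at least `min_fragments` (default 2) reference fragment ions each
  have an observed fragment within `msms_tol` (default 0.5 Da).

Fragments are paired greedily by smallest absolute m/z difference,
each observed and each reference ion used at most once. Greedy nearest
pairing is a deliberate choice: at unit-resolution tolerances it agrees
with optimal assignment in all realistic cases and is trivially
auditable. Identification is monotone in both tolerances.

## Activity labels

IC₅₀-based labels use three molar windows: active for
30 nM < IC₅₀ < 99 µM, not-active for IC₅₀ > 100 µM. Values in neither
window — including the 99–100 µM gap those bounds leave open — map to
an explicit third class, `excluded`, rather than being silently binned.

## Univariate chemometrics

Per metabolite, one-way fixed-effects ANOVA across storage-day groups,
then Tukey's HSD on all day pairs (studentized-range distribution,
N − k error degrees of freedom; Tukey–Kramer when group sizes differ).
A metabolite that is constant everywhere gets F = 0, p = 1 and a
degenerate-data flag. No correction is applied *across* metabolites:
per-metabolite p-values are reported raw, as such tables are
conventionally printed; Tukey adjustment applies only within a
metabolite. Callers who need a family-wise or FDR guarantee across
metabolites must apply it downstream.

The volcano analysis compares one early and one late storage day:
log₂ FC = log₂(mean_early / mean_late) on raw (unscaled) intensities, so
a metabolite depleted during storage carries a *positive* log₂ FC. The
p-value is a two-sided Wilcoxon rank-sum: exact when both groups have
≤ 12 observations and no ties, otherwise the normal approximation with
mid-ranks and tie-corrected variance. Significance requires both
p < 0.05 and |log₂ FC| ≥ 1 (i.e., at least two-fold change); both
thresholds are configurable. Rank tests are invariant to per-metabolite
monotone rescaling, so computing p on raw rather than autoscaled data
affects only the fold-change axis.

## PLS-DA

Class indicators are one-hot encoded and centered; NIPALS PLS2 extracts
components by alternating regressions with deflation of both blocks
(convergence tolerance 1e−12 on the score vector, 500 iteration cap,
components truncated at the rank of the centered predictor block with a
warning). Weights have unit norm and successive score vectors are
orthogonal to numerical precision. Prediction assigns the class with
the largest predicted indicator; exact ties resolve to the lowest class
index. Two components are the default, matching the convention of
two-component score plots.

* **R²** — fraction of indicator variance explained in fit.
* **Q²** — 1 − PRESS/TSS over held-out predictions under stratified
  K-fold CV (default 10 folds, reduced with a warning when the smallest
  class is smaller), residuals taken against the training-fold model
  and means.
* **VIP** — VIP_j = √(p · Σ_a w_ja² SSY_a / Σ_a SSY_a); mean(VIP²) = 1
  identically.
* **Permutation test** — the statistic is the CV classification
  accuracy (Q² selectable); p = (1 + #{permuted ≥ observed})/(n_perm + 1)
  with seeded label shuffles, 1000 permutations by default.

A subtlety worth recording: CV accuracy is discrete (multiples of 1/n),
and ties between permuted and observed values make the permutation p
*conservative* — valid but super-uniform under the null. The continuous
Q² statistic yields an exactly uniform null p (up to the attainable
atoms). The test suite checks uniformity on Q² and one-sided validity
(size ≤ nominal) on accuracy.

## Descriptor engine

Descriptor definitions are delegated to RDKit's registered descriptor
list; the default panel is the curated 16-descriptor set found to
discriminate NOX2 actives (BCUT2D eigen descriptors, PEOE/SMR/SlogP
surface-area bins, E-state indices, connectivity chis, QED,
FractionCSP3), in importance order. Multi-fragment SMILES (salts,
hydrates) are reduced to the largest covalent fragment before
computation. A descriptor that is undefined for a structure propagates
as an explicit NaN — never silently zeroed — and rows with missing
values are excluded from training with a logged count.

Normalization is plain z-scoring: per-descriptor mean and n−1 standard
deviation fitted over all training rows (both classes pooled), applied
verbatim — never refitted — to test sets and deployment queries. Two of
the bundled query SMILES do not match their compound names chemically;
they are kept as printed, so predictions apply to the printed
structures.

## ML design

**Ranking.** Four classifier families — random forest, a single CART
tree, extremely randomized trees, and XGBoost — are each refit
`n_reps` = 100 times with fresh seeds on the full dataset (400 cycles).
After each fit the descriptors in the top `top_positions` = 16 ranks of
the impurity-based importances are recorded; frequency = number of
cycles in the top positions. "Top 16 positions" is the package's
reading of "highly ranked"; it is configurable. Exact importance ties
are broken by an infinitesimal seeded jitter; frequency ties by mean
importance rank, then name. When the pool has exactly 16 descriptors
every frequency saturates and the ordering rests on mean importance
rank — still informative, since informative descriptors rank high
within every cycle.

**Design.** Per epoch: stratified 70/30 split (stratification is
imposed so both classes appear on both sides); normalization fitted on
the training side only; SMOTE equalization of the normalized training
classes; for each prefix size m = 2..16 of the ranked descriptors,
repeated stratified K-fold (5 folds × 3 repeats) mean accuracy on the
balanced training set; best m by highest CV accuracy, ties to the
smaller m; refit on the balanced training set and score the untouched
test set. Five epochs per classifier; the classifier-level deployment
m is the argmax of the CV-accuracy curve averaged over epochs. All
classifier hyperparameters are library defaults, snapshotted into the
bundle manifest. The K-fold evaluation runs on the SMOTE-balanced
training set (following the normalize → balance → evaluate step
order); a config switch evaluates on the raw training split instead.

**SMOTE.** Implemented in-package: each synthetic minority sample
interpolates between a random minority point and one of its k = 5
nearest minority neighbours (Euclidean, in normalized descriptor
space), uniform interpolation factor; k is reduced with a warning for
very small classes, and a singleton class is an error. Classes are
equalized to the majority size.

**Chance level under balancing.** On exchangeable classes (zero effect)
a classifier trained on SMOTE-balanced data predicts each class at
roughly equal rates, so its expected test accuracy sits near 0.5 — not
at the majority rate (107/179 ≈ 0.598) that an imbalance-exploiting
classifier would achieve. Null-data checks therefore compare the mean
test accuracy to the majority baseline within three per-epoch Monte
Carlo standard deviations, a band that contains both chance levels.

**ROC AUC** is computed by the rank-based Mann–Whitney identity with
ties counted one half.

## Consensus deployment

Each classifier is refit on the *full* labeled dataset with fresh
normalization statistics and (by default, switchable) SMOTE balancing,
using its best m ranked descriptors — optionally pinned to a single m
for all classifiers. A bundle directory holds a JSON manifest (format
version, seeds, config snapshot, class counts, hyperparameters,
decision threshold 0.5), the normalization statistics, the serialized
model, and three stored probe vectors whose outputs are re-verified on
load; a format-version mismatch is an explicit error. A query is called
active/not-active by each bundle (threshold 0.5 on the active-class
probability); the consensus is the common call when all bundles agree
and `unresolved` otherwise. Consensus is invariant to bundle order, and
a query whose descriptors cannot be computed is marked `failed` without
affecting the rest.

## Synthetic data: scope and limits

The intensity generator draws
value = trend(day) × exp(ε), ε ~ N(0, σ²) — multiplicative log-normal
noise keeps intensities positive, the defining constraint of peak
areas; default σ = 0.1 (≈ 10% CV, typical of replicate LC-MS peak
areas). Trends are flat, exponential incline/decline (per-day rate
relative to the first sampled day), or a transient Gaussian-bump peak.
The compound generator draws class-conditional Gaussians with unit
variance: informative descriptors shift by `effect` sd in the active
class, so power is closed-form (two-class Bayes error
Φ(−effect·√k/2) for k informative descriptors); default sizes 107
active / 72 not-active over 16 descriptors mirror the curated NOX2 set.

What the generators do **not** emulate: retention times or spectra,
missing values, inter-metabolite and inter-descriptor correlation,
batch effects, heteroscedastic noise, or real molecular structure
(synthetic compounds are descriptor vectors, not SMILES — descriptor
computation is exercised against the real bundled query set instead).
Passing tests on synthetic data demonstrate the statistical machinery
is calibrated and the pipeline leak-free under known ground truth; they
do not certify performance on real LC-MS or ChEMBL data, whose headline
metrics depend on an undeposited, version-dependent training set.

## Problem sizes in the test suite and acceptance script

Null calibration uses 2000 simulated metabolite-tests (20 matrices ×
100 metabolites at the study layout); permutation uniformity uses 200
runs of 60 samples × 10 features with 49 permutations; the ML checks
use the study-shaped 179-compound datasets with the full 400-cycle
ranking, with the five-epoch design demonstrated on the
gradient-boosting system (the full four-classifier design is available
through `evaluate_all` and the CLI). These sizes were chosen to give
stable Monte Carlo estimates at interactive runtimes on a single CPU.

## Known limitations

* PLS-DA indicator regression is a pragmatic classifier; probabilities
  are not calibrated and no applicability-domain estimate accompanies
  consensus calls.
* The identification rule annotates tentatively; it does not perform
  isotope/adduct reasoning or spectral-library scoring.
* Raw-spectrum parsing (mzML), peak picking, FDR machinery across
  metabolites, hyperparameter tuning and nested CV are out of scope.
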