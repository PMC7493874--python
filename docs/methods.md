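# Methods

## Fingerprint representation

A molecular fingerprint is a fixed-length binary vector built by
enumerating substructure patterns (atom environments, paths, torsions,
atom pairs, layered path features) and hashing each pattern to a handful
of bit positions that are OR-ed into the vector.  Collisions mean a set
bit is only evidence *for* a pattern, while an all-zero hash footprint
proves absence.  Seven types are computed at 1024 bits through RDKit's
generators:

| type       | generator settings |
|------------|--------------------|
| RDKit      | path-based, defaults |
| Morgan     | circular, radius 2, connectivity invariants |
| AtomPair   | hashed atom pairs, defaults |
| Torsion    | topological torsions, defaults |
| Layered    | layered path fingerprint, defaults |
| FeatMorgan | circular, radius 2, pharmacophoric feature invariants |
| ECFP4      | circular, radius 2, count simulation + chirality |

The literature rarely states radii or invariant settings for these
names; toolkit defaults are used, and the two radius-2 circular variants
(Morgan vs ECFP4) are deliberately configured with different generator
settings (count simulation, chirality) so they produce distinct folded
vectors, since the pipeline treats them as distinct descriptors.  1024
bits is the default everywhere (larger sizes are accepted by parameter
but not exercised by the default tests).  SMILES inputs are sanitized
and reduced to their largest fragment before hashing; both behaviours
can be disabled.

Classifier inputs are the signed recodings `2*bit - 1 ∈ {−1,+1}`: on a
sparse 0/1 vector most convolutional windows would see an almost-zero
input, and the recoding removes that bias while preserving the binary
information.  Stacked k×1024 matrices (2 ≤ k ≤ 7, rows in the canonical
type order above) feed the 2D networks.

## IC50 labeling

There is no canonical IC50 activity cut-off (< 1 μM is clearly active,
> 10 μM clearly inactive), so the threshold is estimated from the data:
Lloyd's K-means with k = 2, ten restarts and tolerance 1e-6 on the raw
IC50 values in μM, threshold = mean of the two centroids.  The raw
(not log) scale is used so that recovered centroids and cluster bounds
are directly comparable with reported values on that scale.  In one
dimension the optimal two-cluster partition is a contiguous split of the
sorted sample, which the restarted algorithm finds reliably; the test
suite checks it against an exhaustive split search for n ≤ 200.  An
elbow (WCSS vs k) curve is computed as a diagnostic for the choice
k = 2.  The threshold is treated as a dataset artifact: it is persisted
as JSON next to the labeled table and never hard-coded.  Records with a
missing IC50 are dropped and counted.  Labeling is boundary-inclusive
(active iff IC50 ≤ threshold).

## Splitting schemes

*Scheme 1 (discrimination)*: stratified 80/10/10 train/validation/test;
each partition's class ratio stays within one sample of the global
ratio.  *Scheme 2 (early screening)*: 90% of the actives and 2720/6360
of the inactives form the training part, the remainder the test part;
the training part is further split 90/10 into train and validation.
The quotas are expressed as class proportions — on an 800-active /
6360-inactive set they yield exactly 720 actives of 3440 training and
80 actives of 3720 test compounds — so they transfer to datasets of any
size.  Stratified 10-fold cross-validation folds are assigned by
dealing class-shuffled ids round-robin, which bounds both fold-size and
per-class differences at one.  Ratio stress sets (1:20/1:50/1:100) are
built by subsampling actives while keeping every inactive (falling back
to subsampling inactives when too few actives exist).  Duplicate
compounds are removed by canonical SMILES before splitting.  All
sampling flows from a single integer seed.

## Convolutional classifiers

Both the 1D and the 2D network use four convolution blocks
(conv → ReLU → 2× max-pool), a flatten, dense ReLU layers of
1024/512/256 units with dropout after each, and one sigmoid output.
Direct classifiers use 128/64/32/16 filters; the stacked-ensemble
members use 512/256/128/64.  2D kernels (a, b) are oriented with `a`
along the 1024 bit positions and `b ∈ {1,2}` across the fingerprint
rows — the row dimension is at most 7, which is what the small second
extents in the kernel grid imply — and 2×2 pooling stops acting on the
row axis once a single row remains.  The loss is binary cross-entropy
(the output is a single sigmoid unit); probabilities are clipped to
[1e-7, 1−1e-7] wherever a log is taken.

Training uses mini-batch gradient descent (Adam by default, lr 1e-3,
batch 32) with early stopping and best-epoch checkpointing: the monitor
is validation balanced accuracy for discrimination, validation
sensitivity for active-only selection, and training stops after
`patience` non-improving epochs (patience 0 therefore trains exactly one
epoch past the best).  Defaults are max 100 epochs, patience 10.
Dropout defaults to 0.2 and is placed after the dense hidden layers.
Class weighting is deliberately absent: imbalance is handled by the
split schemes.  Runs are bit-reproducible under a fixed seed in
single-threaded execution.

The engine itself (`fpscreen.nn`) is a compact NumPy implementation:
convolutions are evaluated as contiguous matrix products (an im2col
gather for thin inputs, per-offset shifted GEMMs for wide ones), pooling
uses pairwise comparisons with ties to the earlier element, and the
sigmoid is folded into the loss gradient.  Backward passes are verified
against central finite differences in float64.  Adam, Adamax, RMSprop,
Adagrad and (momentum) SGD are provided; optimizer moments update in
place, so an optimizer instance is bound to one network.

### Hyperparameter grid

The grid mirrors the reference search space: first-layer filter count in
{1024, 512, 256, 128, 64, 32, 16} with successive layers halved (the
pattern of both stated architectures), learning-rate decade ladders over
[1e-6, 1] and [2e-5, 0.2], dropout 0.2–0.9 in steps of 0.1, 1D kernels
{2, 3, 4}, 2D kernels {(20,2) … (3,1)}, batch sizes 8–128 doubled, and
all five optimizers.  `grid_search` scores each spec by the k-fold
cross-validated mean of the task objective and returns the full
leaderboard; a `budget` caps how many specs are evaluated (the complete
cartesian product is enumerable but is meant to be sampled or
budget-limited — the full search is a multi-day GPU-scale undertaking).

## Ensembles

*Voting*: the best 1D CNN per fingerprint type votes with its hard
0.5-thresholded label; seven members make a majority always defined.
*Tuned-MLP-Out*: seven members (512/256/128/64 filters) are retrained
from scratch, frozen, and their seven output probabilities feed a
one-hidden-layer MLP head — 3 ReLU units, lr 1e-3, Adam for
discrimination; 5 units, lr 1e-4, Adamax for active-only selection.
Freezing the members keeps the two phases independently reproducible
and matches the parallel-probabilities design; end-to-end fine-tuning
is deliberately not done.  The head is early-stopped on validation
*loss*: with ~20 parameters its thresholded metrics are flat until the
loss has dropped, so loss is the informative monitor (defaults: max 300
epochs, patience 30).  The head's sigmoid output provides the ranking
probabilities for enrichment evaluation.

## Baselines

RBF-kernel SVM and Random Forest consume the identical signed
fingerprints (FeatMorgan by default).  Scheme-1 settings: SVM C=5, γ=1;
RF 100 trees, Gini.  Scheme-2: SVM C=1, γ=0.1; RF 2 trees, Gini.  Where
one source sentence says γ=1 for both schemes and another gives γ=0.1
for scheme 2, the more specific per-scheme pairs govern.  SVM ranking
scores are Platt-calibrated probabilities.  Note that γ values of this
magnitude presuppose the feature distribution of the original screening
data; on 1024-dimensional signed vectors whose pairwise distances are
large, an RBF kernel at γ=1 degenerates toward the identity matrix, so
the synthetic-data tests exercise the SVM with a dimension-scaled γ.

## Metrics

All scalar metrics derive from the 2×2 confusion matrix (active =
positive).  MCC is defined as 0 with a warning when a margin is
degenerate; the identity |MCC| = √(χ²/n) against the Pearson statistic
is enforced to 1e-10 in tests.  AUC is computed from midranks (ties
count one half).  The enrichment factor at p% uses
window = ⌊p·n/100⌋, hits = actives in the window, and percentage
100·hits/min(window, P) — the min keeps a window larger than the total
active count P able to reach 100%.  Score ties are broken by stable
input order; on continuous network outputs ties are effectively absent.
A reported EF10% cell whose percentage implies a denominator of P−1,
and one table entry off by 0.25 points, are treated as printing
artifacts and excluded from the reference checks.

## Synthetic data generator

The generator reproduces the fingerprint mechanism itself rather than
molecules: a library of abstract patterns, each hashed to 4 bit
positions (configurable to 5) per pseudo-type, seven pseudo-types with
independent hash maps over the same pattern universe, compounds as
random pattern sets rendered by OR-ing their hash footprints.  This
mimics "different fingerprint types look at the same structure through
different encodings" at the level the classifiers can sense: redundant
but differently-collided views.  Eight designated motif patterns act as
the bioactivity signature: an active carries several of them (uniformly
2–8) with probability `q_signal` (default 0.9), the way a true binder
presents multiple pharmacophore features; an inactive carries exactly
one motif with probability `noise_rate` (default 0.05), a decoy-like
partial match.  Background pattern sets hold 10–30 patterns from a
400-pattern universe.  IC50 values are lognormal mixtures with medians
0.92/13.9 μM and σ_log = 0.3, so under 2% of the inactive component's
mass crosses the mid-centroid threshold (~7.4 μM) and essentially none
of the active component's does.

With q_signal = 0.9 and noise = 0.05 the label noise itself caps what
any classifier can do: ~10% of actives carry no motif at all, so
sensitivity tops out near 0.9 and AUC near 0.95.  Passing tests on this
generator demonstrate that the pipeline recovers a planted, nearly
separable substructure signal; they do not demonstrate performance on
real bioactivity data, where signal is weaker, assay noise is
structured, and chemical series induce train/test correlations that
random splits ignore.

## Desk-scale end-to-end check

The end-to-end test uses 500 actives / 5000 inactives (the 1:10
screening ratio), a scheme-1 split, a direct 1D CNN on the
validation-selected best single fingerprint type (max 30 epochs,
patience 5) for the balanced-accuracy recovery, and a
Tuned-MLP-Out whose members train for up to two epochs on a stratified
half of the training partition before the head is fitted — at this data
size the motif signal saturates the members within a fraction of an
epoch, and the reduced member schedule keeps the whole check at
single-CPU desk scale.  The ensemble's EF1% on the held-out screen is
required to be 100%.

## Known limitations

- Synthetic compounds are abstract pattern sets; no chemically valid
  SMILES are generated, and nothing chemical (scaffolds, series,
  assay heterogeneity) is emulated.
- No scaffold or temporal splitting; random stratified splits only.
- No count-based or 3D fingerprints; no learned-from-SMILES features.
- The ChEMBL extraction workflow is documented as a recipe only (query
  the target's bioactivities, export IC50 rows as CSV with id/smiles/
  ic50 columns); the package starts from such an export.
- Single-threaded CPU training; the engine is sized for 1024-bit inputs
  and the stated architectures, not for general deep learning.
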