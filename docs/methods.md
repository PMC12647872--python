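# Methods

## Data model

A cohort is a set of participant trajectories on a fixed 6-month visit grid
(visit 0 = baseline, at most 13 visits).  Each visit is an 89-feature
numeric vector with an explicit observation mask.  The default schema names
71 clinically standard features — demographics (4), family history (1),
MDS-UPDRS part I/II/III items (13/13/18, each scored 0–4), Schwab & England
ADL (1), MoCA (5 domains + total), UPSIT (4 booklets), ESS (8 items),
medication flags (3) — and pads with 18 configurable auxiliary time-varying
features to reach the 89-feature width the architecture expects.  Part
totals are sums of the item features, so part III ranges 0–72 under this
item set.  Long-format CSV (one row per observed cell) is the canonical
interchange; missingness is encoded by absence.

## Synthetic cohort generator

The generator emulates the *structural* properties the method exploits, not
the marginal distributions of any real cohort:

* Each PD participant draws a latent per-part intercept and slope from
  their subtype's profile; part totals are linear in visit index plus
  within-visit Gaussian noise, clipped to scale ranges.  Draws are
  truncated at ±2.5 sd so the planted class regions are disjoint whenever
  the profile gaps exceed the truncation spans — this makes "zero noise ⇒
  exactly recoverable" a well-defined regime rather than a probabilistic
  one.
* Default profiles separate the paces in both baseline severity and slope
  (part-III intercepts 34 / 22 / 11 points, slopes 2.5 / 1.2 / 0.4 points
  per 6 months; HC ≈ 1.5 points, flat), consistent with the common finding
  that faster progressors present more severely.  The slope ordering
  rapid > moderate > slow ≥ HC is the planted ground truth.
* Item scores are produced from each latent total by largest-remainder
  allocation over per-participant Dirichlet weights (concentration 25),
  drawn **once** per participant: a patient's item profile — which symptoms
  dominate — is stable over time, so item trajectories follow the latent
  totals.  The allocation guarantees items are integers in [0, 4] summing
  exactly to the rounded total.
* Auxiliary scales trend with the subtype (S&E and MoCA decline, UPSIT
  drifts down, ESS drifts up) and the filler features track overall
  severity with participant-specific coefficients, as most clinical scales
  do.  Medication flags switch on when latent motor severity crosses a
  participant-specific threshold and then persist.
* Missingness is completely at random within a visit-parity stratum:
  yearly (even-index) visits lose cells at a lower rate (default 0.10)
  than intermediate visits (0.25), mirroring the missingness-by-visit
  pattern of real 6-month protocols.  Static features are recorded at
  baseline only.  Follow-up length is uniform on 4–13 visits.
* Default subtype counts (145 / 152 / 94 / 188) mirror the published
  cohort composition.

What the generator does **not** emulate: real covariance among items,
informative (outcome-dependent) missingness, measurement floor/ceiling
pile-ups, site effects, or medication-induced score fluctuation.  Passing
recovery tests therefore demonstrates pipeline correctness in the regime
the unsupervised stage assumes — progression structure dominating the
feature covariance — not performance on restricted real data.

## Preprocessing

Coverage filtering drops features observed in too few participants, then
participants observing too few of the remaining features (both thresholds
are configuration; no defaults are claimed).  Imputation is per participant:
static features carry their observed constant; time-varying features are
filled from the ordinary-least-squares line over visit index (clipped to
the feature's range, rounded for binary flags), falling back to constant
extension with one observation and to the cohort's per-visit median with
none.  Observed cells are never altered and the operation is idempotent.
Normalization is min–max to [0, 1] per feature with statistics learned on a
reference (training) split; binary features pass through; out-of-range test
values are preserved so the inverse transform is exact.

The imputation-shift diagnostic reports, per feature and averaged, the
absolute change in mean and standard deviation between the observed-only
and post-imputation distributions, plus the mean standardized distance of
imputed cells from the observed mean ("z-score distance"; features with
zero observed variance are skipped and flagged).  The z-distance definition
is one defensible reading of the convention and is isolated in a single
function so an alternative can be swapped in.

## Subtype extraction

The trajectory autoencoder is a single-layer LSTM encoder/decoder pair
(hidden = embedding width 32) trained for 70 epochs with Adam at 2·10⁻³,
minimizing the batch mean of per-participant visit-averaged reconstruction
losses; padded steps are masked out of both the recurrence and the loss.
Two deliberate design choices depart from a naive reading and are the
result of diagnosing failure modes on synthetic data:

* **Input features.**  The autoencoder consumes the time-varying features
  only.  Static demographics carry no progression information, but a binary
  feature like sex is cheap to encode and reconstruct, and when included it
  dominated the embedding geometry — K-Means clustered by sex, not pace.
* **Clustering geometry.**  K-Means (k-means++, 10 restarts, fixed seed)
  runs on per-coordinate standardized embeddings, with the scale floored at
  20 % of the largest coordinate sd so near-dead latent dimensions are not
  amplified into noise.  The standardization is stored in the clustering
  model and applied identically at label transfer.  Raw LSTM state
  coordinates have arbitrary relative scales; without standardization the
  cluster boundaries were driven by a few high-variance coordinates.

Further conventions: the embedding is the encoder's final hidden state;
forget-gate biases initialize to 1 so states integrate whole sequences from
the first epochs (important at this short training budget); the outlier
gate removes participants whose reconstruction loss exceeds `L_max`, given
either absolutely or as a loss-distribution quantile (default 0.99; the
validation experiments use 0.95 with 5 % planted outliers).  AIC for
K-Means is computed under an equal-weight spherical-Gaussian mixture with a
shared variance estimated from within-cluster dispersion and
m = k·d + 1 parameters; any other convention shifts all k equally.
Clusters are ordered by mean per-participant OLS slope of the part-III
total (ties: mean final total, then cluster index).  HCs are excluded from
clustering and labelled HC by rule.

## The dual-task network

Component widths and the parameter accounting (34,703 deployed):

| component | structure | parameters |
|---|---|---|
| SiVE encoder | FC 89→128→64→32→16, ReLU, dropout 0.3 | 22,384 |
| CLS token | learnable, width 16 | 16 |
| positional embeddings | learned, 14 (CLS + 13-visit grid) and 24 (max context + horizon span) positions × 16 | 608 |
| DiSE encoder | 1 transformer encoder layer, 1 head, FF 32, dropout 0.2, post-norm | 2,224 |
| subtype decoder | FC 16→8→4 | 172 |
| score embeddings | 3 × (101 levels × 16), padding index 100 | 4,848 |
| score projection | concat(48) → 16 | 784 |
| score decoder | 1 transformer decoder layer, 1 head, FF 32, dropout 0.1 | 3,344 |
| score head | FC 16→16→3 | 323 |

The SiVE *decoder* (22,457 parameters) exists only for phase-1 pretraining
and is excluded from the deployed count, as are the two loss-balance terms
w₁, w₂ (loss parameters, not network weights).  Positional embeddings are
learned; attention uses the packed-QKV convention (one 16→48 input
projection plus an output projection, both with bias); encoder layers carry
two LayerNorms and decoder layers three.  The per-component table is
emitted by `parameter_count_table` so any alternative accounting is
auditable.

Decoder input path: each of the three totals is rounded and clipped to the
101-level vocabulary (levels 0–99 plus padding index 100), embedded
per-part, concatenated and projected to width 16.  Clipping applies only to
this input path — regression targets and head outputs stay continuous and
unclipped (part III can exceed 99 on the real scale).  The decoding start
input is the final observed triplet of the input window.  Hidden
activations are ReLU; the regression head is linear.

## Training

Three phases (batch sizes 8 / 64 / 128, learning rates 10⁻³ / 3·10⁻⁴ /
3·10⁻⁴, Adam): (1) SiVE autoencoder on single visits; (2) encoder +
subtype decoder on windows under the weighted cross-entropy, score branch
frozen; (3) the joint objective with teacher forcing — pure regression loss
while epoch ≤ E_thres (default 20; the validation experiments use 8 at
their smaller scale) with the upper branch frozen, then the
exponentially-balanced sum with w₁, w₂ trainable from 0.  Freezing is
implemented by scoping each (sub-)phase's optimizer to exactly the unfrozen
parameters, so frozen weights are bitwise untouched (asserted in tests).
Class weights default to inverse class frequency normalized to mean 1.
Batches mix window sizes and horizons, padded with attention masks on the
input side and loss masks on the target side.  Epoch budgets are
configuration; the defaults (100 / 60 / 100) suit full-size runs, while the
examples and validation experiments use 15 / 15 / 35–40 epochs with an
epoch subsample cap of 4,096 windows — problem sizes chosen so a complete
run takes minutes on one CPU while still clearing the validation
thresholds comfortably.

The sliding-window count formula N(p, W) = (|L_p|−W)(|L_p|−W+1)/2 holds for
the uncapped horizon; with the 5-step cap the implementation enumerates
Σᵢ min(5, |L_p|−W−i), and the formula is asserted only for the uncapped
case.

## Evaluation conventions

Two distinct "overall RMSE" conventions are implemented explicitly:
summary tables use the arithmetic mean of the three per-score RMSEs (and
overall MSE = arithmetic mean of MSEs), while horizon tables pool the three
per-score values by quadratic mean.  Per-class accuracy equals the class's
recall; overall accuracy is pooled (micro); precision/recall/F1 are
macro-averaged; all on the percent scale.  Overall R² is pooled across the
three scores about each score's own mean.  The paired Wilcoxon signed-rank
comparison takes per-instance errors — 1 − p(true class) for
classification, the squared error summed over the three scores for
regression — and drops zero differences.  Stratified reports repeat both
report types within sex and age (<60 / ≥60) subgroups.

## Numerical and implementation notes

The package carries its own minimal reverse-mode autodiff over NumPy
(float64) with the layers the models need; gradients are verified against
central finite differences in the test suite.  Dropout draws from a
model-owned generator seeded from the model seed, so training runs are
bit-reproducible.  K-Means, silhouette and Davies–Bouldin come from
scikit-learn; the Wilcoxon test from SciPy (exact null at small n without
ties).  Degenerate inputs are contracts, not crashes: equidistant
label-transfer points take the lowest cluster index, all-zero Wilcoxon
differences return (0, 1), degenerate normalization features map to 0, and
out-of-vocabulary scores are clipped at the decoder input rather than
raising.

## Limitations

Synthetic validation bounds what the tests can show: real cohorts have
weaker subtype separation, informative missingness and item covariance the
generator does not model, so recovery and accuracy numbers here are
best-case pipeline checks, not clinical performance estimates.  Under the
generator's full missingness (10 % / 25 %) the unsupervised stage recovers
planted subtypes only partially (ARI roughly 0.45–1.0 across seeds) —
consistent with subtypes on real data being *defined* by, rather than
recovered by, the clustering.  The quantized score-embedding path loses
sub-point resolution of decoder inputs, and forecasts beyond the trained
5-step horizon extrapolate outside the learned positional range up to the
24-position cap.
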