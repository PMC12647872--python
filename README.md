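# pdprog

Dual-task modelling of Parkinson's disease (PD) progression from
longitudinal clinical visits: unsupervised discovery of **progression
subtypes** (rapid / moderate / slow pace, plus healthy controls) and
**autoregressive forecasting of future MDS-UPDRS I–III total scores**, in a
single shared-encoder network.

The package is aimed at researchers working with longitudinal movement-
disorder cohorts (PPMI-style data on a 6-month visit grid) who want a
reproducible, CPU-friendly implementation of the full pipeline — and, since
such cohorts are access-restricted, a synthetic cohort generator that plants
known progression structure so every stage can be validated end to end.

## The model

A participant's longitudinal record is `L_p = {x_BL, x_1, …, x_n}`, one
89-feature vector per 6-month visit (demographics, MDS-UPDRS I/II/III items,
Schwab & England ADL, MoCA, UPSIT, ESS, medication).  The pipeline has two
stages:

1. **Subtype extraction.**  After coverage filtering, per-participant
   least-squares imputation and min–max normalization, an LSTM autoencoder
   (hidden width 32, 70 epochs, Adam at 2·10⁻³) compresses each
   trajectory into one embedding, minimising the visit-averaged
   reconstruction loss `L_rec(p) = (1/|L_p|) Σᵢ ‖xᵢ − x̂ᵢ‖²`.  Participants
   with `L_rec > L_max` are removed as outliers.  K-Means (k = 3, chosen by
   AIC / silhouette / Davies–Bouldin) clusters the PD embeddings; clusters
   are named by their mean part-III slope (fastest = rapid).  HCs form the
   fourth class by rule, and the fitted centroids transfer labels to
   external cohorts.

2. **The dual-task network** (34,703 trainable parameters): an MLP
   autoencoder maps each visit to a 16-d Single-Visit Embedding (SiVE,
   89→128→64→32→16); a single-head transformer encoder with a CLS token
   turns a window of SiVEs into a Disease-State Embedding (DiSE) `d_p`; an
   MLP head emits subtype logits `s = [s_r, s_m, s_s, s_HC]`, and a
   transformer decoder cross-attends to `d_p` to forecast
   `u = [u_I, u_II, u_III]` autoregressively, embedding previous
   (quantized) totals through a 101-level vocabulary.  Training runs in
   three phases — SiVE pretraining (`Σ‖x−x̂‖²`), classification with the
   weighted cross-entropy `L_subtype = Σ w_{y_n} ℓ_n / Σ w_{y_n}`, and a
   joint phase that optimizes `L_MSE = Σ_j α_j‖u_j − û_j‖²` alone for the
   first `E_thres` warm-up epochs and
   `(e^{−w₁}/2) L_MSE + (e^{−w₂}/2) L_subtype` (w₁, w₂ trainable)
   afterwards, with teacher forcing.  Sliding windows of W ∈ {2,…,5} visits
   with up to 5-step targets provide `N(p, W) = (|L_p|−W)(|L_p|−W+1)/2`
   samples per participant (uncapped).

Everything — including the reverse-mode autodiff, LSTM, attention and Adam —
is implemented in NumPy inside the package (`pdprog.nn`); there is no deep
learning framework dependency.

## Worked example

`examples/02_subtype_extraction.py` generates a 160-participant synthetic
cohort (noise sd 0.4 points), trains the trajectory autoencoder and clusters
the PD embeddings:

```
embeddings: 120 PD participants x 32 dims
k=2: AIC=    8984.1  silhouette=0.223  Davies-Bouldin=1.735
k=3: AIC=    8662.7  silhouette=0.163  Davies-Bouldin=2.059
(lower AIC / DB and higher silhouette favour that cluster count)

adjusted Rand index vs planted subtypes: 0.904 (1.0 = exact recovery)
recovered cluster sizes: {'rapid': 40, 'moderate': 36, 'slow': 44}
```

The ARI of 0.90 means the unsupervised stage recovers the planted pace
groups almost exactly at this noise level; AIC prefers k = 3, matching the
number of planted paces.  `examples/03_dual_task_training.py` continues to
the supervised stage and prints a held-out patient's 2-year forecast next to
the ground truth, e.g.

```
  subtype probabilities: rapid=1.00, moderate=0.00, slow=0.00, HC=0.00
  + 6 months: predicted ( 14.4,  16.0,  38.5)  true ( 12.0,  16.5,  41.2)
  +24 months: predicted ( 17.4,  19.8,  43.5)  true ( 15.0,  21.0,  48.0)
```

A thin CLI mirrors the stages: `pdprog simulate`, `pdprog preprocess`,
`pdprog subtype`, `pdprog train`, `pdprog evaluate` (see `--help`).

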