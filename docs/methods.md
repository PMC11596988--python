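# Methods

This note documents the models and procedures implemented in `quartersleep`,
the parameter choices that matter, what the synthetic cohort generator does
and does not emulate, and the package's known limitations.

## Analysis window and quarter-nights

A hypnogram is a sequence of 30-s epochs labelled W, N1, N2, N3 or R.
Persistent sleep onset is the first epoch beginning a run of at least 10
consecutive non-W epochs (5 min of continuous sleep); brief N1 interruptions
do not break the run requirement because the run must be strictly non-W — the
simplest reading of "continuous sleep".  The analysis window extends to one
past the last non-W epoch of the recording.  Quarter-nights are four equal
contiguous partitions of this window; when its length is not divisible by 4
the remainder epochs are assigned one each to the earliest quarters (a
deterministic convention; the alternative assignments differ by at most one
epoch per quarter).

Subjects with no qualifying sleep run are excluded from the feature table
with a logged reason.

## Sleep metrics

Stage proportions (including W) are fractions of epochs within the analysis
window, not of total sleep time, so the five proportions sum to 1.  TST is
minutes of non-W epochs; SSI (stage-shift index) counts label changes between
adjacent epochs — wake counting as a stage — per hour of window.  REM-onset
latency (`REMonSet`) is measured in minutes from persistent sleep onset to
the first REM epoch; lights-off is not available in hypnogram-only input, and
the analysis window itself starts at onset, so onset is the natural
reference (configurable).  Nights without REM receive the sentinel value
"full window duration" plus a diagnostic `REM-missing` flag column that is
not part of any feature set: the sentinel preserves ordering (longer = later)
without undefined values.

Quarter TST is reported in minutes (not as a fraction), keeping the unit of
the whole-night metric.

## Transition matrices

Within each quarter, ordered adjacent-epoch pairs are counted into a 5×5
matrix, self-transitions included (the full matrix is only 25 features per
quarter with the diagonal).  Rows with at least one outgoing pair are
normalized to conditional probabilities; never-visited rows are zeros rather
than missing, so downstream models need no imputation for them (a visited
mask is retained for diagnostics).  Probabilities rather than raw counts make
quarters of unequal length comparable; a counts-per-hour representation is
available via a flag.  Pairs straddling a quarter boundary are not counted,
keeping quarters independent; across quarters the pair count is therefore the
window length minus 4.

## qEEG

Each 30-s epoch of the single EEG channel is cut into fifteen non-overlapping
2-s slices.  A slice is rejected if any sample sits at or beyond the recorder
clip limits, or if three or more consecutive samples are identical
(flat-line).  When the recording supplies no physical limits the observed
extrema stand in, with a warning.  Surviving slices get a multitaper PSD:
DPSS tapers with time-bandwidth product 2 and 3 tapers — a standard
resolution/variance compromise at 2-s windows (4 Hz main-lobe width); both
are configurable.  Band power is the rectangular sum of PSD bins in half-open
intervals [low, high) over δ 0.5–4, θ 4–8, α 8–12, σ 12–16, β 16–30,
γ 30–47 Hz; relative power divides by the total across the six bands, so the
six values sum to 1 and are invariant to amplitude scaling.  Slice values are
averaged per epoch, then over epochs of each stage within each quarter.
Epochs marked `no_score` are excluded.  A stage never validly observed in a
quarter yields a missing value, median-imputed later *inside the training
split* of the classifier — the data are never imputed globally, which would
leak held-out information.

## Hypnodensity features

Hypnodensities (per-epoch probability distributions over the five stages, the
soft output of an automated stager) arrive at 15-s or 30-s resolution; 15-s
rows are averaged pairwise to the 30-s grid, dropping an odd trailing row.
Per quarter we take the mean of each stage's probability (5 marginals), the
mean per-epoch product p_X·p_Y for each unordered stage pair (10 mixtures),
and the mean per-epoch Shannon entropy in nats (0 to ln 5 ≈ 1.609).
Mixtures are averaged per epoch rather than formed from quarter-mean
marginals: the per-epoch product is what captures within-epoch state mixing,
which is the scientific motivation for these features; the alternative is
available behind a flag.  Marginal means commute exactly with the 15→30-s
averaging (linearity); mixtures and entropy do not, which is inherent to
their non-linearity and documented rather than "fixed".

## Synthetic cohort generator

The generator exists so that every downstream stage — extraction, statistics,
classification, importance — can be exercised and validated end-to-end with
known ground truth.  Each group (NT1, NT2, IH, control) has a profile:

* **Hypnogram**: a time-inhomogeneous Markov chain over the five stages with
  one transition matrix per quarter, built from an architecture template with
  two knobs — *stability* (shared diagonal mass; stage persistence) and an
  *N1 pull* per quarter (off-diagonal mass shifted toward N1, the
  fragmentation signature).  A Markov chain was chosen over a cyclic
  ultradian model because the transition-feature extractor can then recover
  the generating matrices exactly, giving a closed verification loop.
* **REM onset**: a latency in minutes is drawn from a gamma distribution with
  group-specific mean and shape (shape 1 — exponential — for NT1, capturing
  its short-latency/sleep-onset-REM mode; shape 4 for controls and IH,
  concentrating latency away from zero as with intact REM cycling; defaults
  30/45/90/90 min for NT1/NT2/IH/control).  REM is suppressed (column zeroed,
  rows renormalized) before the latency epoch, and at the first sleeping
  epoch from the latency onwards the chain is placed in REM.  Planting the
  onset makes the sampled latency the night's actual REM onset; with
  suppression alone, the stochastic waiting time for the chain to route into
  REM (mean 15–30 min, similar spread) would dominate the parameter and make
  it unrecoverable.
* **EEG**: per-epoch frequency-shaped Gaussian noise whose expected relative
  band powers equal a stage-dependent weight table (N3 delta-dominant, wake
  alpha-led, REM mixed), at 128 samples/s — enough to resolve the 47 Hz band
  edge while keeping fixtures small.  Optional artifacts replace 2-s slices
  with flat lines at a configured rate.
* **Hypnodensity**: Dirichlet rows centred on the scored stage,
  α_i = 0.5 + c·1{i = stage}; the concentration c controls how one-hot the
  rows are, low c emulating mixed states.  Native 15-s resolution so the
  downsampling path is exercised.
* **Heterogeneity**: per subject, stability and pulls get Gaussian jitter
  (SD 0.035 and 0.05) and the concentration a lognormal factor (σ = 0.4), so
  group distributions overlap as in real cohorts; without this the groups
  are perfectly separable, degenerating every importance question.
* Ages are Gaussian per group (37.0 ± 14.5, 30.0 ± 10.8, 30.3 ± 10.6,
  34.4 ± 12.0 years), clipped to 18–80.  Default group sizes 23/18/21/8
  preserve the ~114:41 NT1:control imbalance of a reference clinical cohort
  at one-fifth scale.  Default night length is 960 epochs (8 h).  Everything
  is reproducible from a master seed via per-subject child seeds recorded in
  the manifest.

What the generator does **not** emulate: ultradian sleep cycling, realistic
EEG waveforms (spindles, K-complexes, slow waves), apneas and limb movements,
age effects on architecture, scorer disagreement, and hypnodensities from an
actual staging network.  Passing tests therefore demonstrate that the
pipeline recovers structure *of the kind the generator encodes* — group
differences in REM timing, fragmentation, mixed states and spectra — not
clinical performance on real recordings.

### The recovery experiment

The classification-recovery condition uses two groups that differ **only** in
REM-latency (scale 10 min for NT1 vs 90 min for controls) and transition
instability (stability 0.90 vs 0.92, rising N1 pull 0.03→0.18), with NT1
n = 40 vs control n = 15.  The contrast magnitudes encode REM latency as the
dominant discriminative axis, with transition features secondary — the ground
truth this experiment asks the pipeline to recover.  On this cohort the
random-forest framework reaches mean AUC_ROC ≈ 0.86–0.95 over 20
realizations depending on the cohort draw (only ~5 controls land in each
held-out split, so cohort-level sampling moves the mean by a few points), and
`REMonSet` is the top-ranked importance feature in 75–100% of realizations.

## Classification framework

Tasks: NT1 (positive) versus controls, NT2, IH, NT2+IH, or all three.  Each
realization draws a stratified 70/30 split; 200 realizations by default (the
test suite and the acceptance script use 20 on the synthetic cohort to keep
desk-scale runtimes in minutes).  Strictly inside the training rows:

1. median imputation (medians from training rows only);
2. SMOTE: the minority class is oversampled to parity by interpolating
   between a minority member and one of its k = 5 nearest minority
   neighbours (k reduced with a warning for tiny classes);
3. recursive correlated-feature removal: while any pair of features has
   |Spearman ρ| > 0.9, drop the member with the lower preliminary importance
   (single-feature rank AUC on the training rows), falling back to the
   member with higher mean absolute correlation; deterministic;
4. model fit with small-grid 5-fold CV tuning (random forest, 100 trees,
   max_features ∈ {√p, 0.5p}; XGBoost depth ∈ {3, 5}; Gaussian process RBF
   untuned).

Held-out F1 (positive class), AUC_ROC and AUC_PR are summarised as mean and
SD across realizations.  Realizations failing on degenerate splits are
skipped and logged; the run aborts if more than 10% fail.

### Feature importance

Two estimators of "score drop when the feature is removed from the
classifier", selected by `importance_mode`:

* **refit** (default): remove the feature, refit the model with identical
  hyperparameters, score the held-out set.  Faithful to the literal removal
  semantics but expensive, and on small held-out sets (tens of subjects) the
  refit itself re-randomizes tree construction, so single-realization drops
  carry substantial model-sampling noise.
* **permutation**: keep the fitted model and permute the feature's held-out
  column, averaging the drop over 10 draws.  The standard low-variance
  approximation of the same quantity; unused features get drops near zero
  exactly.  The desk-scale recovery experiment uses this mode because, at 55
  subjects and ~290 surviving features, refit noise (±1 held-out subject
  changing side ≈ 0.06 F1) otherwise swamps per-realization rankings.

The drop metric is F1 by default, AUC selectable.  Per-feature drops are
averaged across realizations (zero for realizations where the feature was
filtered out) and ranked.

## Group statistics

Per feature: ordinary least squares `feature ~ group + age` ("ANOVA
controlling for age" realized as ANCOVA with a linear age covariate), type-II
F test on the group term, Benjamini–Hochberg adjustment across the full
feature family (a single global family rather than per feature set —
configurable), and Tukey HSD pairwise comparisons on age-adjusted values
(the fitted age slope removed), applied regardless of omnibus significance.
Constant features are flagged and excluded from the FDR family.  Significance
is α = 0.05.  Null simulations put the per-feature type-I error at ≈ 0.05.

## Numerical and degenerate-input conventions

Epoch length is fixed at 30 s; other lengths are resampled at read time by
majority/repetition with integer ratios.  Transition extraction requires at
least 2 epochs per quarter; quartering requires a 4-epoch window.  All-zero
EEG windows raise rather than return NaN.  Entropy uses natural logarithm
with 0·log 0 = 0.  Probability-row validation tolerates 1e-6 (file
round-trips), proportion identities 1e-9.  Seeds below 2³¹ are derived from
a master seed via a child generator everywhere randomness occurs, so every
artifact is reproducible from (config, seed).

## Known limitations

* The EDF+ annotation reading path requires `mne` (optional extra) and is
  validated against hand-parsed annotation lists, not against binary EDF
  fixtures.
* The recursive correlation filter is O(p²) per realization; at a few
  hundred features this is negligible, at tens of thousands it would not be.
* The Gaussian-process backend is untuned and slow beyond a few hundred
  subjects.
* Quarter-night boundaries inherit any error in persistent-sleep-onset
  scoring; no sensitivity analysis over the onset definition is built in.
* A linear mixed model of quarter-by-diagnosis time evolution is out of
  scope; the ANCOVA screen and the classifier are the supported analyses.
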