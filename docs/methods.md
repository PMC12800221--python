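# Methods notes

## Model and unit of analysis

The pipeline models population-averaged morphology, not single cells. Each
imaging field is summarized by the per-feature median of its segmented
cells; those field profiles are the rows for normalization, feature
selection, classification and scoring. Medians (not means) limit the
influence of mis-segmented or mitotic cells. Per-cell scoring is
deliberately out of scope.

The classifier treats the EMT time course as a 5-class problem
(Control, 24 h, 48 h, 4 d, 8 d of TGF-β1 induction). The continuous EMT
score is the expectation of the progression weight under the predicted
class distribution, EMT = Σ p_n w_n, so it is bounded by [min w, max w] and
strictly increases when probability mass moves to a later time point.
Because the score is linear in the probabilities, scoring per field and
averaging per well equals averaging probabilities first; we score per field
so that well-level 95% confidence intervals (t-based, N = fields) are
available.

## Normalization

Robustize: x′ = (x − median)/IQR per feature, computed per plate across all
conditions — including when scoring unlabeled plates, which makes the
train/score convention identical but means a plate's own composition sets
its scale. Quartiles use linear interpolation of order statistics (numpy
default), fixed so results are bit-reproducible. Features with IQR = 0 map
to 0 rather than NaN; the low-variance filter removes them immediately
afterwards, and zeros keep the matrix finite in the meantime.

## Feature selection

Bulk stage, in order: features with any missing value; variance < 0.01;
pairwise Pearson |r| > 0.9 (of each offending pair the member with the
larger mean absolute correlation to all remaining features is dropped, ties
broken lexicographically — deterministic and in line with common profiling
practice); then a blocklist, defaulting to colocalization metrics known to
be unstable in aggregated profiles (`Costes`, `Manders`, `RWC` name
patterns), fully overridable.

Importance stage: permutation importance of a fitted
histogram-gradient-boosting classifier on the training split — baseline
accuracy minus mean accuracy over 5 seeded shuffles per feature. Features
with importance ≤ 0 are ineligible; the top 25 eligible are scanned in
descending importance and kept only if Spearman |ρ| ≤ 0.75 against every
already-kept feature. The panel size is therefore data-driven; on the
synthetic generator's default plate a single feature typically survives,
because all informative features respond to the same one-dimensional latent
EMT position and are thus mutually rank-correlated. Real Cell Painting data
carry many weakly coupled axes and retain larger panels (~15); this is a
property of the data, not of the algorithm, so the panel size is reported
rather than forced.

## Classifiers

Six families (k-NN, linear SVC, SGD, RBF SVC, random forest,
histogram-based gradient boosting) are compared with stratified 5-fold,
3-repeat cross-validation on the 80/20 training split, all with library
default hyperparameters recorded in the model manifest. Only the final
histogram-gradient-boosting model must provide calibrated probabilities;
linear SVC and SGD take part in the accuracy comparison only. The model
archive (`.cpamodel`) is a zip of a JSON manifest (class order, panel,
weights, config fingerprint, blob checksum, format version) plus a joblib
blob; loading verifies the checksum, format version and panel/blob
consistency, and restores bit-identical predictions.

## Outlier removal

Per condition (including the control; unlabeled profiles form one group),
an Isolation Forest seeded from the pipeline config is fitted on the panel
features and the ⌊contamination · n⌋ most anomalous profiles are removed —
thresholding at the contamination quantile of the anomaly scores with ties
broken by row index, so the flagged count is deterministic. Conditions with
fewer than 20 profiles are skipped with a warning; at a 5% contamination
rate, flagging below that size is noise. PCA inspection is regarded as a
passive diagnostic and has no filtering effect.

## Transcriptomic calibration

The hallmark score is the geometric mean of linear-scale expression over
the hallmark-EMT gene set (log2 input is exponentiated first; non-positive
linear values are an error, never silently offset). Weights are the fold
change of this score versus control, which makes w(control) = 1 exact and
the weights invariant to overall scaling. Geometric-mean fold change and
arithmetic-mean log2 fold change coincide up to exponentiation, so either
reading of the calibration yields identical weights; we implement the
geometric mean. The published default weights (1, 2.92, 4.39, 4.92, 6.07)
derive from an external RNA-seq time course and are shipped as constants;
regenerating them exactly would require that external dataset.

KS score: signed two-sided Kolmogorov–Smirnov statistic
max(F_E − F_M) − max(F_M − F_E) between the epithelial-set and
mesenchymal-set expression ECDFs within a sample, positive = mesenchymal.
This is a deliberate simplification of the original KS-score method: no
hypothesis-test gating is applied, the statistic itself is the score.

76GS score: per-gene weights are Pearson correlations with CDH1 across
samples (constant genes get weight 0), expression is mean-centered per gene,
and the score is the weighted sum. Centering makes scores comparable across
samples (they sum to zero) but also means a score is only meaningful
relative to the other samples in the same matrix.

## Synthetic data

The plate generator emulates: an ordered 5-condition time course at latent
positions (0, 0.25, 0.45, 0.7, 1.0); 10 wells/condition × 9 fields/well
(the reference plate design); Poisson cell counts per field (mean 120,
minimum 1); 50 informative features responding linearly to the latent
position with mixed-sign coefficients scaled by `effect_size` (default 1);
100 redundant features (informative parent + N(0, 0.05) noise) to exercise
the correlation filters; 250 pure-noise features; nested well (σ = 0.1) and
cell (σ = 1) Gaussian noise; and optional outlier wells shifted by 10 cell
σ. Defaults were chosen so that per-field medians of ~120 cells give
adjacent conditions a separation a few times larger than the field-level
noise — a "strong effect" plate on which the classifier should approach
its ceiling.

What it does **not** emulate: the nonlinear, branching trajectory of a real
EMT time course (responses here are linear in the latent position),
feature-specific noise families and heavy tails of real CellProfiler
features, plate-edge and batch effects, or segmentation failure modes. A
green pipeline test therefore establishes that the machinery recovers a
monotone morphological progression under the stated noise model — not that
real data will reach any particular accuracy.

The expression generator places 122 hallmark genes on a programmed mean
log2 fold-change trajectory (default: the published hallmark trajectory)
over a flat background (500 genes, baseline log2 = 5, noise σ = 0.1,
3 replicates per time point — typical RNA-seq scale and design).

## Numerical and design choices

- All randomness flows from a single integer seed per run; identical
  configs give identical outputs, and generator tables are byte-identical
  across runs.
- Inner join on (image, object) keys when merging compartment tables:
  membership in all three compartments is required, since the merge
  behavior for partially segmented cells is otherwise undefined. Missing
  values are dropped at ingestion, never imputed.
- Stratified splits and folds; a class with fewer samples than folds is an
  error rather than a silent degenerate fold.
- ANOVA uses the standard one-way F; groups that are all
  zero-within-variance are rejected as degenerate. Tukey HSD provides the
  adjusted pairwise p-values.
- The package is a library with narrative examples rather than a
  command-line tool: its consumers are analysis notebooks and scripts, and
  every end-to-end chain (`run_train`, `run_score`) is a plain function
  that writes its artifacts plus a JSON run manifest for provenance.

## Known limitations

- Per-plate normalization without an anchor condition means scores from
  plates with very different composition are not directly comparable.
- Probability calibration of the gradient-boosting model is not assessed;
  the EMT score inherits any miscalibration.
- The default progression weights are specific to the NMuMG TGF-β1 time
  course; other systems need recalibration via the `calibrate` functions.
- Test-suite simulations run at reduced plate/feature scale where full
  scale adds runtime without changing the property under test.
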