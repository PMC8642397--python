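# Methods

## Scope and model

`peakvote` classifies precursor peak groups in Skyline-style chromatogram
exports as peptide or noise, and uses the classification to screen pairs in
MS1 dimethyl (light +28 Da / heavy +34 Da) quantification. A peak group is
the set of up to three isotope XIC traces (M, M+1, M+2) of one precursor,
each with an integration interval, plus report-level metadata (idotP,
mass error in ppm, per-isotope areas). The assignment rule is unanimity:
a group is a peptide only if all six classifiers vote peptide. This is a
deliberate precision/recall trade — the unanimous-positive set is the
intersection of the members' positive sets, so its false-positive count is
bounded above by every member's, while some true peptides are lost.

## The nine features

All trace-derived features are computed inside the integration interval
("the window"); every sub-computation that fails on degenerate input
reports *missing*, and missing values become 0 in the final vector, making
feature extraction total.

- **idotP** and **average mass error (ppm, signed)** are copied from the
  report. When per-isotope mass errors exist, their mean is used. The
  error is kept signed; threshold filters use its absolute value.
- **FWHM** (the primitive under two features): apex = max in-window
  intensity, half-max = apex/2; the left/right crossings are the outermost
  up/down crossings of the half-max level, linearly interpolated; a side
  that never falls to half-max uses the window boundary. Missing when the
  window has < 2 samples or a non-positive apex.
- **fwhm_sd**: population standard deviation of the per-isotope FWHMs.
- **jagging score**: the number of samples strictly below half-max whose
  time lies strictly between the crossings, summed over isotopes. A smooth
  unimodal peak scores 0 by construction.
- **snr**: in-window apex over a noise floor, where the floor is the
  median intensity outside the window; with no outside samples or a zero
  floor it falls back to the smallest positive in-window intensity. This
  definition is a design choice (robust, parameter-free, monotone in peak
  height); other S/N conventions exist.
- **shape similarity**: the mean pairwise Pearson correlation of the
  isotope traces over a common in-window grid. A pair containing a
  zero-variance trace contributes 0 (degenerate). Traces sharing identical
  time vectors are used as-is; otherwise all traces are linearly
  interpolated onto the union of in-window time points, which avoids
  fabricating resolution.
- **co-elution score and count**: for each unordered isotope pair the
  mean-centred windowed traces are cross-correlated; each lag's value is
  normalised by its overlap length (otherwise the full-overlap zero lag is
  favoured and one-sample shifts are never recovered), and lags are capped
  at half the window so near-empty overlaps cannot win. The best lag is
  the argmax, ties going to the smallest |lag|. Score = mean over pairs of
  |lag| × median sampling interval (minutes); count = number of pairs with
  best lag exactly 0 (0–3). The count definition is a design choice.
- **boundary intensity**: per trace, (I(start) + I(end)) / (2 × apex) with
  boundary intensities interpolated, averaged over isotopes and clipped to
  [0, 1]. The apex-relative (dimensionless) form was chosen so the feature
  measures boundary behaviour rather than acting as a proxy for absolute
  intensity after min-max scaling; the boundary values join the apex
  candidates so collapsed or off-sample windows stay defined (collapsed
  boundaries on the apex give exactly 1).

Average retention time is retained as group metadata but is not a feature.

## Preprocessing and routing

Features are scaled to [0, 1] by min-max ranges learned from the training
split (constant columns map to 0; out-of-range application values clip).
PCA is fitted on the scaled training matrix (covariance, mean-centred);
the retained component count is the smallest k whose cumulative explained
variance reaches `variance_target` (default 0.99), or a fixed k on
request. Component signs are fixed so each component's largest-magnitude
loading is positive, making loadings reproducible. SVM, ANN, KNN and GNB
consume the PCA scores; RF and the boosted trees consume raw features
(trees are scale-invariant and benefit from the original axes).

## Training

Hyperparameters for five members are chosen by stratified 5-fold
cross-validated accuracy over modest grids (SVM: linear kernel,
C ∈ {0.01…100}; KNN: k ∈ {3…11}; ANN: one/two hidden layers
{(10),(50),(100),(50,25)} × L2 {1e-4,1e-3,1e-2}, 600 max epochs;
RF: 100–500 trees × depth {5,10,∞}; boosted trees: 100/300 trees × depth
{3,5,7} × learning rate {0.05–0.3}). Grids are ordered simplest-first and
ties break toward the first (simplest) entry, giving full determinism; GNB
has no tuned hyperparameters. One master seed derives the split, the fold
assignment and each member's initialisation, so a fixed seed reproduces
identical models and votes. The XGB ensemble slot is implemented with
scikit-learn's `GradientBoostingClassifier` (the same gradient-boosted
tree family). Probabilistic members vote with their hard 0.5-threshold
labels.

`stratified_split` preserves class proportions to within rounding; it also
accepts explicit per-class test counts, because published splits are not
always exactly proportional (e.g. 380/357 into 219+161 / 199+158).

## Synthetic data: what it emulates and what it does not

The generator's stated world (defaults): a nanoLC gradient sampled every
0.05 min (3 s MS1 cycle), Gaussian peaks with σ ∈ [0.05, 0.15] min,
integration boundaries at ±2.5σ, isotope envelope 0.6/0.3/0.1, apex
intensities log-uniform over 10⁴–10⁷, 4% multiplicative trace jitter and a
2% baseline. Peptides: three co-eluting envelope-scaled traces, idotP ~
N(0.97, 0.02) clipped to [0, 1], mass error ~ N(0, 1.5 ppm). Noise: idotP
~ N(0.90, 0.08) — median 0.90 by construction, so more than half of noise
passes an idotP ≥ 0.85 filter — mass error ~ N(0, 5 ppm), and one of three
defect morphologies per group (equal thirds): low-S/N jagged traces, a
peak integrated on its tail, or discordant isotope shapes with injected
elution lags (M+1 always lags ≥ 1 sample). Each group draws a defect
severity s = u^(1/separation), u ~ U(0,1): at the default separation 1,
severities are uniform and low-severity noise is nearly indistinguishable
from peptide — the irreducible overlap a manual annotator faces — while
higher separation makes the classes cleanly separable. About 10% of noise
groups lose one isotope trace.

What a green test on this world establishes: the feature numerics, the
preprocessing/routing, the unanimity logic and the quantification
arithmetic behave as specified, and the pipeline separates classes whose
differences lie in the engineered morphologies. What it does not
establish: performance on real chromatograms, whose noise is not a
one-defect mixture and whose feature covariance differs. Concretely, on
real annotated data the first principal component of the scaled features
has been reported to align almost entirely with idotP (loading ≈ 0.93)
with four components carrying essentially all variance; on the synthetic
table PC1 is instead dominated by the co-elution/shape block (idotP
loading ≈ 0.19, eight components to 99% variance). The packaged training
table is this synthetic world frozen at one seed and is labelled synthetic
in its filename and loader.

The quantification generator draws light areas log-uniformly over
10⁵–10⁸ and sets heavy = light × 2^−(r+ε), ε ~ N(0, noise_sd) on the log₂
scale, so `true_log_ratio = 0` emulates an equal mix. Optional distorted
pairs are noise-morphology groups whose idotP/mass error are forced
through the conventional filter and whose ratio noise is much larger —
the pollution the unanimous vote is meant to reject.

## Numerical and interface choices

- Log ratios default to base 2 (MA-plot convention); the base is
  configurable and recorded on every pair. Summaries report both the
  population SD of log ratios and the SEM, the two common readings of a
  reported "deviation".
- The conventional filter ships two presets: annotation (idotP ≥ 0.85,
  |ΔM| ≤ 10 ppm) and quantification (idotP ≥ 0.9, |ΔM| ≤ 6 ppm); both
  boundaries are inclusive and missing values fail.
- Dimethyl tags are recognised as bracketed mass deltas on the sequence
  (`K[+28]`, `K[+ 34]`, decimal variants) and stripped to form the pairing
  key; a duplicate light or heavy group for one key is an error rather
  than a silent choice.
- A missing isotope area contributes 0 to the three-isotope sum; a pair is
  dropped only when a side's total is 0.
- Chromatogram parsing accepts Skyline "Results Grid" headers or canonical
  snake_case names, comma- or semicolon-delimited list cells (detected per
  cell), and seconds-to-minutes conversion via a flag. Absent integration
  boundaries default to the full trace extent and are flagged. Unparseable
  numeric cells abort with the offending row named — never silently
  zeroed.
- Model archives embed a format-version tag and the training seed; a
  version mismatch raises an explicit incompatibility error.
- Precision is undefined (None), not 0, when nothing is predicted
  positive.

## Known limitations

- The six members' hyperparameter grids are pragmatic defaults, not a
  reconstruction of any published tuning protocol.
- Majority or soft voting is not offered as a primary rule; unanimity is
  the point of the design.
- No peak re-integration, smoothing, retention-time alignment or
  protein-level roll-up; Skyline (or the simulator) is trusted for XIC
  extraction and boundaries.
- Published real-data results at full scale (hundreds of peak pairs from
  a mouse-liver equal-mix experiment) require the original raw data and
  are out of scope; the quantification claims verified here are the
  structural ones (CLT-bounded equal-mix mean, exact antisymmetry under
  label swap, distortion rejection).
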