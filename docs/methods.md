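# Methods

## Decoding model

The decoding stage assumes a fixed library of seven emotion models: spatial
coefficient vectors w_e over a common in-brain voxel grid, conceptually the
output of a partial-least-squares fit to stimulus-evoked data. The package
never fits these models; they are immutable inputs (real NIfTI volumes or
synthetic maps).

Per subject, each voxel's time course is standardized to mean 0 and sample
standard deviation 1 (denominator n−1, fixed for bit-reproducibility),
*within each run separately*, since runs are acquired independently; runs
are concatenated only after scoring. Standardization is per voxel across
time rather than per volume across voxels: temporal z-scoring is what makes
the scalar-product score invariant to per-voxel positive affine transforms
of the raw signal, which is the invariance a decoding analysis needs.
Voxels constant within a run are zeroed and flagged rather than producing
NaNs.

Scores are the plain scalar product of standardized data and coefficients
(no further normalization). One-versus-all labels are the per-volume
argmax; exact ties resolve to the lowest category index and are flagged —
ties have measure zero on continuous data but labeling must be
deterministic. Occupancy counts always sum to T.

## Synthetic generative model

The generator emulates the statistical structure the analyses assume, not
fMRI physics. Its components and defaults:

* **Voxel grid** — 10×10×10 lattice with a centered ball mask (radius 5.5,
  ≈672 in-mask voxels): desk-scale while exercising 3D mask logic.
* **Weight maps** — 7 rows, each with ⌈sparsity·V⌉ (default 10 %) nonzero
  standard-normal entries; a configurable fraction of support shared across
  rows (default 0, disjoint); rows scaled to unit ℓ2 norm, mirroring the
  near-equal norms of real emotion models.
* **Hidden states** — a first-order Markov chain over the 7 categories.
  No claim is made that spontaneous emotion follows a Markov process; it is
  the simplest generator of label runs and occupancy structure the
  downstream stages can detect. `dwell_transition(d)` gives the sticky
  chain (1−1/d)·I + (1/d)·1πᵀ.
* **Time series** — data[t] = amplitude · w_{state(t)} + AR(1) noise
  (lag-1 coefficient `ar_phi`, default 0.3; innovation sd `noise_sd`,
  default 1), independent across voxels. No spatial correlation, hemo-
  dynamics, physiological noise or motion: those are preprocessing
  concerns outside this pipeline, so passing tests says nothing about
  robustness to them.
* **Cohorts** — per-subject states are drawn independently per volume from
  an occupancy distribution whose tilted categories satisfy exactly
  logit(p_e) = logit(1/7) + β_e·covariate, the remaining mass shared
  equally by untilted categories. Independent draws (rather than a sticky
  chain) keep decoded counts binomial, matching the GLM fitted downstream;
  a dwell-structured cohort would overdisperse the counts and is left to
  the user. The default cohort amplitude is 10 (signal-dominated) so that
  decoded occupancy tracks planted occupancy and parameter recovery tests
  the inference, not the decoder.
* **Experience sampling** — probes every 30 s plus Poisson(λ = 4 s) jitter,
  so inter-probe gaps are ≥30 s and the first probe leaves a full
  pre-rating window. The hidden state is piecewise constant between
  probes, hence constant throughout each 10-s window. Reports match the
  window's state with probability `congruence`, else a uniform other
  category. The rating screen is modeled as 16 radial sectors with 4
  intensity rings and a central neutral disk; the original screen's
  hand-drawn polygons are unpublished, so a regular radial layout stands
  in. Terms map onto the seven categories (relief→content; joy,
  satisfaction→amusement; surprise/fear/anger/sadness/neutral as-is);
  other terms are dropped with a flag.
* **Network parcels** — disjoint random in-mask voxel sets (no contiguity),
  sufficient for overlap arithmetic.

Every generator is a pure function of its arguments including the seed.

## Temporal dynamics

Linear trends use OLS of score on the centered volume index per subject
(slope units: score per timepoint; a per-second regressor is a trivial
rescale) and a one-sample t test on slopes (df = n−1). Smoothing splines
are cubic with the penalty selected per subject by generalized
cross-validation, so the effective number of parameters may differ across
subjects; coherence r_cv(i) is the Pearson correlation between subject i's
fitted curve and the pointwise mean of the other subjects' fitted curves,
averaged over i. Constant fitted curves are excluded with a warning.
Splines are fit to the run-concatenated series.

Wavelet surrogates ("wavestrapping") use the Daubechies-4 wavelet at
maximal dyadic depth with periodized boundaries; detail coefficients are
permuted within each level and the approximation band is left intact, so
slow trends, the series mean, per-level energies and (approximately) the
autocorrelation function are preserved while temporal alignment is
destroyed. Periodization gives exact per-level multiset conservation for
any series length (reconstruction is truncated back to T for odd lengths).
Sign-flipping is deliberately not applied by default. The surrogate
frequency null relabels each surrogate draw by argmax, recounts, and
recomputes the across-category Friedman statistic; the empirical p uses
the add-one convention (1 + #{null ≥ observed})/(n_iter + 1), which cannot
return zero.

Note a consequence of keeping the approximation band: a *static* score
offset between categories survives surrogation, so the test is calibrated
against — not powered against — pure mean shifts. Its power lies against
occupancy structure the per-level energies cannot explain (e.g. asymmetric
score marginals or temporal coupling), which is what the test suite
exercises.

## Frequency statistics

Friedman tests use midranks with the standard tie correction; a fully tied
table yields statistic 0 and p = 1 rather than NaN. Wilcoxon signed-rank
tests report a z from the normal approximation with tie and continuity
corrections (positive z = above chance); below 25 nonzero untied
differences the p-value switches to the exact distribution. Pairwise
comparisons (21 category pairs) report mean within-subject rank
differences with simultaneous Nemenyi-type bounds (studentized-range
quantile at α = 0.05) and BH-FDR flags at q = 0.05 across all 21 tests; on
real data one would instead group the corrections into the targeted
families of a registered analysis — the synthetic pipeline corrects across
everything it emits.

Covariate GLMs are binomial with a logit link, one covariate at a time
(seven models per measure, no adjustment, plain binomial likelihood —
overdispersion handling is left as an option since the generative model is
exactly binomial); inference uses a t distribution with n−2 degrees of
freedom and slopes are reported with e^β odds ratios. Complete separation
is flagged non-converged. Subsample robustness draws k subjects (default
21) without replacement 1,000 times and correlates subsample mean
proportions with the full-sample means.

## Experience-sampling concordance

Pre-rating windows cover the ⌊window/TR⌋ whole volumes ending at the
volume of rating onset (exclusive); partial volumes and events too early
for a full window are dropped with a warning. Per subject, the congruent
value is the reported model's mean score over trials and the incongruent
value the mean of the six other models (averaged within trial first); the
identity (congruent + 6·incongruent)/7 = grand mean holds by construction.
Both samples are tested against zero with Wilcoxon signed-rank tests;
Lilliefors normality p-values are reported but never change the test
choice. Trialwise accuracy pools trials across subjects and is tested
against the marginal-product chance level Σ_e p_report(e)·p_decoded(e)
with a one-sided binomial test. Per-model accuracies are not reported
(rare categories make them unstable); the 7×7 confusion counts are emitted
instead. Frequency correlations are Fisher-transformed with |z| clipped at
atanh(1−1e−12) (flagged) before the one-sample t test, and the mean r is
back-transformed.

## Spatial diagnostics

Importance maps multiply a model's coefficients elementwise by the mean
standardized activity of that model's labeled volumes; subjects with zero
labeled volumes are flagged and excluded from the group stage. Group
inference is a voxelwise one-sample t test with BH-FDR at q = 0.05 over
defined voxels. Jaccard overlap thresholds the model map on |value| (both
signs inform classification; positive-only is available) at the quantile
committing the same number of voxels as the network parcel, then takes
intersection over union; the full 7×k matrix and per-emotion maxima are
both available. An empty union is defined as overlap 0 with a flag.

## Problem sizes and verification

The test suite and `scripts/acceptance.py` run everything at desk scale:
grids of 216–1,000 voxels (136–672 in-mask), T = 64–256 volumes, cohorts
of up to 500 subjects, 50-replicate power/recovery loops, and 100
meta-replicates for null calibration. These sizes give Monte-Carlo error
comfortably inside the asserted tolerances while keeping the full suite in
a few minutes. What passing shows: the estimators are correctly
implemented, calibrated under their own generative assumptions, and
recover planted effects of realistic magnitude (e.g. a 0.0025 log-odds
tilt over a 0–60 covariate range). What it cannot show: behavior under
spatially correlated, nonstationary or artifact-laden real fMRI noise.

## Known limitations

* The Markov/iid hidden-state model is a stand-in; no generative claim
  about spontaneous emotion dynamics is made or tested.
* The surrogate test's power profile depends on the keep-approximation
  convention (see above); scrambling the approximation band as well would
  trade trend preservation for sensitivity to mean shifts.
* The rating-screen geometry is a regular radial idealization of a
  hand-drawn original.
* Binomial GLMs assume independent volumes; sticky state dynamics would
  require quasi-binomial or cluster-robust extensions, not implemented.
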