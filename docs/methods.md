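# Methods

This note documents the models, conventions and design choices behind
`hrdelay`, in the order data flows through the pipeline.

## Signal model and phase conventions

The generative and analysis models share one clock: `t = 0` at the start
of a run, stimulus ON at each cycle start, cycle length `T` (default
12 s at TR = 1 s). The noise-free raw-intensity signal of voxel `v`
under condition `c` is

    raw(v, t) = B_v · [1 + m_v·t + (A_vc/100) · sin(2π(t − d_vc)/T)] + ε_t,
    ε_t ~ Normal(0, σ_v)

with baseline `B_v` (arbitrary scanner units), linear drift slope `m_v`
(fraction of baseline per second), signed amplitude `A_vc` (%BOLD, half
peak-to-peak) and delay `d_vc` (seconds). The sinusoid peaks at
`t = T/4 + d_vc` within each cycle: a zero-delay response peaks mid-ON
(3 s), which fixes the delay convention everywhere as
**delay = (fitted peak time − T/4) mod T**, larger = later. In the
complex response-vector representation `z = β_sin + i·β_cos` this is
`d = (−arg z · T/2π) mod T`; values a rounding error below `T` are
snapped to 0 (delay lives on a circle). Delays are only ever averaged by
complex (vector) averaging followed by the angle — never by arithmetic
means of delay values — and delay differences are wrapped to
(−T/2, T/2].

Amplitude modulation by condition: gratings at orientation θ use
`A_vc = A_v · (1 + κ_v · cos 2(pref_v − θ))`, a minimal cosine tuning
over the orientation circle (the field provides no agreed voxel tuning
model; this is the simplest structure making orientation decodable from
amplitude patterns). The plaid uses the untuned `A_v` (RMS-contrast
matched stimuli produce similar overall drive) and adds a uniform delay
shift to every stimulus-driven voxel. Negative-BOLD voxels invert the
sign of `A_vc` (phase + π), the simplest model consistent with a bimodal
voxel phase distribution. An optional second harmonic
(`second_harmonic_ratio`, default 0) can widen the positive lobe; it is
a stand-in, not a claim about real waveform shape.

## Generator defaults and what they emulate

Defaults are chosen once as realistic for 1 mm, TR 1 s gradient-echo EPI
of early visual cortex at 3 T:

| parameter | default | rationale |
|---|---|---|
| baseline `B_v` | N(1000, 50) a.u. | scanner-like raw intensities so the vein metric operates on absolute signal |
| noise σ_v | N(15, 3) a.u. (~1.5 %BOLD) | high-resolution thermal + physiological noise |
| amplitude `A_v` | N(1.2, 0.3) %BOLD | typical block-design V1 response |
| delay `d_v` | N(participant mean, 0.3) s; participant mean N(5.0, 0.5) s | observed V1 delays average ~4.9 s, range 3.6–5.6 s |
| tuning depth κ | N(0.3, 0.1), clipped ≥ 0 | makes ±45° decodable without saturating |
| drift slope | N(0, 1e-4) /s | up to ~±1% over a run |
| negBOLD fraction | 0.33 | fraction of ROI voxels anti-phase to the stimulus |
| vein fraction | 0.20 | matches the 80th-percentile vein cut |
| plaid delay shift | 0.18 s, between-participant SD 0.08 s | group effect ~180 ms, per-participant range ~80–330 ms |
| run delay jitter | SD 0.15 s | hemodynamic state fluctuations between runs |
| run amplitude jitter | SD 10% (multiplicative) | idem |
| session effects | amplitude scale SD 5%, delay offset SD 0.1 s | makes cross-session CV non-trivial |

Run- and session-level global jitters matter: without them, run-resampled
bootstrap CIs of delay estimates would be implausibly narrow and
cross-session validation would be trivially easy. With them, per-estimate
(participant × condition) 95% CI widths land in the 0.1–0.6 s range
observed in real data.

Flags are constructed, not merely sampled: negative-BOLD voxels are
placed outside the stimulus annulus (0.75–7 dva within a 0–10 dva field);
vein voxels draw baseline from 0.5–0.8× the non-vein median and noise/
amplitude from 2–4× the non-vein medians, so the defining property (low
baseline, high variability, large responses) holds exactly and is
testable.

What the generator does **not** emulate: spatially correlated
(physiological) noise, cortical-depth structure, scanner drift
nonlinearity, motion, distortion, or any anatomical registration error.
Passing tests therefore demonstrate the *statistical machinery* —
unbiased estimation, correct test sizes, leak-free cross-validation,
recovery of injected effects — not performance on real scanner data;
absolute AUC levels in particular are optimistic because voxel noise is
independent.

## Estimation

%BOLD conversion is per run and voxel: `100·(raw − mean)/mean`; voxels
with non-positive run mean are flagged NaN and excluded downstream. The
sinusoidal and FIR GLMs share one OLS core: rows of the first
`n_censored_cycles` (default 2, i.e. 24 timepoints) are dropped; the
drift regressor is the volume index centered on the retained rows
(removing baseline/drift collinearity; whether to center is not
externally constrained — centering is this package's choice); interest
and nuisance regressors are fit jointly in a single OLS. Rank
deficiency raises an error naming the collinear columns. The FIR model
uses one delta regressor per cycle position 1…11; position 0 is absorbed
by the baseline, so reconstructed waveforms start at exactly 0.

Display-only HR normalization rescales a participant's zero-centered
waveform by the group/participant amplitude ratio and circularly shifts
its time axis by the participant-minus-group delay difference using a
periodic cubic spline. It exists to overlay waveform *shapes* and never
feeds statistics.

## Selection cascade

Stage A replaces a full iterative contour-extraction heuristic with a
simplified, isolated stand-in: eccentricity is warped by its empirical
CDF over ROI voxels (uniformizing voxel density, emulating cortical
magnification compensation), the 0/1 polarity indicator is smoothed over
warped visual-field Cartesian coordinates with a Gaussian kernel
(bandwidth 0.5 warped units, configurable), and a voxel passes when the
smoothed polarity exceeds 0.5 *and* it lies inside the stimulus annulus.
Fewer than 10 in-annulus voxels triggers a fallback to annulus
membership with a warning. The interface isolates this step so the full
heuristic could be substituted later.

Polarity itself is the wrapped phase difference to the ROI-averaged
vector: positive iff in (−π/2, π/2], the upper bound inclusive as a
documented tie-break; zero-amplitude voxels are negative by convention.

Stage B uses the one-sample Hotelling T² on the 2-D vector coordinates,
`T² = n·m̄ᵀS⁻¹m̄`, `F = (n−p)/(p(n−1))·T²` on (p, n−p) df with p = 2,
α = 0.05 with *no* multiple-comparison correction (deliberately, as in
the procedure this implements). Stage D ranks voxels by the one-way
MANOVA condition effect, scaled as `T² = (N−k)·trace(W⁻¹B)`
(Hotelling–Lawley); with two groups this reduces to the classic
two-sample T², and only the ranking matters for the percentile cut. The
repeated-measures structure of the original MANOVA adaptation is not
recoverable; runs are treated as independent samples. Singular scatter
matrices (e.g. identical vectors) yield NaN and the voxel fails the
stage, with the reason logged.

The vein metric is computed on the **raw** (not %BOLD) series: SD of the
baseline+drift-detrended residuals (denominator n−2) over the run-mean
baseline, averaged across runs. Percentile cuts use linear interpolation
between order statistics and *strict* comparisons (ties at the threshold
are excluded); stage C keeps voxels strictly below the 80th percentile
of the vein metric over A∧B passers, stage D strictly above the 20th
percentile of condition T² over C passers. If a strict comparison
empties the pool (all values tied), the filter falls back to the
non-strict comparison with a warning. Masks nest by construction:
D ⊆ C ⊆ A∧B.

## Decoding

Normalization and z-scoring statistics always come from the training
session — applying train statistics to test data is the only
non-circular reading of "normalizing the training data". The per-voxel
complex divisor is the train-run mean (train mean maps exactly to
1 + 0i); voxels with zero train mean are dropped from both sets.
Encodings: `delay` = angle wrapped to (−π, π] (near zero after
normalization, so residual wraps are rare but handled); `amplitude` =
modulus; `both` = the n×2p matrix `[all real parts | all imaginary
parts]`, column order fixed for reproducibility. z-scoring is per
encoded column (the per-voxel-pair alternative for the 2p case is
ambiguous in the source description; per-column is implemented). The
classifier is `sklearn.svm.SVC(kernel="linear", C=1)` — the libsvm
C-SVC with its default regularization. AUC is computed threshold-free
from decision values in the Mann–Whitney form (ties half-credit).

Cross-validation is strictly between sessions: selection, normalization
and training use session i; only the trained model crosses to session
j ≠ i, restricted to session i's voxel selection; both directions are
reported and averaged. When response vectors are averaged across voxels
for *reporting* (condition means, delay effects), each session instead
uses the *other* session's selection, again avoiding circularity.

## Inference

Permutation nulls shuffle condition labels independently within each
3-run triplet — the unit within which run order was randomized — "before
estimation": since per-run OLS is label-free, this is implemented by
relabeling run-level vectors and re-running every label-dependent stage
(the stage-D cut and the SVM); a test asserts the equivalence against a
literal re-analysis with reordered runs. The permutation p is the plain
fraction of null values ≥ observed (no +1 correction), and significance
requires the observed AUC to exceed the null's 95th percentile, matching
the 95%-of-null criterion exactly. A cached fast path (numerically
identical to the estimator path, asserted by a test) makes the default
8,192 permutations tractable.

Bootstrap CIs resample with replacement at original size — runs for
single-participant statistics, participants for group statistics — with
central percentile intervals (95% default, 90% for error-bar style
displays). The bivariate credible contour evaluates a Gaussian KDE
(Silverman's rule by default; bandwidth exposed as a parameter since no
external value constrains it) at every resampled 2-D mean and lowers the
density threshold until ≥95% of resamples are enclosed; the polygon is
extracted from a grid at that level.

Group tests are the standard textbook forms (one-sample/paired t,
Wilcoxon signed-rank, one-way and 2×2 repeated-measures ANOVA via
`statsmodels` AnovaRM, Pearson/Spearman), validated against independent
hand-formula computations in the tests.

Seeding: one master seed; child seeds derive via `numpy` SeedSequence
spawning, so every stage is reproducible bit-for-bit and independent
analyses do not share streams.

## Problem sizes and numerical choices

Tests and the calibration script run desk-scale problems chosen for
statistical resolution: 40–120 voxels, 5 triplets per session (the low
end of the 5–7 used in the emulated design), 100 null studies for the
chance-level check, 10,000 voxels for the test-size check, 400 datasets
× 512 permutations for the specificity check, and 48 simulated
participants where a 3-standard-error bound must resolve an AUC effect
of ~0.1 against chance. Calibration targets themselves (α = 0.05, the
80/20 percentiles, 95% significance rule) are never adjusted.

Degenerate inputs are handled explicitly rather than silently: zero
amplitude ⇒ delay undefined (error); zero-variance encoded columns are
dropped with a log message; singular covariances fail stage B; empty
percentile pools raise; all-tied pools fall back non-strictly with a
warning.

## Known limitations

* Stage A is a simplified stand-in for a full contour-extraction
  heuristic; it assumes reasonably dense, annulus-respecting coordinates.
* Independent voxel noise makes amplitude decoding saturate near AUC 1.0
  at realistic amplitudes; relative comparisons between encodings remain
  meaningful, absolute levels do not transfer to real data.
* The condition-sensitivity statistic treats runs as independent samples
  (no run-repetition factor).
* No multiple-comparison correction anywhere, by design.
* Real-data ingestion expects preprocessed, session-aligned voxel
  timeseries (NIfTI + metadata); no registration or preprocessing is
  performed.
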