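# hrdelay

**Decoding stimulus information from the apparent delay of fMRI BOLD
responses.**

Most fMRI analyses treat the hemodynamic response (HR) *amplitude* as the
signal and its shape — in particular its delay — as a vascular nuisance.
Under periodic visual stimulation, however, the BOLD response reduces to a
sinusoid whose *phase* is a sensitive proxy for HR delay, and spatial
patterns of these apparent delays across V1 can carry stimulus information
of their own (for example, cross-orientation suppression induced by plaid
overlays lengthens the V1 response delay by ~0.2 s while leaving amplitude
unchanged).

`hrdelay` is a tested, reusable implementation of that analysis for
researchers working with periodic-design visual fMRI: a synthetic-study
generator with known ground truth, sinusoidal and model-free (FIR) response
estimation, a four-stage voxel selection cascade, linear-SVM decoding of
delay/amplitude patterns with strict between-session cross-validation, and
permutation/bootstrap inference.

## The model

Each 120 s run presents one stimulus condition (−45° grating, +45° grating,
or a plaid overlay) in 10 cycles of 6 s ON / 6 s OFF at TR = 1 s. After
conversion to %BOLD relative to the run mean, each voxel's run timeseries
is fit by OLS with

* regressors of interest `sin(2πt/T)`, `cos(2πt/T)` at the cycle length
  `T = 12 s`,
* nuisance regressors (constant baseline, linear drift),
* the first two cycles (24 timepoints) censored.

The fit coefficients form the complex **response vector**
`z = β_sin + i·β_cos`: `|z|` is half the peak-to-peak response amplitude
(%BOLD) and the phase of `z` gives the **apparent delay**
`d = (t_peak − T/4) mod T`, the fitted peak time relative to mid-ON.
Delays are always averaged circularly (complex mean, then angle). A
model-free HR is estimated by replacing the sine/cosine pair with 11 delta
(FIR) regressors covering cycle positions `t0+1 … t0+11`.

Per session, voxels pass four selection stages: (A) the stimulus'
cortical representation, from the smoothed positive/negative-BOLD polarity
map in density-uniformized visual-field coordinates; (B) stimulus-driven
voxels, by a one-sample Hotelling T² test of the mean response vector
against the origin (α = 0.05, uncorrected); (C) non-vein voxels, keeping
those below the 80th percentile of the vein-likeliness metric
(SD of the detrended raw signal / baseline); (D) the most
condition-discriminant voxels, keeping those above the 20th percentile of
the condition T² (Hotelling–Lawley) statistic.

Decoding trains a linear C-SVM (libsvm backend, C = 1) on run-by-voxel
patterns of delay (vector angles), amplitude (vector lengths), or both
(real and imaginary parts concatenated), after voxel-wise complex
normalization and per-column z-scoring estimated on the training session
only. Performance is the ROC AUC of the decision values on the *other*
session's runs; significance comes from within-triplet label permutation
(observed AUC must exceed 95% of its null), and confidence intervals from
bootstrap resampling (runs within participant, participants at the group
level; 2-D effects use a Gaussian-KDE 95% credible contour).

## Worked example

Simulate a six-participant study at the default generator settings
(orientation-tuned amplitude patterns plus a 0.18 s plaid delay shift),
run the full pipeline, and summarize:

```python
import json
from hrdelay import StudyDesign
from hrdelay.pipeline import StudyConfig, run_study

cfg = StudyConfig(design=StudyDesign(n_triplets_per_session=5),
                  n_participants=6, n_voxels=120,
                  n_permutations=0, n_resamples=2000, seed=7)
bundle = run_study(cfg, "results/example")
summary = json.loads((bundle / "summary.json").read_text())
```

The AUC summary (`auc_summary.csv`) from this exact run:

```
  auc  ci_high  ci_low  encoding       pair_type
0.696    0.721   0.670     delay             all
0.540      NaN     NaN     delay grating|grating
0.773      NaN     NaN     delay   plaid|grating
1.000    1.000   1.000 amplitude             all
1.000      NaN     NaN amplitude grating|grating
1.000      NaN     NaN amplitude   plaid|grating
0.999    1.000   0.997      both             all
1.000      NaN     NaN      both grating|grating
0.998      NaN     NaN      both   plaid|grating

group plaid-grating delay: 231 ms [177, 286] ms (95% bootstrap CI)
t(5) = 7.43, p = 0.001
```

Read it as the double dissociation the pipeline is designed to expose:
amplitude patterns decode every condition pair, while delay patterns
decode only the pairs involving the plaid (0.77 vs 0.54 for the two
gratings — chance is 0.5), because the generator injects a delay shift
only for the plaid condition. The group-level circular-mean delay
difference (231 ms here; each synthetic participant draws their own true
shift around 180 ms) is recovered with its bootstrap CI. Synthetic data
at these settings are cleaner than real scanner data, so the amplitude
AUCs saturate; see `docs/methods.md` for what the simulation does and
does not emulate.

The same pipeline is scriptable from the shell:

```bash
hrdelay run-all --config config.yaml --seed 7 --out results/example
hrdelay simulate|estimate|select|decode|infer|summarize --help
```

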