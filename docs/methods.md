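# Methods

This note documents the models behind `gaitpress`, the parameters that
matter, and the choices made where the design was genuinely open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sensor-array model (`pressure_model`)

Each cell of the 8×8 mat is a force-sensing resistor obeying
`R = k_pr / P` (`k_pr` in Ω·kPa; default 1e5, placing the full 0–1000 kPa
detection range inside the ADC span without saturation — at the default
feedback resistor `r_f = 900 Ω` a 1000 kPa load reads exactly full scale).
The amplifier/ADC chain is
`D = 2^m (k_pr + P·r_f)/k_pr · v_ref/v_adc_ref` with `v_ref = 0.5 V`,
`v_adc_ref = 5 V`, `m = 10`; the real-valued `D` is **floored** then
clipped to `[0, 2^m]`, matching ADC truncation (the rounding convention is
otherwise arbitrary, so it is fixed and documented). Zero load is an open
circuit; in network computations it is represented by a large sentinel
resistance (1e12 Ω) so the linear solver stays well-posed.

Scanning is simulated in two modes. With the zero-potential drive
(unselected rows grounded, unselected columns at `v_ref`) every sneak path
is cut and the scan equals the ideal per-cell ADC output bit for bit. With
the drive off, the measured resistance of the selected cell is the
two-terminal resistance of the whole crossbar with all other lines
floating, obtained by solving the 16-node Laplacian system (full nodal
analysis, not a truncated path expansion; the same solver handles the
small arrays used as oracles in tests). The parasitic coupling strength is
the finite zero-load resistance `r_leak` of real FSR cells (default
1e4 Ω), which is what lets current sneak through nominally unloaded
neighbors: a single 400 kPa load then perturbs cells sharing its row or
column by roughly ten counts and distant cells by less, while the
elimination drive reduces the perturbation to zero.

Calibration fits counts against load (kg) by ordinary least squares
(`scipy.stats.linregress`); the up-down 0→11→0 kg protocol is treated as
one pooled fit. All loads equal is a degenerate design and an error.

## Synthetic gait generator (`gait_synth`)

No public dataset of children's insole pressure exists for this task, so
the generator is a first-class, tested component that defines the study
conditions.

**Spatial templates.** The grid is mapped to anatomical regions (heel rows
0–1, midfoot rows 2–3, forefoot rows 4–7; column 0 medial). The normal
template carries ~30% of load on the heel, ~10% on the midfoot (the medial
arch cells at zero) and ~60% on the forefoot. Pathological templates apply
the published regional load-shift factors before renormalization: ×1.61
lateral midfoot and ×1.49 lateral forefoot for toe-in; ×1.72 medial
midfoot and ×1.52 medial forefoot for toe-out. Flat foot activates the
previously unloaded arch cells at the mean loaded-midfoot weight and
shifts load toward the midfoot (×1.3) — the enlarged contact area by which
flat foot is clinically diagnosed.

**Dynamic model.** Walking is periodic at the subject's cadence
(1.8–2.4 steps/s in the default roster) with a 60% stance fraction
(standard gait physiology). Within stance, heel → midfoot → forefoot
raised-cosine activation bumps (centers 0.13/0.30/0.45 of the cycle)
reproduce the rolling load transfer; swing is unloaded. The instantaneous
grid is `mass · kpa_per_kg · (template/max) · envelope` plus truncated
Gaussian noise, clipped to the 0–700 kPa children's range
(`kpa_per_kg = 12`, so an 18–38 kg child peaks at 216–456 kPa). Because
the envelope is smooth and cadence ≲ 2.4 Hz, effectively all non-DC
spectral energy falls below 10 Hz — the premise of the five 2-Hz feature
bands — which a test verifies by direct DFT integration.

**Static model.** Standing is the mass-scaled template modulated by a slow
(0.3 Hz, ±4%) medial-lateral sway, with a per-trial log-normal regional
perturbation (`posture_sd = 0.12`) representing the unnatural poses
children adopt when asked to stand still, plus sensor noise. Mass scales
the whole grid and is cancelled by the downstream unit normalization.

**Subjects and datasets.** Each subject gets a deterministic log-normal
footprint jitter keyed on the subject id (`subject_jitter_sd = 0.05`), a
mass, cadence and a foot-progression angle consistent with the diagnosis
(normal within −3°…+20°, toe-in below, toe-out above; FPA is metadata
only — class identity drives the template). The default roster has 17
children with a 9 flat / 4 normal / 2 toe-in / 2 toe-out mix.
`make_dataset` computes recording durations so that downstream windowing
yields exactly the requested samples per class, and derives all per-
recording seeds from one `SeedSequence`, so datasets are bit-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: left/right asymmetry, inter-stride timing
variability, foot placement shifts on the mat, sensor drift/hysteresis,
and the true within-class heterogeneity of clinical populations. Accuracies
on this synthetic study characterize the pipeline's correctness, not
expected clinical performance; headline numbers from hospital data are not
reproducible without those recordings.

## Preprocessing (`preprocess`)

The One Euro filter (first-order adaptive low-pass whose cutoff rises
linearly with the filtered derivative) is provided for display smoothing
of streaming data, initialized by passing the first sample through, with
defaults `min_cutoff = 1 Hz`, `beta = 0.05`, `d_cutoff = 1 Hz`. It is
**off** in the classification pipeline: it belongs to the acquisition GUI,
not the recognition method. Sliding windows default to 512 frames with a
25-frame (0.5 s) stride, giving many overlapping training samples per
trial; standing trials are cut into non-overlapping 100-frame (2 s)
segments, dropping the remainder.

## Features (`features`)

"Amplitude" is read as the magnitude |S(k)|, not power, and band sums use
the one-sided bins 1…L/2 only (real inputs; the doubling convention is
irrelevant after unit normalization). Band edges are half-open (lo, hi] at
bin frequencies k·fs/L, so the DC bin never contributes and each bin lands
in exactly one band. The Hann taper has the same 512-frame width as the
DFT. The 30-cell sensor mask (a 3×2 heel block, two midfoot rows of six,
and a 4×4 forefoot block minus corners, in row-major order) is a
configuration item: what matters downstream is its size and order, which
fix the 150-/30-element feature dimensions. An all-zero window (e.g. a
lifted foot) yields a flagged all-zero vector rather than an error, for
robustness in streaming use.

## Reduction (`reduction`)

PCA centers the data, takes the SVD (equivalent to eigendecomposing the
(n−1)-denominator sample covariance but numerically stabler) and keeps the
minimal leading components reaching the explained-variance target. LDA
solves the generalized symmetric eigenproblem `S_B w = λ S_W w`; since
`S_W` is singular whenever features (150) outnumber samples, it is
regularized with a ridge `1e-6 · trace(S_W)/p · I`. Both fix eigenvector
signs by making each component's largest-magnitude entry positive, so
serialized models are reproducible. LDA output dimension defaults to
C−1 = 3 for the four gait classes.

## Classifiers (`classify`)

The SVM dual is solved by SMO with Platt's two-level partner selection:
for each KKT-violating example (tolerance 1e-3 by default), first the
partner maximizing |E_i − E_j|, then, if that step stalls, the remaining
examples in index order — all deterministic, so training needs no RNG.
Each pair step solves its two-variable subproblem exactly, which is why
the dual objective is non-decreasing (asserted in tests against a recorded
objective trace, and the final solution against a brute-force QP on small
problems). Multiclass uses one-vs-one voting with ties broken by class
order. The RBF `gamma` defaults to the scale convention
1/(n_features · Var X) with the variance pooled over all feature entries.

The network is intentionally minimal: 3 layers total, 10 logistic hidden
units, softmax output, full-batch gradient descent on cross-entropy for
500 epochs. The learning rate is 0.5: with full-batch descent and unit-norm
inputs the loss surface is gentle, and substantially smaller rates (e.g.
0.01) fail to fit even cleanly separable 4-class data within the default
epoch budget. Weight initialization is the only randomness, so a seed
fixes the trained model exactly.

## Evaluation (`evaluate`)

Stratified k-fold shuffles within class and deals round-robin, keeping
per-fold class proportions within one sample. The reducer and classifier
are fitted inside each fold on the training split only. Reported metrics
mirror the standard results-table layout: per-class recall in the
canonical order (normal, toe-in, toe-out, flat), macro-averaged precision
in percent (with overall accuracy also reported, since "precision" and
"accuracy" are often used interchangeably for that single percentage), the
fold-averaged confusion matrix (rows actual, columns predicted), and the
wall time to predict a reference batch (2000 dynamic / 130 static
samples). Timing is hardware-dependent and excluded from automated
assertions. LOSO holds out one subject per round and skips (with a
warning) rounds whose training split lacks a class. Fold-accuracy
comparisons use a two-sample t-test — Welch by default, pooled variance as
an option — with the degenerate equal-constant-groups case defined as
t = 0, p = 1.

## Problem sizes

The reference synthetic study uses 200 samples per class (800 per
section), tenfold CV; the generalization study uses 60 windows per class
over 8 subjects with exaggerated footprint jitter (`subject_jitter_sd =
1.2`) to create the subject-confounded regime in which within-subject CV
stays high while LOSO collapses toward chance. These sizes exercise every
code path at comfortable statistical resolution while keeping the whole
acceptance run under a minute.

## Known limitations

- The crosstalk model is first-order physical (leak resistance + nodal
  analysis); real mats add wiring resistance, amplifier input impedance
  and temperature effects that are not modeled.
- The One Euro filter parameters are display-oriented defaults, not tuned
  against any reference implementation's traces.
- Kernel PCA, alternative LDA formulations, probability calibration and
  other transforms (FWT, DCT) are out of scope.
- The generator emits a single instrumented foot and no gait-phase
  labels; phase segmentation (IC/LR/MS/TS/PS/SP) is display vocabulary,
  not a pipeline stage.
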