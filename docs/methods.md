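# Methods

This note documents the models, estimators and numerical choices in
`tgpac`, in the spirit of a package methods appendix: what is computed, under
which assumptions, which defaults matter, and what the synthetic testbed can
and cannot show.

## Signal model of the synthetic generator

One trial of one channel is

    s(t) = a_theta * cos(2*pi*f_theta*t + psi)
         + a_gamma * [1 + m(t) * cos(2*pi*f_theta*t + psi - phi_c)] * cos(2*pi*f_gamma*t)
         + noise_amp * n_{1/f}(t)

* `f_theta = 6 Hz`, `f_gamma` default 40 Hz, sampling rate 1000 Hz (any
  `fs > 2 f_gamma` is accepted), epochs −1500..2500 ms around stimulus onset.
* **Modulation law.** Gamma amplitude is multiplicatively modulated,
  `1 + m cos(θ − phi_c)`, so the depth `m ∈ [0, 1]` is directly
  interpretable (0 = none, 1 = envelope touches zero) and the envelope stays
  nonnegative.  The underlying physiology offers no unique generative form;
  this is the simplest law whose envelope phase equals the theta phase minus
  `phi_c` exactly, so the generator's own bookkeeping can serve as the
  oracle for recovery tests.
* **Pre/post switch.** `m(t)` moves from the pre-stimulus to the
  post-stimulus depth through a 50 ms raised-cosine crossfade at t = 0;
  an abrupt switch would inject broadband energy that the wavelet stage
  would smear into both analysis windows.
* **Theta phase.** `psi` is uniform per trial and shared across channels
  (one coherent theta source), making trial averaging of PLV meaningful and
  non-degenerate.
* **Background.** 1/f noise (power exponent 1, typical of broadband EEG) is
  synthesized by inverse-FFT spectral shaping of white Gaussian noise,
  normalized to unit variance and scaled by `noise_amp`.
* **Amplitudes.** Defaults `a_theta = 10 μV`, `a_gamma = 2 μV`,
  `noise_amp = 5 μV`.  The single-trial gamma SNR of real recordings is not
  publicly characterized for this paradigm; `noise_amp` is therefore a free
  parameter, fixed once so that the 100-trial post-window PLV at `m = 0.5`
  clearly exceeds its permutation null (it does: ≈ 0.39 against a null mean
  ≈ 0.18) while `m = 0` stays inside the null.
* **Phase heterogeneity.** Each channel can carry a fixed offset to
  `phi_c` (drawn uniformly when a cluster's `phase_spread` is set).  This is
  the mechanism behind the cluster-homogeneity phenomenon: per-electrode PLV
  is invariant to the offset, but cluster-averaged phase-binned profiles
  flatten when offsets scatter.

The generator does **not** emulate: volume conduction/head-model mixing,
eye-blink or muscle artifacts, non-stationary theta frequency, trial-to-trial
amplitude drift, or continuous recordings.  Passing tests on this testbed
therefore demonstrates estimator correctness (recovery of injected coupling,
calibrated nulls, contract arithmetic), not robustness to every artifact of
real scalp data.

The behavioral generator is the high-threshold observer that the capacity
formulas invert: K of S items stored, detection iff the relevant item is
stored, otherwise a "change" guess with probability g.  Whole-display test
arrays give P(hit) = k + (1−k)g and P(FA) = g with k = min(K/S, 1);
single-probe arrays give P(FA) = (1−k)g.

## Preprocessing

* Re-referencing subtracts the mean of named reference channels (e.g.
  averaged mastoids); baseline correction subtracts each channel/trial's
  mean over a window, default −200..0 ms (the conventional choice; only
  "pre-stimulus" is prescribed by the paradigm).
* Trial rejection: peak-to-peak per channel over the full epoch, rejecting a
  trial when **any** channel exceeds 150 μV.  Whether the original criterion
  was per channel or pooled is not documented anywhere; the any-channel rule
  is the stricter reading and is logged per trial.
* CSD: spherical-spline surface Laplacian (Perrin-type; stiffness m = 4,
  ridge λ = 1e−5, Legendre series to order 50 — common toolbox defaults),
  solved as one augmented linear system per dataset.  A Hjorth
  nearest-neighbor variant (channel minus mean of its k = 4 nearest
  neighbors) serves small or planar synthetic montages where the spline is
  ill-posed (< 8 channels).  Both are reference-free.  The in-silico studies
  default to voltage (no CSD) because the synthetic montage has no volume
  conduction to undo; a warning notes this.
* ICA eye-blink correction and bad-channel interpolation are out of scope;
  a hook records that they were skipped so manifests stay honest.
  No filtering is applied.

## Time-frequency decomposition

Complex Morlet wavelets, 5 cycles (σ_t = n_cycles/(2πf)), truncated at
±5 σ_t, FFT convolution.  Amplitude is the modulus and phase the argument of
the coefficient — the only reading consistent with the PLV formula.  The
kernel is normalized so a unit-amplitude sinusoid at the wavelet's frequency
yields modulus ≈ 1; since PLV is phase-only downstream, the normalization
convention has no effect on coupling values (verified against mne's
L2-normalized implementation up to the predicted √f factor).  Edge samples
within n_cycles/(2f) seconds of either epoch boundary are masked invalid per
frequency rather than padded; both analysis windows must lie inside the mask
(for 6 Hz theta the mask is 417 ms, and the pre window starts 560 ms inside
the epoch).  The analysis grid is integer frequencies, 2–70 Hz.

## Coupling estimation

* **Envelope phase.** The windowed envelope is demeaned before the analytic
  signal: the envelope is nonnegative, so without demeaning its Hilbert
  phase is DC-dominated and the PLV degenerates toward 1 regardless of
  coupling.  A constant envelope has no phase; such cells are flagged NaN,
  never silently computed.
* **Windows.** Half-open sample ranges at the recording's rate; at 1000 Hz
  the pre window (−940..−200 ms) has 740 samples and the post window
  (300..1900 ms) 1600.
* **Splicing.** To equalize sample counts, each trial's (theta phase,
  envelope phase) *pairs* are resampled to the target length:
  ⌊target/N⌋ full random permutations plus a without-replacement remainder,
  so multiplicities differ by at most one.  Splicing phase pairs (rather
  than raw signal) avoids corrupting wavelet and Hilbert phases with
  discontinuities.  The near-equal multiplicities keep the spliced chance
  level within ~2 % of the 740-unique-sample Rayleigh level (√π/2/√740 ≈
  0.0326); drawing the remainder with replacement would inflate it by
  ~12 %.  The splice bias — chance level tracking unique samples, not
  spliced length — is characterized by tests, not hidden; spliced and
  unspliced pre-window PLV can be computed side by side.
* **Permutation null.** Default: per-trial random circular shift of the
  theta-phase series, preserving autocorrelation — the choice that yields a
  calibrated false-positive rate (coverage of the null's central 95 %
  interval at m = 0 measured at 91–94 % over 100-run batches).  Shifts are
  drawn over the full 1..N−1 range: with trial averaging, a few near-zero
  lags cannot pull a permutation's mean toward the observed value; a
  `min_shift_frac` option exists for single-trial nulls where they could.
  The literal time-point shuffle of theta phases is available as
  `method="timepoint_shuffle"`; its null mean matches the iid Rayleigh
  level.  Nulls are computed with an FFT cross-correlation over all shifts
  (exact, verified against brute force) and follow the identical
  window/splice/trial-average aggregation path as the observed PLV.
* **Aggregation.** Unweighted means: first across a band's 1 Hz frequency
  rows (25–35 and 45–55 Hz bands have 11 each), then across a cluster's
  electrodes.
* **Phase-binned profiles.** Amplitude is normalized per trial by its
  within-window mean, pooled across trials into 18 equal-width theta-phase
  bins (20°; the bin count is unspecified in the source methods and 18 is a
  common choice).  Empty bins are NaN.  The profile's modulation depth is
  its first-harmonic amplitude (projection on e^{iθ}), robust to bin noise;
  the count-weighted mean of bin means is exactly 1 by construction.

## Capacity

`k_formula` computes Pashler's K = S(h−f)/(1−f) (whole display; undefined at
f = 1) and Cowan's K = S(h−f) (single probe).  Negative estimates are
returned as computed.  The overall estimate is the unweighted mean across
set sizes ≥ 2 (configurable): a one-item display saturates for any realistic
capacity.  More generally, recovery is only identified for set sizes above
the true capacity — at S ≤ K the display saturates (h = 1) and K̂ is capped
at S — so consistency checks use supra-capacity set sizes (e.g. true K = 3
with S ∈ {4, 6}, where bias at 200 trials/set size is < 0.01 items).

## Statistics

The design is balanced within-subject, so the planned mixed-model contrast
reduces algebraically to per-subject scores tested against zero: window
effect (post − pre), focused task contrast with weights (2/3, −1/3, −1/3)
over (WM+, WM−, passive), and their interaction (the contrast of post − pre
differences).  Cohen's d is the classical one-sample d of the per-subject
scores (mean/SD) — deliberately not comparable to mixed-model effect-size
conventions that can produce d in the thousands for near-zero residual
variance.  Tests are two-sided by default with a one-sided option for the
directional hypothesis.  Pearson r uses the exact t transform; BH-FDR wraps
the standard step-up (tested against a brute-force enumeration).
Zero-variance scores are flagged, not silently turned into infinities.
Greenhouse–Geisser RM-ANOVA and Bayes factors are not reimplemented; the
exported subject × condition × window × cluster × band table is the input
any established routine needs.

## Pipeline, determinism, problem sizes

Every stochastic step takes an explicit seed; per-subject seeds derive from
the study seed via `SeedSequence`, and rerunning a config reproduces every
table byte-for-byte.  The run directory contains tidy CSVs and a manifest
with the package version, seed and full config.

The in-silico replication studies are run at reduced scale chosen to keep a
full 100-run batch around three minutes on one core while leaving the
qualitative result unambiguous: 20 subjects, 3 conditions × 10 trials,
single channel per cluster, one gamma frequency (40 Hz), 500 Hz sampling,
post-stimulus depth 0.4 (and 0.8 for the inflated-WM+ alternative).  The
type-I-error study of the focused contrast draws 1000 subject-level cell
tables directly from a Gaussian subject-intercept model with equal condition
means — the contrast consumes the cell table, so nothing is lost by not
simulating EEG for each of the 1000 studies.  `scripts/acceptance.py` states
the size (`n`) it used next to every value it reports.

## Known limitations

* Within-electrode coupling only; no cross-electrode (distal) PAC, no
  comodulograms over theta frequencies other than 6 Hz, and no alternative
  PAC metrics (modulation index, mean vector length, GLM-PAC).
* The circular-shift null's coverage is close to, but ~1–3 points below,
  nominal at these window lengths (finite permutation counts and the wrap
  discontinuity); detection decisions at the 99th percentile are
  conservative with respect to this.
* The spherical-spline CSD assumes a spherical head and unit-sphere
  electrode positions; no realistic geometry.
* Synthetic realism limits listed above; real-data import is limited to the
  native container format.
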