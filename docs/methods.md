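# Methods

## Stimulus model

Each color stream is a random walk on the hue circle: a uniformly random
starting hue, a step of exactly 1° per frame at 60 frames/s for 480 frames
(8 s), and a walk direction that can revert at candidate frames spaced by
independent uniform integer draws from 30–100 frames. At each candidate the
direction reverts with probability `reversal_prob` (default 1.0). Two streams
form a trial only if their circular distance is ≥ 60° at *every* frame; pairs
are formed by rejection sampling (or by greedy scan over a pre-computed
pool), which conditions only on the separation constraint and therefore
leaves the two histories otherwise independent. For probe-time targets a
trial is truncated at a uniform random length of 360–480 frames (6–8 s).

Hue angle maps to color as a circle of radius 0.0576 in CIE u′v′
chromaticity, centered on the white point (u′=0.1978, v′=0.4683) at
14.5 cd/m² — 0° on the +u′ axis, counter-clockwise positive. Rendering
(dot clouds, display calibration) is out of scope.

**Reversal statistics caveat.** With certain reversal at uniform 30–100-frame
intervals, a 150-trial set shows ≈ 14 combined reversals per trial and a mean
combined inter-reversal interval of ≈ 0.52 s (see
`analysis/01_simulate_stimuli.py`). Published descriptions of this paradigm
report fewer, more irregular reversals, implying a per-candidate reversal
probability below 1 (the phrase "could revert" leaves it unspecified); hence
`reversal_prob` is an explicit configuration parameter and no test asserts
specific reversal statistics. The hue-intersection fraction of the two
streams likewise depends strongly on this parameter and on the pairing
procedure, and is reported descriptively only.

## Observer model

The synthetic observer reports each probed target with von Mises error whose
concentration depends on which stream currently holds the high-precision
resource: `sd_high` for the favored stream, `sd_low` for the other
(`0 < sd_high ≤ sd_low`, defaults 8°/16° — a two-to-one precision split of
realistic magnitude for continuous color report). Allocation is either

- **fixed** — the favored stream is drawn once per trial with probability ½, or
- **alternating** — favor at probe time `t` follows the sign of
  `cos(2πf·(t − t_cue) + φ)`, a deterministic phase function at `f` Hz
  (default 1), with the phase reset by the luminance cue (0.2 s after hue
  onset) on cue-present trials and randomized per trial otherwise. A
  deterministic phase function is used because the downstream claim under
  test is an antiphase relation, not a switching-time distribution.

In dual-report trials the favored stream is reported first with probability
`first_confidence` (default 0.9). The observer emits no uniform guesses and
no swap errors by default (the mixture under test has no such components);
an optional `swap_rate` exists to stress the pairing rule. These are the
respects in which the generator is deliberately simpler than real data —
passing tests demonstrate correct estimator behavior under the model's own
assumptions, not robustness to lapses, motor noise or learning.

## Pairing

`first_min` assigns response 1 to the target minimizing the absolute
circular difference, response 2 to the remaining target; `global_min` lets
the smallest of the four target–response distances fix the first assignment.
Exact ties (measure-zero on continuous data) break deterministically toward
target *a* and the earlier response slot. Signed errors feed the mixture;
absolute errors feed the half-normal time-course fits.

## Constrained von Mises mixture

EM on radian-scaled errors with both weights fixed at 0.5 and both means
clipped to ±10° after each M-step (box constraint). The M-step inverts
A(κ) = R̄ with the Best–Fisher starting approximation refined by four Newton
steps; κ is clamped to [1e−3, 1e4] (the upper cap triggers a degenerate-fit
warning). Initialization is a moment fit to the inner/outer halves of the
absolute-error distribution; `n_restarts` (default 10) jittered starts run
as one vectorized EM and the best final log-likelihood wins. Convergence:
log-likelihood change < 1e−6 nats, at most 500 iterations.

Precision is `sd = √(1/κ)` in radians converted to degrees. Whether the
original analyses applied √(1/κ) to degree- or radian-scaled data is
ambiguous; radians are used here because κ is defined for the radian-scaled
von Mises. Precision *ratios*, on which all cross-condition conclusions
rest, are invariant to this choice.

## Validation

- **Monte-Carlo null:** responses are re-simulated at the fitted SD pair on
  the subject's actual targets (dual-report trials re-pass through the
  pairing rule; this is configurable), refit 1000 times, and the cloud
  summarized by a 4-parameter Gaussian (two means, two axis SDs, no
  covariance). The observed pair's squared axis-standardized radius is
  referred to a 2-df chi-square; the empirical cloud tail is reported
  alongside. Calibration is verified by drawing observed pairs from the
  fitted Gaussian itself, which makes the p-value uniform by construction of
  the mapping.
- **Equal-deviation ratio null:** datasets with *no* true precision split
  (one common SD) are refit to quantify the upward bias of the fitted ratio.
  At 300 errors per dataset the median fitted ratio is ≈ 1.15–1.19 across
  common SDs of 10–25°, and ratios above 1.928 occur in < 1% of simulations;
  the bias shrinks toward 1 as the sample grows. When per-subject SDs are
  unavailable a representative 15° is used, with a 10–25° sweep reported.
- **Permutation consistency:** the summed per-subject Euclidean distance
  between precision pairs in two conditions, against 10,000 random
  re-assignments of subjects, add-one rule (the identity permutation counts),
  so p can never be exactly 0.
- **Regression through the origin:** a = Σxy/Σx², F on (1, n−1) df.

## Time-course and spectral analysis

Per subject, condition (cue-absent; cued stream and uncued stream of
cue-present trials) and SOA, precision is the half-normal MLE scale
√(mean(x²)) of absolute errors — no mixture, because the cue identifies the
streams. The design provides 36 trials per cued/uncued-stream cell and 72
per cue-absent cell at each of six SOAs (3.0–4.0 s in 200 ms steps,
3.0–3.5 s in 100 ms steps, or 3.00–3.20 s in 40 ms steps after hue onset).
Each subject's 18 cells are z-scored against their own mean and SD.

The cued and uncued time-courses (6 points) are mean-removed, zero-padded to
16 samples and discrete-Fourier-transformed, so bin k lies at k/(16·dt) Hz —
for dt = 0.2/0.1/0.04 s the bins include 0.9375 & 1.25 / 3.75 / 4.6875 Hz.
Mean removal prevents DC leakage into the lowest bins of so short a padded
series. Per-subject phase differences (cued − uncued, wrapped to (−180°,
180°]) give an across-subject phase-locking value per bin; the peak-PLV bin
is selected within the resolvable band — one cycle per observation window,
1/(6·dt), up to the Nyquist frequency 1/(2·dt), excluding the exact Nyquist
bin, whose phase for a real signal is degenerately 0/180° and whose PLV is
therefore trivially inflated. At the peak bin, v-tests (modified Rayleigh;
V = n·R̄·cos(m − θ₀), u = V·√(2/n), one-sided normal upper tail) test for
concentration at 0° (in-phase) and 180° (antiphase). Whether to Fourier-
transform raw or z-normalized series was an open choice; z-normalized is the
default since normalization precedes the spectral step in the analysis
chain.

## Problem sizes and determinism

The test suite and the analysis drivers run the estimators at the study's
own scale where that is what is being checked (300 errors per mixture fit,
1000-fit ratio nulls, 15-subject cohorts of 864 trials, 10,000-permutation
tests) and at reduced replication counts for auxiliary sweeps (250–300
simulations per sweep point, 200 recovery seeds). Every stochastic stage
draws from a generator derived from one top-level seed salted with the stage
name, so any stage can be reproduced in isolation; identical seeds give
bitwise-identical outputs.

## Known limitations

- The observer's alternation is deterministic and common to all subjects;
  real rhythmic sampling would add phase and frequency jitter, lowering PLV.
- The mixture has no guess/swap components, so gross lapses would inflate
  both fitted SDs rather than being absorbed.
- Reported stimulus reversal statistics depend on `reversal_prob`, which the
  source description leaves underdetermined (see the caveat above).
- Group-level statistics that depend on real between-subject variability
  (correlations, slopes of actual cohorts) are demonstrated on synthetic
  cohorts only.
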