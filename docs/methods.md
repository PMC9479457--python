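# Methods

This note documents the models, parameter choices, and limitations behind
`streamseg`. The package simulates a rhythm-based delay-detection paradigm
for studying voluntary auditory stream segregation in normal-hearing (NH)
and cochlear-implant (CI) listeners, together with the analysis that turns
yes/no responses into sensitivity (d′) estimates.

## Stimulus timing

A trial is a sequence of `n_pairs` ∈ {3, 9} A–B burst pairs. All times are
in milliseconds from the first A onset; every burst lasts 80 ms.

- B onsets: 130 + 260·k for pair k (B–B onset interval 260 ms, i.e. a
  stimulus rate of 1/0.260 ≈ 3.8 AB pairs/s).
- A onsets: nominally 260·k. The first A is unjittered; every subsequent A
  draws an independent uniform jitter on [−40, +40] ms, so the
  offset-to-onset gap between a jittered A and either adjacent B (at its
  grid position) spans [10, 90] ms. The source description gives only a
  jitter magnitude range (0–40 ms); we draw magnitude and sign
  independently, which is equivalent to the symmetric uniform draw and
  makes each adjacent gap individually cover the quoted 10–90 ms range.
- Final B shift: +35 ms on *delayed* trials; −u, u ~ U[0, 10] ms, on
  *no-delay* trials. Gap invariants are checked against the final B's
  nominal grid position because the shift *is* the signal under detection,
  not part of the jitter rule.

These rules make the 9-pair delayed sequence exactly 2.325 s and 9-pair
no-delay sequences 2.28–2.29 s. For 3-pair sequences the same rules give
0.765 s (delayed) and 0.72–0.73 s (no-delay); the 0.665/0.62–0.63 s
sometimes quoted for 3-pair sequences is inconsistent with the stated
rules (it is 100 ms short, exactly one swapped digit), so the rules win.

## Synthesis

Bursts are Gaussian noise passed through a 10-pole Butterworth band-pass
(second-order sections, causal — zero-phase filtering would be unphysical
for a real-time stimulus), with bandwidth 162 Hz for bands below 5 kHz and
216 Hz for the high (large-separation) bands. Amplitude modulation, when
present, multiplies the filtered noise by 1 + sin(2πf·t) (100% depth) —
i.e. AM is applied after filtering, so the ±f sidebands extend beyond the
noise band; the opposite order is a one-line change and alters the
electrodogram slightly. Each burst gets 8-ms raised-cosine (cos²)
onset/offset ramps and is scaled to its nominal level under a fixed
digital calibration: 60 dB SPL ↦ RMS 0.05 full scale. Relative levels are
therefore exact while absolute SPL is a property of playback hardware and
out of scope. A level of 0 is the silence convention. Sequences are
rendered at 44.1 kHz with fresh noise per burst and silence elsewhere.

WAV I/O uses mono float32 RIFF files (round-trip error < 2⁻²² full scale);
writing refuses to clip.

## ACE electrodogram simulation

The simulation maps a waveform to pulse events (electrode 1 = most basal,
22 = most apical) under the ACE n-of-m strategy: default 22-channel
frequency allocation spanning 188–7,938 Hz built from 62 contiguous 125-Hz
FFT bins (bins per channel, apical→basal: 1×9, 2×4, 3×2, 4×2, 5×2, 6, 7,
8), 900 frames/s, eight maxima. This table's geometric band centers
reproduce the clinical-map center frequencies of the most common user map
(1683 Hz ↦ electrode 12, 2871 ↦ 8, 6485 ↦ 2) to within a few Hz, which is
how the table edition was validated; other users' clinical maps differ and
are carried in their profiles.

Per frame, channel envelopes are the root of summed Blackman-windowed
128-point FFT bin powers (16-kHz analysis rate), smoothed over 3 frames.
Two deliberate modeling choices sit on top:

1. **Spread of excitation.** A narrowband burst in practice activates 4–5
   neighboring electrodes, more toward the base than the apex — a spread
   that FFT-window leakage alone badly under-predicts (and symmetric
   leakage cannot produce). Each strongly driven channel therefore
   radiates an excitation-spread kernel in log-frequency: 68 dB/octave
   toward higher-CF (basal) channels and 98 dB/octave toward lower-CF
   (apical) ones, combined by maximum with the direct envelopes. The
   slopes are constrained to a few-dB window by requiring the simulation
   to reproduce the reported activation sets of the three reference bursts
   (B at 1683 Hz → electrodes {9–13}; A at 2871 → {6–10}; A at 6485 →
   {1–4}); the chosen values sit mid-window and are of the order of
   published spread-of-excitation slopes. Only channels whose
   burst-averaged envelope is within 4 dB of the maximum act as spread
   sources; this keeps stochastic adjacent-bin leakage (which fluctuates
   ±10 dB frame to frame in narrowband noise) from re-radiating through
   the kernel.
2. **Activation floor.** A selected channel emits a pulse only if its
   effective envelope is within 40 dB of the stimulus peak (and of the
   frame peak); without a floor, n-of-m selection marks noise-floor
   channels "active" during every frame.

All of these (slopes, floor, source gate, smoothing, maxima, allocation)
are fields of `ACEConfig`. With the defaults, the three reference bursts
reproduce their activation sets in 200/200 random noise realizations, the
sets are contiguous with ≤ 5 members, always contain the assigned
electrode, and the A–B electrode-set distance is non-decreasing in
spectral separation. Current-level mapping (T/C levels), pulse
interleaving, and neural spread are out of scope — pulse magnitudes are
envelope units.

## Session engine

A block is 65 yes/no trials (50% delayed), of which the first 5 are
familiarization and excluded from scoring; feedback (the correct answer)
is delivered to the observer after each response. A session is: optional
loudness balancing, training to criterion, then the 18 conditions in
pseudorandom order — duration × spectral cells shuffled first, AM levels
shuffled within each cell, and the two repetitions of every condition in
consecutive blocks (36 blocks total).

Every trial draws a fresh 31-bit seed from the session stream and runs on
its own generator; the seed is logged in the trial record so any trial's
stimulus can be regenerated bit-exactly. Re-running a session with the
same master seed reproduces the entire log.

**Training gate.** Training blocks are 40 trials, cycling through all 18
conditions in canonical grid order; the gate passes as soon as any
large-separation/AM0-0 block reaches d′ ≥ 1.5 (inclusive), with a cap of
20 blocks. Under this schedule two gate-eligible blocks fall inside the
cap, which gives the gate its intended operating characteristics: a d′ = 2
observer passes within the cap with probability ≈ 0.99 and a d′ = 0.5
observer escapes with probability ≈ 0.035.

**Loudness balancing.** The cited adaptive procedure is not specified in
detail, so the package implements a standard interleaved transformed
staircase on the A level against the 60-dB B reference: a 1-up/2-down
track from +10 dB (converging at the 70.7% "A louder" point) and a
2-up/1-down track from −10 dB (29.3%), 4-dB steps halved to 2 dB after two
reversals, ten reversals per track, PSE = mean of the last six reversal
levels per track averaged across tracks. For a symmetric psychometric
function the two convergence points bracket the point of subjective
equality; an unbiased simulated judge recovers 60 ± 1 dB and a +6 dB
loudness bias shifts the matched level to ≈ 54 dB. All staircase constants
are keyword arguments.

## Simulated observers

The task's perceptual mechanism (rhythm tracking vs final-gap
discrimination) is not settled, so two observer families are provided.

**Statistical (SDT) observer.** Implements the equal-variance Gaussian
model exactly: P(respond delayed | delayed) = Φ(d′/2 − c), P(respond
delayed | no-delay) = Φ(−d′/2 − c). Its generating d′ per condition comes
either from an explicit 18-entry table or from a linear rule in spectral
octaves, AM-rate octaves, duration, and group. `demo_params()` ships an
illustrative table mimicking the qualitative pattern of interest — graded
spectral effect for NH, large-separation-only effect for CI, a penalty for
the largest AM separation, 9-pair > 3-pair — and is explicitly *not* a fit
to any behavioral data. Feedback is ignored (stationary behavior); no
learning is modeled.

**Envelope observer.** A mechanistic listener that receives only the
waveform and the B band's center frequency. Front end: 2-pole Butterworth
band-pass one octave wide around the B center (deliberately broader and
shallower than the stimulus band), full-wave rectification, 4-pole 150-Hz
low-pass. Onsets are rising crossings of 0.5 × the trace peak with
hysteresis (re-arm below half-threshold) and a 100-ms refractory period
that ignores intra-burst envelope dips (including the zeros of 100%-depth
AM). The decision statistic is the final inter-onset interval plus
Gaussian internal noise (σ = 10 ms), judged against a 277.5-ms criterion —
midway between the nominal 260-ms and delayed 295-ms intervals.

The defaults are chosen so the distractor's filtered residual is graded
across the spectral separations: at no separation the A bursts fall inside
the filter and rhythm tracking collapses to near chance; at the moderate
separation (0.75 oct) the residual (~0.57 of the B peak) is
borderline-detectable and accuracy is intermediate; at the large
separation (1.89 oct) the residual (~0.19) is sub-threshold and accuracy
is high. This ordering — the mechanistic analogue of the
spectral-separation effect — is verified at 2,000 trials per condition.
Because burst envelope peaks of narrowband noise fluctuate, the detector
occasionally misses a weak burst even with vanishing internal noise, so
accuracy saturates near (not at) 1 in the σ → 0 limit.

## d′ analysis

Sensitivity is d′ = Φ⁻¹(h) − Φ⁻¹(f) on the last 60 trials of each block.
Extreme rates are corrected before the transform; two rules are
implemented:

- `"2n"` (default): 0 → 1/(2N), 1 → 1 − 1/(2N). Standard descriptive
  choice; its block-level estimator overestimates slightly (exact bias,
  by binomial enumeration at 60 trials: +0.03 at d′ = 1, +0.09 at d′ = 2,
  +0.13 at d′ = 2.5).
- `"loglinear"`: (count + 0.5)/(N + 1) applied to every rate. Near
  unbiased (|bias| ≤ 0.06 up to d′ = 3 at 60 trials); used for the
  parameter-recovery checks, where the question is precisely whether the
  pipeline returns the generating d′.

A session summary is the 36-row table of per-block counts, corrected
rates, and d′; the build-up contrast is mean d′(9-pair) − mean d′(3-pair),
overall and per spectral separation. Group-level inferential statistics
(mixed-effects models, post-hoc corrections, power analysis) are
deliberately not reimplemented: they are off-the-shelf procedures that
belong to the analysis of human data.

## What the simulations do and do not show

The synthetic observers carry the statistical structure the analysis
assumes — sensitivity varying with spectral separation, AM separation,
duration, and group — so green tests demonstrate that the paradigm
generator, session engine, and scoring recover known ground truth
(parameter recovery, gate operating characteristics, monotone orderings).
They say nothing about human listeners: no attention, learning, loudness
growth, audiogram, or bilateral hearing is modeled, the envelope observer
is one plausible mechanism among several, and the demonstration d′ tables
are illustrative. Simulation sizes in the shipped tests (1,000 blocks per
recovery point, 2,000 trials per ordering condition, 10,000 timing draws)
were chosen to make the Monte-Carlo error small relative to each check's
tolerance.
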