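"""Simulated listeners for the delay-detection task.

Two observer families are provided, because the perceptual mechanism behind
the task is not settled (rhythm tracking of the B stream vs discrimination
of the final A-B gap):

* :class:`SDTObserver` — a statistical listener implementing the
  equal-variance Gaussian model that underlies the d' analysis.  Its
  generating sensitivity per condition is either an explicit table or a
  linear rule in spectral separation (octaves), AM-rate separation
  (octaves), sequence duration, and listener group.  Useful for parameter
  recovery: the analysis pipeline should estimate back the d' this observer
  was given.

* :class:`EnvelopeObserver` — a mechanistic listener that hears only the
  rendered waveform.  It band-passes around the B band, extracts the
  envelope, detects burst onsets by threshold crossing, and judges the final
  inter-onset interval against a criterion, with internal Gaussian timing
  noise.  When the A band overlaps its filter, A bursts corrupt onset
  detection and accuracy falls — the mechanistic analogue of the
  spectral-separation effect.

Both observers ignore trial feedback (stationary behavior).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log2

import numpy as np
from scipy import signal
from scipy.stats import norm

from .paradigm import AM_RATES, Condition, ListenerProfile, octave_separation

DELAYED = "delayed"
NO_DELAY = "no_delay"


class Observer:
    """Base interface the session engine drives."""

    #: whether the engine must render audio for this observer
    needs_audio: bool = False

    def respond(self, trial, rng: np.random.Generator) -> str:
        raise NotImplementedError

    def feedback(self, correct_answer: str) -> None:  # noqa: B027 - optional hook
        pass


def am_octave_separation(am_sep: str) -> float:
    """Octave separation of the A and B modulation rates (0 if unmodulated)."""
    ra, rb = AM_RATES[am_sep]
    if ra == 0 or rb == 0:
        return 0.0
    return abs(log2(ra / rb))


@dataclass
class SDTObserverParams:
    """Latent sensitivity of an equal-variance Gaussian observer.

    If ``dprime_map`` is given it overrides the linear rule.  The rule is
    d' = max(0, beta0 + betaF * spectral_octaves + betaA * am_octaves
                 + betaD * 1[9-pair] + betaG * 1[NH]).
    """

    dprime_map: dict[str, float] | None = None
    beta0: float = 0.3
    beta_spectral: float = 0.8
    beta_am: float = -0.1
    beta_duration: float = 0.45
    beta_group: float = 0.2
    criterion: float = 0.0

    def generating_dprime(self, condition: Condition, profile: ListenerProfile) -> float:
        if self.dprime_map is not None:
            try:
                return self.dprime_map[condition.label()]
            except KeyError:
                raise KeyError(
                    f"dprime_map has no entry for condition {condition.label()!r}"
                ) from None
        row = profile.band_table[condition.spectral_sep]
        spectral_oct = octave_separation(float(row["a_cf"]), float(row["b_cf"]))
        d = (
            self.beta0
            + self.beta_spectral * spectral_oct
            + self.beta_am * am_octave_separation(condition.am_sep)
            + self.beta_duration * (condition.n_pairs == 9)
            + self.beta_group * (profile.group == "NH")
        )
        if not np.isfinite(d):
            raise ValueError("generating d' is not finite")
        return max(0.0, d)

    @classmethod
    def constant(cls, dprime: float, criterion: float = 0.0) -> "SDTObserverParams":
        """An observer with the same generating d' in every condition."""
        from .paradigm import build_condition_grid

        table = {c.label(): float(dprime) for c in build_condition_grid()}
        return cls(dprime_map=table, criterion=criterion)


def sdt_respond(
    trial_type: str,
    dprime: float,
    rng: np.random.Generator,
    criterion: float = 0.0,
) -> str:
    """One yes/no response from the equal-variance Gaussian model.

    P(respond delayed | delayed)  = Phi(d'/2 - c)
    P(respond delayed | no-delay) = Phi(-d'/2 - c)
    """
    if dprime < 0:
        raise ValueError("generating d' must be >= 0")
    mean = dprime / 2.0 if trial_type == DELAYED else -dprime / 2.0
    p_delayed = norm.cdf(mean - criterion)
    return DELAYED if rng.random() < p_delayed else NO_DELAY


class SDTObserver(Observer):
    needs_audio = False

    def __init__(self, params: SDTObserverParams | None = None,
                 profile: ListenerProfile | None = None):
        self.params = params or SDTObserverParams()
        self.profile = profile

    def respond(self, trial, rng: np.random.Generator) -> str:
        profile = self.profile or trial.profile
        d = self.params.generating_dprime(trial.condition, profile)
        return sdt_respond(trial.trial_type, d, rng, self.params.criterion)


@dataclass
class EnvelopeObserverParams:
    """Mechanistic listener parameters.

    ``sigma_ms`` is internal timing noise added to the estimated final
    interval; ``criterion_ms`` is the decision bound on that interval
    (the nominal B-B interval is 260 ms, a delayed final interval 295 ms).
    The front-end band-pass is 2 * ``filter_halfwidth_oct`` octaves wide
    around the B center frequency with ``filter_poles`` Butterworth poles —
    deliberately broader and shallower than the stimulus band so that
    distractor leakage is graded across spectral separations.
    """

    sigma_ms: float = 10.0
    lowpass_hz: float = 150.0
    lowpass_poles: int = 4
    onset_threshold: float = 0.5
    min_interval_ms: float = 100.0  # refractory: ignores intra-burst envelope dips
    criterion_ms: float = 277.5
    filter_halfwidth_oct: float = 0.5
    filter_poles: int = 2

    def __post_init__(self) -> None:
        if self.sigma_ms <= 0:
            raise ValueError("sigma_ms must be positive")
        if not (260.0 <= self.criterion_ms <= 295.0):
            raise ValueError("criterion_ms must lie between 260 and 295 ms")


def detect_onsets(
    samples: np.ndarray,
    sample_rate: int,
    b_center_freq: float,
    params: EnvelopeObserverParams,
) -> np.ndarray:
    """Burst-onset times (ms) from the B-band envelope.

    Full-wave rectification + low-pass, then rising threshold crossings with
    hysteresis (the envelope must fall below half the threshold before a new
    onset can register).
    """
    lo = b_center_freq * 2.0 ** (-params.filter_halfwidth_oct)
    hi = b_center_freq * 2.0 ** (+params.filter_halfwidth_oct)
    hi = min(hi, 0.45 * sample_rate)
    sos_bp = signal.butter(max(params.filter_poles // 2, 1), [lo, hi],
                           btype="bandpass", fs=sample_rate, output="sos")
    band = signal.sosfilt(sos_bp, samples)
    sos_lp = signal.butter(params.lowpass_poles // 2, params.lowpass_hz,
                           btype="low", fs=sample_rate, output="sos")
    env = signal.sosfilt(sos_lp, np.abs(band))
    peak = env.max()
    if peak <= 0:
        return np.array([])
    thr = params.onset_threshold * peak
    refractory = int(params.min_interval_ms / 1000.0 * sample_rate)
    above = env >= thr
    below_reset = env < 0.5 * thr
    armed = True
    last = -refractory
    onsets = []
    for i in range(len(env)):
        if armed and above[i] and i - last >= refractory:
            onsets.append(i)
            last = i
            armed = False
        elif not armed and below_reset[i]:
            armed = True
    return np.asarray(onsets, dtype=float) / sample_rate * 1000.0


def envelope_respond(
    samples: np.ndarray,
    sample_rate: int,
    b_center_freq: float,
    params: EnvelopeObserverParams,
    rng: np.random.Generator,
) -> str:
    """Respond from the waveform alone (no timing metadata)."""
    onsets = detect_onsets(samples, sample_rate, b_center_freq, params)
    if len(onsets) < 2:
        return DELAYED if rng.random() < 0.5 else NO_DELAY
    interval = onsets[-1] - onsets[-2] + rng.normal(0.0, params.sigma_ms)
    return DELAYED if interval > params.criterion_ms else NO_DELAY


class EnvelopeObserver(Observer):
    needs_audio = True

    def __init__(self, params: EnvelopeObserverParams | None = None):
        self.params = params or EnvelopeObserverParams()

    def respond(self, trial, rng: np.random.Generator) -> str:
        w = trial.waveform
        if w is None:
            raise ValueError("EnvelopeObserver needs a rendered waveform")
        return envelope_respond(
            w.samples, w.sample_rate, float(trial.b_spec.center_freq),
            self.params, rng,
        )


class GuessingObserver(Observer):
    """Responds at random; d' should estimate to ~0."""

    def respond(self, trial, rng: np.random.Generator) -> str:
        return DELAYED if rng.random() < 0.5 else NO_DELAY


class OracleObserver(Observer):
    """Always correct; useful as an engine check."""

    def respond(self, trial, rng: np.random.Generator) -> str:
        return trial.trial_type


@dataclass
class SimulatedLoudnessJudge:
    """Loudness-comparison judgments for the balancing procedure.

    ``bias_db`` may be a constant or a callable of frequency: a +6 dB bias
    at the A frequency means A sounds 6 dB louder than its physical level,
    so the point of subjective equality sits near 54 dB.
    """

    bias_db: float | object = 0.0
    sigma_db: float = 1.0

    def _bias(self, freq: float) -> float:
        return float(self.bias_db(freq)) if callable(self.bias_db) else float(self.bias_db)

    def is_louder(self, a_level: float, a_freq: float, b_level: float,
                  rng: np.random.Generator) -> bool:
        perceived = a_level + self._bias(a_freq) + rng.normal(0.0, self.sigma_db)
        return perceived > b_level


def demo_params(group: str) -> SDTObserverParams:
    """Illustrative generating-d' tables mimicking the qualitative pattern
    of interest: a graded spectral-separation effect for NH, a large-
    separation-only effect for CI, a penalty for the largest AM separation,
    and higher sensitivity for 9-pair than 3-pair sequences.

    These are demonstration values, not fits to any behavioral data.
    """
    if group not in ("NH", "CI"):
        raise ValueError("group must be 'NH' or 'CI'")
    spectral_gain = (
        {"none": 0.0, "moderate": 0.7, "large": 1.6}
        if group == "NH"
        else {"none": 0.0, "moderate": 0.1, "large": 1.5}
    )
    am_penalty = {"AM0-0": 0.0, "AM200-50": -0.1, "AM300-50": -0.25}
    table: dict[str, float] = {}
    from .paradigm import build_condition_grid

    for c in build_condition_grid():
        d = 0.35 + spectral_gain[c.spectral_sep] + am_penalty[c.am_sep]
        d += 0.45 if c.n_pairs == 9 else 0.0
        table[c.label()] = max(0.0, d)
    return SDTObserverParams(dprime_map=table)
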