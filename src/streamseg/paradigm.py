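"""Stimulus paradigm: conditions, listener profiles, and burst timing.

The paradigm presents sequences of A and B narrowband-noise bursts in the
pattern ABAB..., where the B bursts form a temporally regular (isochronous)
target stream and the A bursts an irregular distractor stream.  On *delayed*
trials the final B burst is displaced 35 ms late from its regular grid
position; on *no-delay* trials it is advanced by 0-10 ms.  A listener who can
perceptually segregate the B stream from the A stream can track the B rhythm
and detect the delay; the harder the streams are to segregate, the worse the
detection.

Timing rules (all in milliseconds, measured from the first A onset):

* every burst lasts 80 ms (including 8-ms ramps, handled in synthesis);
* B onsets fall on the grid 130 + 260*k for pair k = 0 .. n_pairs-1;
* nominal A onsets fall on 260*k; the first A is never jittered, every
  other A carries an independent uniform jitter in [-40, +40] ms, so each
  offset-to-onset gap between an A burst and either adjacent (grid-position)
  B burst lies in [10, 90] ms;
* the final B is shifted by +35 ms (delayed trials) or by -u, u ~ U[0, 10]
  (no-delay trials), relative to its grid position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import yaml

BURST_MS = 80.0
FIRST_AB_ONSET_ASYNC_MS = 130.0
BB_ONSET_MS = 260.0
DELAY_MS = 35.0
MAX_ADVANCE_MS = 10.0
MAX_JITTER_MS = 40.0

SPECTRAL_LEVELS = ("none", "moderate", "large")
AM_LEVELS = ("AM0-0", "AM200-50", "AM300-50")
N_PAIRS_LEVELS = (3, 9)

#: A/B modulator rates (Hz) for each AM-separation level.
AM_RATES = {"AM0-0": (0.0, 0.0), "AM200-50": (200.0, 50.0), "AM300-50": (300.0, 50.0)}


class ConfigurationError(ValueError):
    """Raised for unknown condition levels or malformed profiles."""


@dataclass(frozen=True)
class BandSpec:
    """Acoustic definition of one narrowband-noise burst type.

    ``level`` is in dB SPL under the package's fixed digital calibration
    (see :mod:`streamseg.synthesis`); a level of 0 denotes silence.
    """

    center_freq: float
    bandwidth: float
    am_rate: float = 0.0
    level: float = 60.0

    def __post_init__(self) -> None:
        if self.center_freq <= 0:
            raise ValueError(f"center_freq must be positive, got {self.center_freq}")
        if not (0 < self.bandwidth < self.center_freq):
            raise ValueError(
                f"bandwidth must be in (0, center_freq), got {self.bandwidth}"
            )
        if self.am_rate < 0:
            raise ValueError(f"am_rate must be >= 0, got {self.am_rate}")


@dataclass(frozen=True)
class Condition:
    n_pairs: int
    spectral_sep: str
    am_sep: str

    def __post_init__(self) -> None:
        if self.n_pairs not in N_PAIRS_LEVELS:
            raise ConfigurationError(f"n_pairs must be one of {N_PAIRS_LEVELS}")
        if self.spectral_sep not in SPECTRAL_LEVELS:
            raise ConfigurationError(f"unknown spectral separation {self.spectral_sep!r}")
        if self.am_sep not in AM_LEVELS:
            raise ConfigurationError(f"unknown AM separation {self.am_sep!r}")

    def label(self) -> str:
        return f"{self.n_pairs}p_{self.spectral_sep}_{self.am_sep}"


@dataclass(frozen=True)
class BurstEvent:
    stream: str  # "A" or "B"
    onset: float  # ms from first A onset
    duration: float = BURST_MS

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class SequenceTiming:
    """Schedule of burst events for one trial."""

    events: tuple[BurstEvent, ...]
    trial_type: str  # "delayed" | "no_delay"
    jitters: tuple[float, ...]  # per-A-burst signed offsets, first is 0
    final_shift: float  # +35 delayed; -u, u in [0,10] no-delay

    @property
    def n_pairs(self) -> int:
        return len(self.events) // 2


@dataclass(frozen=True)
class ListenerProfile:
    """One listener's A/B band assignment at each spectral-separation level.

    ``band_table`` maps a spectral level to a dict with keys ``a_cf``,
    ``b_cf`` and, for CI users, ``a_electrode``/``b_electrode`` (the clinical
    MAP channels the bands were matched to).
    """

    group: str  # "NH" | "CI"
    id: str
    band_table: dict[str, dict[str, float | int]]
    brand: str | None = None

    def __post_init__(self) -> None:
        if self.group not in ("NH", "CI"):
            raise ConfigurationError(f"group must be NH or CI, got {self.group!r}")
        missing = set(SPECTRAL_LEVELS) - set(self.band_table)
        if missing:
            raise ConfigurationError(f"profile {self.id}: missing levels {missing}")


def _profile_data() -> dict:
    text = resources.files("streamseg.data").joinpath("listener_profiles.yaml").read_text()
    return yaml.safe_load(text)


def load_profiles() -> dict[str, ListenerProfile]:
    """Load the packaged listener profiles (one generic NH, six CI users)."""
    raw = _profile_data()
    out: dict[str, ListenerProfile] = {}
    for pid, entry in raw.items():
        out[pid] = ListenerProfile(
            group=entry["group"],
            id=pid,
            band_table=entry["bands"],
            brand=entry.get("brand"),
        )
    return out


def get_profile(name: str) -> ListenerProfile:
    profiles = load_profiles()
    try:
        return profiles[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown profile {name!r}; available: {sorted(profiles)}"
        ) from None


def build_condition_grid() -> list[Condition]:
    """The 18 conditions: 2 durations x 3 spectral x 3 AM separations.

    Canonical order is lexicographic in (n_pairs, spectral level, AM level)
    with levels in their natural (increasing-separation) order.
    """
    return [
        Condition(n, s, a)
        for n in N_PAIRS_LEVELS
        for s in SPECTRAL_LEVELS
        for a in AM_LEVELS
    ]


def _bandwidth_for(center_freq: float) -> float:
    # 162 Hz for the bands below ~5 kHz, 216 Hz for the high (large-sep) bands
    return 216.0 if center_freq >= 5000.0 else 162.0


def band_specs_for(
    profile: ListenerProfile,
    spectral_sep: str,
    am_sep: str,
    a_level: float = 60.0,
    b_level: float = 60.0,
) -> tuple[BandSpec, BandSpec]:
    """A and B burst definitions for one listener and condition.

    The B level is fixed at 60 dB SPL; the A level defaults to 60 and is
    overridden by the loudness-balancing result in a full session.
    """
    try:
        row = profile.band_table[spectral_sep]
    except KeyError:
        raise ConfigurationError(
            f"profile {profile.id} has no level {spectral_sep!r}"
        ) from None
    try:
        am_a, am_b = AM_RATES[am_sep]
    except KeyError:
        raise ConfigurationError(f"unknown AM separation {am_sep!r}") from None
    a_cf, b_cf = float(row["a_cf"]), float(row["b_cf"])
    a = BandSpec(a_cf, _bandwidth_for(a_cf), am_a, a_level)
    b = BandSpec(b_cf, _bandwidth_for(b_cf), am_b, b_level)
    return a, b


def make_sequence_timing(
    condition: Condition, trial_type: str, rng: np.random.Generator
) -> SequenceTiming:
    """Draw one trial's burst schedule.

    Jitters are drawn independently per A burst, uniform on [-40, +40] ms
    (equivalently: magnitude U[0, 40] with a random sign).  The final B shift
    is +35 ms on delayed trials and -U[0, 10] ms on no-delay trials.
    """
    if trial_type not in ("delayed", "no_delay"):
        raise ValueError(f"trial_type must be 'delayed' or 'no_delay', got {trial_type!r}")
    n = condition.n_pairs
    jitters = [0.0] + [float(rng.uniform(-MAX_JITTER_MS, MAX_JITTER_MS)) for _ in range(n - 1)]
    if trial_type == "delayed":
        final_shift = DELAY_MS
    else:
        final_shift = -float(rng.uniform(0.0, MAX_ADVANCE_MS))
    events: list[BurstEvent] = []
    for k in range(n):
        events.append(BurstEvent("A", BB_ONSET_MS * k + jitters[k]))
        b_onset = FIRST_AB_ONSET_ASYNC_MS + BB_ONSET_MS * k
        if k == n - 1:
            b_onset += final_shift
        events.append(BurstEvent("B", b_onset))
    return SequenceTiming(tuple(events), trial_type, tuple(jitters), final_shift)


def sequence_duration(timing: SequenceTiming) -> float:
    """Sequence duration in seconds: last burst offset / 1000."""
    if not timing.events:
        raise ValueError("empty event list")
    return max(ev.offset for ev in timing.events) / 1000.0


def offset_onset_gaps(timing: SequenceTiming) -> list[float]:
    """Offset-to-onset gaps between each A burst and its adjacent B bursts.

    Gaps involving the final B are computed against its *nominal* (unshifted)
    grid position: the +-shift of the final B is the signal under detection,
    not part of the jitter rule the gaps bound.
    """
    n = timing.n_pairs
    gaps: list[float] = []
    for k in range(n):
        a = timing.events[2 * k]
        b_nominal_onset = FIRST_AB_ONSET_ASYNC_MS + BB_ONSET_MS * k
        # gap from A offset to following (grid) B onset
        gaps.append(b_nominal_onset - a.offset)
        if k > 0:
            prev_b_offset = FIRST_AB_ONSET_ASYNC_MS + BB_ONSET_MS * (k - 1) + BURST_MS
            gaps.append(a.onset - prev_b_offset)
    return gaps


def octave_separation(f1: float, f2: float) -> float:
    """|log2(f1/f2)|: the separation of two frequencies in octaves."""
    if f1 <= 0 or f2 <= 0:
        raise ValueError(f"frequencies must be positive, got {f1}, {f2}")
    return abs(math.log2(f1 / f2))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, the convention used when quoting octave values."""
    factor = 10.0 ** ndigits
    return math.floor(x * factor + 0.5) / factor


def pseudorandom_condition_order(rng: np.random.Generator) -> list[Condition]:
    """Block order for a session: 36 slots (18 conditions x 2 repetitions).

    The six duration x spectral-separation cells are randomized first; the
    three AM levels are randomized nested within each cell; the two
    repetitions of every condition occupy consecutive slots.
    """
    cells = [(n, s) for n in N_PAIRS_LEVELS for s in SPECTRAL_LEVELS]
    rng.shuffle(cells)
    order: list[Condition] = []
    for n, s in cells:
        ams = list(AM_LEVELS)
        rng.shuffle(ams)
        for a in ams:
            cond = Condition(n, s, a)
            order.extend([cond, cond])
    return order


def timing_to_rows(timing: SequenceTiming) -> list[dict]:
    """Rows for CSV export: stream, onset_ms, duration_ms, trial_type."""
    return [
        {
            "stream": ev.stream,
            "onset_ms": ev.onset,
            "duration_ms": ev.duration,
            "trial_type": timing.trial_type,
        }
        for ev in timing.events
    ]
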