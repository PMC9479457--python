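"""Yes/no session engine: blocks, training gate, loudness balancing.

A full session mirrors the behavioral protocol: loudness balancing of the A
level against the 60-dB-SPL B reference (moderate and large separations),
40-trial training blocks until the listener reaches d' >= 1.5 on a
large-separation / no-AM-separation block (capped), then the 18 conditions
in pseudorandom order, two consecutive 65-trial blocks each, with signal
(delayed) trials at probability 0.5 and feedback after every response.

Reproducibility: every trial draws a fresh integer seed from the session
stream and runs on its own generator; the seed is logged in the trial
record, so any trial's stimulus can be regenerated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis
from .observers import Observer
from .paradigm import (
    BandSpec,
    Condition,
    ListenerProfile,
    band_specs_for,
    build_condition_grid,
    make_sequence_timing,
    pseudorandom_condition_order,
)
from .synthesis import render_sequence

N_TRIALS_PER_BLOCK = 65
N_FAMILIARIZATION = 5
N_TRAINING_TRIALS = 40
TRAINING_DPRIME_GATE = 1.5
TRAINING_BLOCK_CAP = 20
SIGNAL_PROBABILITY = 0.5


class SessionError(RuntimeError):
    pass


@dataclass
class TrialStimulus:
    """Everything an observer may inspect about one trial."""

    condition: Condition
    trial_type: str
    timing: object
    a_spec: BandSpec
    b_spec: BandSpec
    profile: ListenerProfile
    waveform: object | None = None


@dataclass(frozen=True)
class TrialRecord:
    condition: str
    block_index: int
    trial_index: int  # 1-based within block
    trial_type: str
    response: str
    correct: bool
    familiarization: bool
    seed: int


@dataclass
class BlockResult:
    trials: list[TrialRecord]
    condition: Condition
    repetition: int = 1  # 1 or 2 for experimental blocks

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class Session:
    profile_id: str
    master_seed: int
    a_levels: dict[str, float]
    training_blocks: list[BlockResult]
    blocks: list[BlockResult]
    training_passed: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for phase, blocks in (("training", self.training_blocks),
                              ("experimental", self.blocks)):
            for b in blocks:
                for t in b.trials:
                    rows.append({
                        "phase": phase,
                        "condition": t.condition,
                        "repetition": b.repetition,
                        "block_index": t.block_index,
                        "trial_index": t.trial_index,
                        "trial_type": t.trial_type,
                        "response": t.response,
                        "correct": t.correct,
                        "familiarization": t.familiarization,
                        "seed": t.seed,
                    })
        return pd.DataFrame(rows)


def run_block(
    condition: Condition,
    observer: Observer,
    profile: ListenerProfile,
    rng: np.random.Generator,
    n_trials: int = N_TRIALS_PER_BLOCK,
    block_index: int = 0,
    repetition: int = 1,
    a_level: float = 60.0,
    render_audio: bool | None = None,
) -> BlockResult:
    """Run one block of yes/no trials against an observer.

    Audio is rendered only when the observer listens to waveforms (or when
    forced via ``render_audio``).
    """
    if render_audio is None:
        render_audio = observer.needs_audio
    a_spec, b_spec = band_specs_for(
        profile, condition.spectral_sep, condition.am_sep, a_level=a_level
    )
    records: list[TrialRecord] = []
    for trial_index in range(1, n_trials + 1):
        trial_seed = int(rng.integers(0, 2**31))
        trial_rng = np.random.default_rng(trial_seed)
        trial_type = "delayed" if trial_rng.random() < SIGNAL_PROBABILITY else "no_delay"
        timing = make_sequence_timing(condition, trial_type, trial_rng)
        trial = TrialStimulus(condition, trial_type, timing, a_spec, b_spec, profile)
        if render_audio:
            trial.waveform = render_sequence(timing, (a_spec, b_spec), trial_rng)
        try:
            response = observer.respond(trial, trial_rng)
        except Exception as exc:  # surface the trial context
            raise SessionError(
                f"observer failed on block {block_index}, trial {trial_index} "
                f"({condition.label()}, {trial_type})"
            ) from exc
        if response not in ("delayed", "no_delay"):
            raise SessionError(f"invalid observer response {response!r}")
        observer.feedback(trial_type)
        records.append(TrialRecord(
            condition=condition.label(),
            block_index=block_index,
            trial_index=trial_index,
            trial_type=trial_type,
            response=response,
            correct=response == trial_type,
            familiarization=trial_index <= N_FAMILIARIZATION,
            seed=trial_seed,
        ))
    return BlockResult(records, condition, repetition)


def _is_gate_condition(condition: Condition) -> bool:
    return condition.spectral_sep == "large" and condition.am_sep == "AM0-0"


def training_gate(training_blocks: list[BlockResult],
                  threshold: float = TRAINING_DPRIME_GATE) -> bool:
    """Pass iff any large-separation / AM0-0 training block reaches d' >= 1.5."""
    for block in training_blocks:
        if not _is_gate_condition(block.condition):
            continue
        h, f, ns, nn = analysis.score_trials(block.trials)
        if ns == 0 or nn == 0:
            continue
        if analysis.dprime(h, f, ns, nn) >= threshold:
            return True
    return False


def run_training(
    observer: Observer,
    profile: ListenerProfile,
    rng: np.random.Generator,
    cap: int = TRAINING_BLOCK_CAP,
) -> tuple[list[BlockResult], bool]:
    """Training blocks cycling over all condition types until the gate passes.

    Blocks cycle through the 18 conditions in canonical grid order so the
    training reflects the task of every experimental condition; the gate is
    evaluated on the large-separation / AM0-0 blocks as they occur.
    """
    cycle = build_condition_grid()
    blocks: list[BlockResult] = []
    for i in range(cap):
        cond = cycle[i % len(cycle)]
        blocks.append(run_block(
            cond, observer, profile, rng,
            n_trials=N_TRAINING_TRIALS, block_index=-(i + 1),
        ))
        if training_gate(blocks):
            return blocks, True
    return blocks, False


def loudness_balance(
    judge,
    a_spec: BandSpec,
    rng: np.random.Generator,
    b_ref_level: float = 60.0,
    start_offset_db: float = 10.0,
    step_db: float = 4.0,
    small_step_db: float = 2.0,
    reversals_to_small_step: int = 2,
    reversals_per_track: int = 10,
    reversals_averaged: int = 6,
    max_trials_per_track: int = 400,
) -> float:
    """Adaptive interleaved-track estimate of the point of subjective equality.

    Two transformed staircases on the A level run interleaved: a 1-up/2-down
    track starting above the reference (converging where P("A louder") =
    0.707) and a 2-up/1-down track starting below (converging at 0.293).
    Steps are 4 dB, halved to 2 dB after two reversals; each track stops at
    ten reversals; the PSE is the mean of the last six reversal levels of
    each track, averaged across tracks — the two convergence points bracket
    the PSE symmetrically for a symmetric psychometric function.
    """
    track_means = []
    for rule in ("1up2down", "2up1down"):
        level = b_ref_level + (start_offset_db if rule == "1up2down" else -start_offset_db)
        step = step_db
        reversals: list[float] = []
        direction = 0
        consecutive = 0
        trials = 0
        while len(reversals) < reversals_per_track:
            trials += 1
            if trials > max_trials_per_track:
                raise SessionError(
                    f"loudness balancing did not converge within "
                    f"{max_trials_per_track} trials ({rule} track)"
                )
            louder = judge.is_louder(level, a_spec.center_freq, b_ref_level, rng)
            if rule == "1up2down":
                if louder:
                    consecutive += 1
                    move = -1 if consecutive >= 2 else 0
                else:
                    consecutive = 0
                    move = +1
            else:
                if louder:
                    consecutive = 0
                    move = -1
                else:
                    consecutive += 1
                    move = +1 if consecutive >= 2 else 0
            if move != 0:
                consecutive = 0
                if direction != 0 and move != direction:
                    reversals.append(level)
                    if len(reversals) == reversals_to_small_step:
                        step = small_step_db
                direction = move
                level += move * step
        track_means.append(float(np.mean(reversals[-reversals_averaged:])))
    return float(np.mean(track_means))


def run_session(
    profile: ListenerProfile,
    observer: Observer,
    master_seed: int,
    loudness_judge=None,
    training_cap: int = TRAINING_BLOCK_CAP,
    skip_training: bool = False,
) -> Session:
    """Run a complete simulated session.

    Returns a :class:`Session` whose 36 experimental blocks cover the 18
    conditions twice in pseudorandom order with adjacent repetitions.  If
    ``loudness_judge`` is None the A level stays at the 60-dB reference.
    """
    rng = np.random.default_rng(master_seed)
    a_levels = {"none": 60.0, "moderate": 60.0, "large": 60.0}
    if loudness_judge is not None:
        for level_name in ("moderate", "large"):
            a_spec, _ = band_specs_for(profile, level_name, "AM0-0")
            a_levels[level_name] = loudness_balance(loudness_judge, a_spec, rng)

    if skip_training:
        training_blocks, passed = [], True
    else:
        training_blocks, passed = run_training(observer, profile, rng, cap=training_cap)
    if not passed:
        return Session(profile.id, master_seed, a_levels, training_blocks, [], False)

    order = pseudorandom_condition_order(rng)
    seen: dict[str, int] = {}
    blocks: list[BlockResult] = []
    for i, cond in enumerate(order):
        rep = seen.get(cond.label(), 0) + 1
        seen[cond.label()] = rep
        blocks.append(run_block(
            cond, observer, profile, rng,
            block_index=i, repetition=rep,
            a_level=a_levels[cond.spectral_sep],
        ))
    return Session(profile.id, master_seed, a_levels, training_blocks, blocks, True)
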