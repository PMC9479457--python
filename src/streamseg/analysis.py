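"""Signal-detection scoring: hit/false-alarm rates, d', and build-up.

Sensitivity is the equal-variance Gaussian d' = Z(hit rate) - Z(false-alarm
rate).  Extreme rates (0 or 1), which make Z infinite, are corrected before
the transform; the default is the 1/(2N) rule (0 -> 1/(2N), 1 -> 1 -
1/(2N)), with the log-linear (+0.5 to every cell) correction available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .paradigm import N_PAIRS_LEVELS, SPECTRAL_LEVELS, build_condition_grid

CORRECTIONS = ("2n", "loglinear")


def score_trials(trials) -> tuple[int, int, int, int]:
    """(hits, false_alarms, n_signal, n_noise) over an iterable of records."""
    hits = fas = n_signal = n_noise = 0
    for t in trials:
        if t.trial_type == "delayed":
            n_signal += 1
            hits += t.response == "delayed"
        else:
            n_noise += 1
            fas += t.response == "delayed"
    return hits, fas, n_signal, n_noise


def score_block(block, n_trials: int = 65, n_familiarization: int = 5):
    """Score one experimental block, excluding the familiarization trials."""
    if len(block.trials) < n_trials:
        raise ValueError(
            f"block has {len(block.trials)} trials, expected {n_trials}"
        )
    scored = [t for t in block.trials if t.trial_index > n_familiarization]
    return score_trials(scored)


def corrected_rate(count: int, n: int, correction: str = "2n") -> float:
    if n <= 0:
        raise ValueError("cannot compute a rate from zero trials")
    if correction == "loglinear":
        return (count + 0.5) / (n + 1)
    if correction != "2n":
        raise ValueError(f"unknown correction {correction!r}; use one of {CORRECTIONS}")
    rate = count / n
    if rate == 0.0:
        return 1.0 / (2 * n)
    if rate == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def dprime(
    hits: int,
    false_alarms: int,
    n_signal: int,
    n_noise: int,
    correction: str = "2n",
) -> float:
    """d' = Z(hit rate) - Z(false-alarm rate), with extreme-rate correction."""
    if not (0 <= hits <= n_signal and 0 <= false_alarms <= n_noise):
        raise ValueError("counts exceed trial counts")
    h = corrected_rate(hits, n_signal, correction)
    f = corrected_rate(false_alarms, n_noise, correction)
    return float(norm.ppf(h) - norm.ppf(f))


def dprime_from_rates(hit_rate: float, fa_rate: float) -> float:
    """d' from already-corrected rates in (0, 1)."""
    if not (0 < hit_rate < 1 and 0 < fa_rate < 1):
        raise ValueError("rates must lie strictly inside (0, 1)")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def summarize_session(session, correction: str = "2n") -> pd.DataFrame:
    """The per-block d' table: 36 rows (18 conditions x 2 repetitions)."""
    expected = {(c.label(), r) for c in build_condition_grid() for r in (1, 2)}
    present = {(b.condition.label(), b.repetition) for b in session.blocks}
    missing = expected - present
    if missing:
        raise ValueError(f"session is missing blocks: {sorted(missing)}")
    rows = []
    for b in session.blocks:
        h, f, ns, nn = score_block(b)
        hr = corrected_rate(h, ns, correction)
        fr = corrected_rate(f, nn, correction)
        rows.append({
            "condition": b.condition.label(),
            "n_pairs": b.condition.n_pairs,
            "spectral_sep": b.condition.spectral_sep,
            "am_sep": b.condition.am_sep,
            "repetition": b.repetition,
            "n_signal": ns,
            "n_noise": nn,
            "hits": h,
            "false_alarms": f,
            "hit_rate": hr,
            "fa_rate": fr,
            "dprime": dprime(h, f, ns, nn, correction),
        })
    return pd.DataFrame(rows).sort_values(
        ["n_pairs", "spectral_sep", "am_sep", "repetition"]
    ).reset_index(drop=True)


def condition_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean d' of the two repetitions per condition."""
    return (
        table.groupby(["n_pairs", "spectral_sep", "am_sep"], sort=False)["dprime"]
        .mean()
        .reset_index()
    )


def buildup_effect(table: pd.DataFrame) -> dict:
    """Build-up contrast: mean d'(9-pair) - mean d'(3-pair).

    Returns the overall contrast and its breakdown per spectral separation
    (the duration-by-separation interaction pattern).
    """
    durations = set(table["n_pairs"].unique())
    missing = set(N_PAIRS_LEVELS) - durations
    if missing:
        raise ValueError(f"table lacks rows for n_pairs = {sorted(missing)}")
    mean_by = table.groupby("n_pairs")["dprime"].mean()
    overall = float(mean_by[9] - mean_by[3])
    by_spectral = {}
    for level in SPECTRAL_LEVELS:
        sub = table[table["spectral_sep"] == level]
        m = sub.groupby("n_pairs")["dprime"].mean()
        by_spectral[level] = float(m[9] - m[3])
    return {"overall": overall, "by_spectral": by_spectral}
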