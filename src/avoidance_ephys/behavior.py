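"""Behavioral endpoints of the avoidance task.

Per trial: percent time on the platform during the 30-s tone, the same
occupancy resolved into ten 3-s bins, avoidance latency (first platform
entry after tone onset, capped at 30 s for non-avoiders), percent freezing,
and conditioned suppression of bar pressing,

    suppression = (pretone rate − tone rate) / (pretone rate + tone rate),

with the pretone rate taken over the 60 s before tone onset.  Suppression
is reported unit-scaled in [−1, 1] (0 = no suppression, 1 = complete);
``percent=True`` reproduces the ×100 display scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import (ClassifierConfig, SessionEvents, TrialEvents,
                         interval_overlap_s)


def platform_percent(trial: TrialEvents, tone_s: float = 30.0) -> float:
    """Percent of the tone spent on the platform (half-open windows)."""
    window = (trial.tone_onset_s, trial.tone_onset_s + tone_s)
    return 100.0 * interval_overlap_s(trial.platform_intervals_s, window) / tone_s


def platform_timecourse(trial: TrialEvents, tone_s: float = 30.0,
                        bin_s: float = 3.0) -> np.ndarray:
    """Platform occupancy % in consecutive 3-s bins of the tone."""
    n = int(round(tone_s / bin_s))
    out = np.empty(n)
    for i in range(n):
        lo = trial.tone_onset_s + i * bin_s
        out[i] = 100.0 * interval_overlap_s(trial.platform_intervals_s,
                                            (lo, lo + bin_s)) / bin_s
    return out


def avoidance_latency(trial: TrialEvents, tone_s: float = 30.0,
                      ) -> tuple[float, bool]:
    """(latency_s, never_avoided): first platform entry at/after tone onset
    within the tone, minus onset; trials with no such entry get the 30-s
    cap and the flag."""
    on = trial.tone_onset_s
    for a, _ in trial.platform_intervals_s:
        if on <= a < on + tone_s:
            return a - on, False
    return tone_s, True


def freezing_percent(trial: TrialEvents, tone_s: float = 30.0) -> float:
    """Percent of the tone spent freezing (pre-scored intervals)."""
    window = (trial.tone_onset_s, trial.tone_onset_s + tone_s)
    return 100.0 * interval_overlap_s(trial.freezing_intervals_s, window) / tone_s


def suppression_ratio(pretone_rate: float, tone_rate: float,
                      percent: bool = False) -> float:
    """Conditioned suppression of bar pressing.

    (p − t)/(p + t): 0 = no suppression, 1 = complete suppression (tone
    rate zero); both rates zero returns 0 by convention.  Antisymmetric
    under swapping the two rates.
    """
    if pretone_rate < 0 or tone_rate < 0:
        raise ValueError("press rates must be non-negative")
    denom = pretone_rate + tone_rate
    value = 0.0 if denom == 0 else (pretone_rate - tone_rate) / denom
    return 100.0 * value if percent else value


def press_rates(trial: TrialEvents, tone_s: float = 30.0,
                pretone_window_s: float = 60.0) -> tuple[float, float]:
    """(pretone, tone) bar-press rates in Hz; pretone over the 60 s before
    tone onset."""
    on = trial.tone_onset_s
    p = trial.press_times_s
    n_pre = int(np.sum((p >= on - pretone_window_s) & (p < on)))
    n_tone = int(np.sum((p >= on) & (p < on + tone_s)))
    return n_pre / pretone_window_s, n_tone / tone_s


def trial_summary(trial: TrialEvents,
                  config: ClassifierConfig = ClassifierConfig()) -> dict:
    tone_s = config.tone_duration_s
    lat, never = avoidance_latency(trial, tone_s)
    pre, tone = press_rates(trial, tone_s, config.pretone_rate_window_s)
    return {
        "trial_id": trial.trial_id,
        "pct_platform": platform_percent(trial, tone_s),
        "avoid_latency_s": lat,
        "never_avoided": never,
        "pct_freezing": freezing_percent(trial, tone_s),
        "pretone_rate_hz": pre,
        "tone_rate_hz": tone,
        "suppression": suppression_ratio(pre, tone),
    }


def session_behavior(session: SessionEvents,
                     config: ClassifierConfig = ClassifierConfig(),
                     ) -> pd.DataFrame:
    """Per-trial behavioral summary for a session (one row per trial)."""
    return pd.DataFrame([trial_summary(t, config) for t in session.trials])


__all__ = [
    "platform_percent", "platform_timecourse", "avoidance_latency",
    "freezing_percent", "suppression_ratio", "press_rates",
    "trial_summary", "session_behavior",
]
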