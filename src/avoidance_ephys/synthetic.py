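"""Seeded generator of synthetic avoidance-recording cohorts.

Emulates the statistical structure the analysis assumes: putative
projection units firing ~6 Hz at baseline (log-normal across units),
9-trial sessions of 30-s tones with variable ~3-min inter-trial intervals,
a 2-s footshock co-terminating with the tone (avoidance and fear groups),
platform entries at log-normal latencies with median 3.55 s, bar pressing
that stops while the rat occupies the platform or freezes, and tone-evoked
unit responses: brief excitation at tone onset, or a rate drop to ~2 Hz
starting within a second of onset (brief ~8 s or sustained through the
tone).

Spike trains are inhomogeneous Poisson processes with piecewise-constant
rate, sampled exactly by thinning a homogeneous process at the maximum
rate.  No spikes are emitted during the shock (the recording convention).
Refractoriness is not modeled; at the rates simulated (<15 Hz) its effect
on 500-ms counts is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data_model import (GROUPS, SessionEvents, TrialEvents, UnitRecording,
                         ValidationError, write_events, write_units)

RESPONSE_CLASSES = ("none", "excited", "inhibited_brief", "inhibited_sustained")

#: per-group unit counts by response class, mirroring the recorded cohorts
DEFAULT_COMPOSITION: dict[str, dict[str, int]] = {
    "avoidance": {"excited": 30, "inhibited_brief": 18,
                  "inhibited_sustained": 4, "none": 153},
    "naive": {"excited": 20, "inhibited_brief": 3,
              "inhibited_sustained": 0, "none": 143},
    "fear": {"excited": 25, "inhibited_brief": 3,
             "inhibited_sustained": 0, "none": 163},
}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions."""

    # session structure
    n_trials: int = 9
    tone_s: float = 30.0
    shock_s: float = 2.0
    iti_mean_s: float = 180.0
    iti_jitter_s: float = 60.0      # ITI ~ uniform(mean - jitter, mean + jitter)
    lead_in_s: float = 180.0        # quiet period before the first tone

    # unit firing
    baseline_rate_median_hz: float = 6.0
    baseline_rate_sigma: float = 0.35     # log-normal spread across units
    excite_gain: float = 3.0              # multiplier on the first 0.5 s of the tone
    excite_duration_s: float = 0.5
    inhibit_floor_hz: float = 2.0
    inhibit_onset_lo_s: float = 0.0       # inhibition lag ~ uniform(lo, hi), per unit
    inhibit_onset_hi_s: float = 1.0
    inhibit_brief_s: float = 8.0
    inhibit_sustained_s: float = 28.0

    # behavior
    platform_latency_median_s: float = 3.55
    platform_latency_sigma: float = 0.95  # ~91% of entries later than 1 s
    p_avoid: float = 0.7
    p_platform_naive: float = 0.5
    press_rate_hz: float = 0.5
    freeze_fraction: dict[str, float] = field(
        default_factory=lambda: {"avoidance": 0.30, "naive": 0.05, "fear": 0.60})

    # unit metadata
    spike_width_mean_us: float = 330.0
    spike_width_sd_us: float = 50.0
    composition: dict[str, dict[str, int]] = field(
        default_factory=lambda: {g: dict(c) for g, c in DEFAULT_COMPOSITION.items()})

    def __post_init__(self) -> None:
        for name in ("baseline_rate_median_hz", "excite_gain", "press_rate_hz",
                     "tone_s", "iti_mean_s"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.inhibit_floor_hz < 0:
            raise ValidationError("inhibit_floor_hz must be non-negative")
        for p in (self.p_avoid, self.p_platform_naive):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


# ---------------------------------------------------------------------------
# behavioral sessions


def simulate_session(config: SimConfig, group: str, rng: np.random.Generator,
                     session_id: str | None = None) -> SessionEvents:
    """Draw one session's behavioral/stimulus event stream for a group.

    Avoidance sessions have tones, shocks and platform entries; naive
    sessions have tones and (unforced) platform visits but no shock; fear
    sessions have tones and shocks but no platform events.  Bar presses are
    generated in the 60-s pretone window and during the tone, thinned to
    zero while the rat is on the platform or freezing.
    """
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}")
    trials: list[TrialEvents] = []
    onset = config.lead_in_s
    for i in range(config.n_trials):
        tone_end = onset + config.tone_s
        shock = None
        if group in ("avoidance", "fear"):
            shock = (tone_end - config.shock_s, tone_end)

        platform: list[tuple[float, float]] = []
        headturn = None
        p_entry = {"avoidance": config.p_avoid,
                   "naive": config.p_platform_naive,
                   "fear": 0.0}[group]
        if rng.random() < p_entry:
            # log-normal latency truncated to the tone (≈1% of the mass),
            # so p_entry alone sets the per-trial avoidance probability
            latency = config.tone_s
            for _ in range(100):
                latency = float(rng.lognormal(
                    np.log(config.platform_latency_median_s),
                    config.platform_latency_sigma))
                if latency < config.tone_s:
                    break
            latency = min(latency, config.tone_s - 1e-3)
            entry = onset + latency
            exit_ = tone_end + float(rng.uniform(1.0, 5.0))
            platform.append((entry, exit_))
            headturn = max(onset, entry - float(rng.uniform(0.2, 1.0)))

        freezing: list[tuple[float, float]] = []
        frac = config.freeze_fraction.get(group, 0.0)
        if frac > 0:
            start = onset + float(rng.uniform(0.0, 3.0))
            dur = frac * config.tone_s * float(rng.uniform(0.7, 1.3))
            end = min(start + dur, tone_end)
            if end > start:
                freezing.append((start, end))

        # presses over [onset-60, tone_end), thinned during occupancy/freezing
        t0 = onset - 60.0
        n = rng.poisson(config.press_rate_hz * (tone_end - t0))
        presses = np.sort(rng.uniform(t0, tone_end, size=n))
        for a, b in platform + freezing:
            presses = presses[(presses < a) | (presses >= b)]

        trials.append(TrialEvents(
            trial_id=i + 1,
            tone_onset_s=onset,
            tone_duration_s=config.tone_s,
            shock_interval_s=shock,
            platform_intervals_s=platform,
            headturn_s=headturn,
            freezing_intervals_s=freezing,
            press_times_s=presses,
        ))
        onset = tone_end + float(rng.uniform(config.iti_mean_s - config.iti_jitter_s,
                                             config.iti_mean_s + config.iti_jitter_s))
    sid = session_id if session_id is not None else f"{group}-session"
    return SessionEvents(session_id=sid, trials=trials)


def session_end_s(session: SessionEvents, tail_s: float = 30.0) -> float:
    last = session.trials[-1]
    return last.tone_window_s[1] + tail_s


# ---------------------------------------------------------------------------
# spike trains


def _rate_profile(config: SimConfig, response_class: str,
                  session: SessionEvents, baseline_rate_hz: float,
                  inhibit_onset_s: float,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant rate as (edges, rates); rates[i] holds on
    [edges[i], edges[i+1])."""
    if response_class not in RESPONSE_CLASSES:
        raise ValidationError(f"unknown response class {response_class!r}")
    if baseline_rate_hz < 0:
        raise ValidationError("baseline rate must be non-negative")
    T = session_end_s(session)
    # (start, end, rate) modifications, later entries override earlier ones
    mods: list[tuple[float, float, float]] = []
    for tr in session.trials:
        on, off = tr.tone_window_s
        if response_class == "excited":
            mods.append((on, on + config.excite_duration_s,
                         baseline_rate_hz * config.excite_gain))
        elif response_class.startswith("inhibited"):
            dur = (config.inhibit_brief_s if response_class == "inhibited_brief"
                   else config.inhibit_sustained_s)
            mods.append((on + inhibit_onset_s,
                         min(on + inhibit_onset_s + dur, off),
                         config.inhibit_floor_hz))
        if tr.shock_interval_s is not None:
            mods.append((tr.shock_interval_s[0], tr.shock_interval_s[1], 0.0))
    edges = np.unique(np.concatenate(
        [[0.0, T]] + [[a, b] for a, b, _ in mods]).clip(0.0, T))
    rates = np.full(edges.size - 1, baseline_rate_hz)
    mid = (edges[:-1] + edges[1:]) / 2.0
    for a, b, r in mods:
        if r < 0:
            raise ValidationError("negative firing rate in simulation config")
        rates[(mid >= a) & (mid < b)] = r
    return edges, rates


def _thinned_poisson(edges: np.ndarray, rates: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Exact inhomogeneous Poisson sample by thinning at the maximum rate."""
    rate_max = float(rates.max(initial=0.0))
    T = float(edges[-1])
    if rate_max <= 0 or T <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * T)
    t = np.sort(rng.uniform(0.0, T, size=n))
    local = rates[np.clip(np.searchsorted(edges, t, side="right") - 1,
                          0, rates.size - 1)]
    keep = rng.random(n) < local / rate_max
    return t[keep]


def simulate_unit(config: SimConfig, response_class: str,
                  session: SessionEvents, rng: np.random.Generator,
                  unit_id: str = "u0", region: str = "rPL",
                  group: str = "avoidance",
                  baseline_rate_hz: float | None = None,
                  inhibit_onset_s: float | None = None,
                  spike_width_us: float | None = None) -> UnitRecording:
    """Simulate one unit against a session's event stream.

    The inhibition onset lag is a property of the cell (one draw, applied
    on every trial), matching the per-unit latency analysis downstream.
    """
    if baseline_rate_hz is None:
        baseline_rate_hz = float(rng.lognormal(
            np.log(config.baseline_rate_median_hz), config.baseline_rate_sigma))
    if inhibit_onset_s is None:
        inhibit_onset_s = float(rng.uniform(config.inhibit_onset_lo_s,
                                            config.inhibit_onset_hi_s))
    if spike_width_us is None:
        spike_width_us = float(max(120.0, rng.normal(config.spike_width_mean_us,
                                                     config.spike_width_sd_us)))
    edges, rates = _rate_profile(config, response_class, session,
                                 baseline_rate_hz, inhibit_onset_s)
    spikes = _thinned_poisson(edges, rates, rng)
    return UnitRecording(unit_id=unit_id, region=region,
                         spike_width_us=spike_width_us, group=group,
                         spike_times_s=spikes,
                         ap_mm=float(rng.uniform(3.2, 4.2)) if region == "rPL"
                         else float(rng.uniform(2.2, 3.2)))


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(config: SimConfig, seed: int | np.random.Generator,
                    ) -> dict[str, tuple[list[UnitRecording], SessionEvents]]:
    """Simulate all groups: one session per group plus its units.

    All units of a group share the group session (as if recorded together);
    inhibited units in the avoidance group are placed in rostral PL, other
    units are assigned a region at random, mirroring the observed anatomy.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out: dict[str, tuple[list[UnitRecording], SessionEvents]] = {}
    for group in GROUPS:
        comp = config.composition.get(group, {})
        if not comp:
            continue
        session = simulate_session(config, group, rng, session_id=f"{group}-01")
        units: list[UnitRecording] = []
        k = 0
        for rclass in RESPONSE_CLASSES:
            for _ in range(int(comp.get(rclass, 0))):
                k += 1
                if group == "avoidance" and rclass.startswith("inhibited"):
                    region = "rPL"
                else:
                    region = "rPL" if rng.random() < 0.5 else "cPL"
                units.append(simulate_unit(
                    config, rclass, session, rng,
                    unit_id=f"{group[:2]}{k:04d}", region=region, group=group))
        out[group] = (units, session)
    return out


def write_cohort(cohort: dict[str, tuple[list[UnitRecording], SessionEvents]],
                 out_dir: str | Path) -> dict[str, dict[str, Path]]:
    """Write per-group units/spikes/events CSV triplets under ``out_dir``."""
    out_dir = Path(out_dir)
    paths: dict[str, dict[str, Path]] = {}
    for group, (units, session) in cohort.items():
        gdir = out_dir / group
        gdir.mkdir(parents=True, exist_ok=True)
        p = {"units": gdir / "units.csv", "spikes": gdir / "spikes.csv",
             "events": gdir / "events.csv"}
        write_units(units, p["units"], p["spikes"])
        write_events(session, p["events"])
        paths[group] = p
    return paths


# ---------------------------------------------------------------------------
# optrode (laser) protocols


@dataclass(frozen=True)
class LaserProtocol:
    """Laser ON/OFF block structure for anesthetized optrode validation."""

    off_s: float
    on_s: float
    gap_s: float
    n_trials: int
    name: str = ""

    @property
    def period_s(self) -> float:
        return self.off_s + self.on_s + self.gap_s


#: constant green light: 10 s OFF then 10 s ON, 10 trials
ARCHT_PROTOCOL = LaserProtocol(off_s=10.0, on_s=10.0, gap_s=0.0,
                               n_trials=10, name="ArchT")
#: pulsed blue light: 30 s OFF, 30 s ON, 30 s rest, 5 trials
CHR2_PROTOCOL = LaserProtocol(off_s=30.0, on_s=30.0, gap_s=30.0,
                              n_trials=5, name="ChR2")


def simulate_laser_unit(protocol: LaserProtocol, rate_off_hz: float,
                        rate_on_hz: float, rng: np.random.Generator,
                        ) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Spike train of one unit under an ON/OFF laser protocol.

    Returns (spike_times_s, laser_on_intervals).  Rate is ``rate_off_hz``
    everywhere except during the ON intervals.
    """
    if rate_off_hz < 0 or rate_on_hz < 0:
        raise ValidationError("laser rates must be non-negative")
    T = protocol.period_s * protocol.n_trials
    intervals = []
    mods = []
    for i in range(protocol.n_trials):
        a = i * protocol.period_s + protocol.off_s
        b = a + protocol.on_s
        intervals.append((a, b))
        mods.append((a, b, rate_on_hz))
    edges = np.unique(np.concatenate([[0.0, T]] + [[a, b] for a, b, _ in mods]))
    rates = np.full(edges.size - 1, rate_off_hz)
    mid = (edges[:-1] + edges[1:]) / 2.0
    for a, b, r in mods:
        rates[(mid >= a) & (mid < b)] = r
    return _thinned_poisson(edges, rates, rng), intervals


__all__ = [
    "SimConfig", "RESPONSE_CLASSES", "DEFAULT_COMPOSITION",
    "simulate_session", "simulate_unit", "simulate_cohort", "write_cohort",
    "session_end_s", "LaserProtocol", "ARCHT_PROTOCOL", "CHR2_PROTOCOL",
    "simulate_laser_unit",
]
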