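"""Domain types and tabular I/O for avoidance-ephys.

All times are seconds from session start (floats, 0-based).  Every interval
in the package is half-open ``[start, end)`` so that adjacent windows never
double-count a spike or a second of occupancy.

Interchange formats (UTF-8 CSV, header row, '.' decimal):

* ``units.csv``   — unit_id, region, ap_mm, spike_width_us, group
* ``spikes.csv``  — unit_id, spike_time_s (long format)
* ``events.csv``  — trial_id, event_type, time_s
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGIONS = ("rPL", "cPL")
GROUPS = ("avoidance", "naive", "fear")

EVENT_TYPES = (
    "tone_onset",
    "shock_on",
    "shock_off",
    "platform_entry",
    "platform_exit",
    "headturn",
    "freeze_start",
    "freeze_end",
    "press",
    "laser_on",
    "laser_off",
)


class ValidationError(ValueError):
    """A record violates a domain invariant (named in the message)."""


class ParseError(ValueError):
    """A file row cannot be interpreted (line number in the message)."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ClassifierConfig:
    """Parameters of the peri-event response classifier.

    Defaults encode the analysis conventions of the avoidance recordings:
    500-ms bins, a 10-s pretone baseline (20 bins), a 28-s response window
    (the 2-s shock at tone end is masked), a two-tailed p<0.01 excitation
    threshold and p<0.05 inhibition threshold on the bin z-scores, the
    first-five-trials rule for tone alignment, and the one-tailed p<0.05
    z-criterion on interspike intervals for inhibition latency.
    """

    bin_width_s: float = 0.5
    baseline_bins: int = 20          # 10 s pretone
    response_bins: int = 56          # 28 s; shock epoch excluded
    z_excite: float = 2.58           # first 500-ms bin, two-tailed p<0.01
    z_inhibit: float = -1.96         # first or second bin, two-tailed p<0.05
    n_trials_for_tone: int = 5
    isi_z: float = 1.65              # one-tailed p<0.05 on ISI length
    isi_baseline_s: float = 30.0
    pretone_rate_window_s: float = 60.0   # bar-press pretone rate window
    projection_width_us: float = 225.0
    projection_rate_hz: float = 15.0
    min_platform_latency_s: float = 1.0   # entries earlier than this are
                                          # excluded from entry alignment
    tone_duration_s: float = 30.0
    # brief vs sustained inhibition: "sustained" = inhibited in at least
    # this fraction of bins over sustained_window_s (relative to tone onset)
    sustained_bin_fraction: float = 0.5
    sustained_window_s: tuple[float, float] = (10.0, 28.0)

    def __post_init__(self) -> None:
        if self.bin_width_s <= 0 or self.baseline_bins <= 0 or self.response_bins <= 0:
            raise ValidationError("bin geometry must be strictly positive")
        if self.z_inhibit >= 0:
            raise ValidationError("z_inhibit must be negative")
        for name in ("z_excite", "isi_z", "isi_baseline_s", "pretone_rate_window_s",
                     "projection_width_us", "projection_rate_hz", "tone_duration_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")

    @property
    def n_bins(self) -> int:
        return self.baseline_bins + self.response_bins

    @property
    def bin_edges_s(self) -> np.ndarray:
        """Edges relative to the alignment event, −10 … +28 s by default."""
        lo = -self.baseline_bins * self.bin_width_s
        return lo + np.arange(self.n_bins + 1) * self.bin_width_s


# ---------------------------------------------------------------------------
# core records


@dataclass
class UnitRecording:
    """One sorted unit: spike timestamps plus recording metadata."""

    unit_id: str
    region: str
    spike_width_us: float
    group: str
    spike_times_s: np.ndarray
    ap_mm: float | None = None

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unit {self.unit_id}: unknown region {self.region!r}")
        if self.group not in GROUPS:
            raise ValidationError(f"unit {self.unit_id}: unknown group {self.group!r}")
        if not self.spike_width_us > 0:
            raise ValidationError(f"unit {self.unit_id}: spike_width_us must be > 0")
        t = self.spike_times_s
        if t.size and t[0] < 0:
            raise ValidationError(f"unit {self.unit_id}: negative spike time")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"unit {self.unit_id}: spike times not strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    @property
    def is_empty(self) -> bool:
        """Zero-spike units are retained (flagged), never dropped."""
        return self.n_spikes == 0


def _check_intervals(iv: Sequence[tuple[float, float]], what: str,
                     ctx: str, allow_overlap: bool = False) -> list[tuple[float, float]]:
    out = [(float(a), float(b)) for a, b in iv]
    for a, b in out:
        if not b > a:
            raise ValidationError(f"{ctx}: {what} interval [{a}, {b}) is empty or inverted")
    out.sort()
    if not allow_overlap:
        for (a0, b0), (a1, b1) in zip(out, out[1:]):
            if a1 < b0:
                raise ValidationError(f"{ctx}: overlapping {what} intervals")
    return out


@dataclass
class TrialEvents:
    """Events of one trial, all in absolute session seconds."""

    trial_id: int
    tone_onset_s: float
    tone_duration_s: float = 30.0
    shock_interval_s: tuple[float, float] | None = None
    platform_intervals_s: list[tuple[float, float]] = field(default_factory=list)
    headturn_s: float | None = None
    freezing_intervals_s: list[tuple[float, float]] = field(default_factory=list)
    press_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    laser_intervals_s: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.press_times_s = np.asarray(self.press_times_s, dtype=float)
        ctx = f"trial {self.trial_id}"
        if self.tone_duration_s <= 0:
            raise ValidationError(f"{ctx}: tone_duration_s must be > 0")
        self.platform_intervals_s = _check_intervals(
            self.platform_intervals_s, "platform", ctx)
        self.freezing_intervals_s = _check_intervals(
            self.freezing_intervals_s, "freezing", ctx)
        self.laser_intervals_s = _check_intervals(
            self.laser_intervals_s, "laser", ctx)
        if self.shock_interval_s is not None:
            a, b = self.shock_interval_s
            if not b > a:
                raise ValidationError(f"{ctx}: shock interval empty or inverted")
            self.shock_interval_s = (float(a), float(b))

    @property
    def tone_window_s(self) -> tuple[float, float]:
        return (self.tone_onset_s, self.tone_onset_s + self.tone_duration_s)

    def first_platform_entry_s(self) -> float | None:
        """First platform entry at/after tone onset and before tone end."""
        on, off = self.tone_window_s
        for a, _ in self.platform_intervals_s:
            if on <= a < off:
                return a
        return None


@dataclass
class SessionEvents:
    """Trials of one behavioral session, ordered by tone onset."""

    session_id: str
    trials: list[TrialEvents]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        onsets = [t.tone_onset_s for t in self.trials]
        if onsets != sorted(onsets):
            raise ValidationError(
                f"session {self.session_id}: trials not ordered by tone onset")
        windows = [t.tone_window_s for t in self.trials]
        for (a0, b0), (a1, b1) in zip(windows, windows[1:]):
            if a1 < b0:
                raise ValidationError(
                    f"session {self.session_id}: overlapping tone windows")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# interval algebra


def interval_overlap_s(intervals: Iterable[tuple[float, float]],
                       window: tuple[float, float]) -> float:
    """Total length of ``intervals ∩ window`` (all half-open).

    Invariant to splitting any interval at an interior point.
    """
    lo, hi = window
    total = 0.0
    for a, b in intervals:
        total += max(0.0, min(b, hi) - max(a, lo))
    return total


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def read_units(units_path: str | Path, spikes_path: str | Path) -> list[UnitRecording]:
    """Read unit metadata + long-format spike table into UnitRecording objects.

    Units present in ``units.csv`` but absent from ``spikes.csv`` come back
    with zero spikes (flagged via ``is_empty``), not dropped.
    """
    units_path, spikes_path = str(units_path), str(spikes_path)
    try:
        meta = pd.read_csv(units_path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as parse error
        raise ParseError(f"{units_path}: {exc}") from exc
    _require_columns(meta, ["unit_id", "region", "ap_mm", "spike_width_us", "group"],
                     units_path)
    try:
        spk = pd.read_csv(spikes_path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{spikes_path}: {exc}") from exc
    _require_columns(spk, ["unit_id", "spike_time_s"], spikes_path)
    if spk["spike_time_s"].isna().any():
        line = int(spk.index[spk["spike_time_s"].isna()][0]) + 2  # header + 1-based
        raise ParseError(f"{spikes_path}: unparseable spike_time_s at line {line}")

    by_unit = {uid: g["spike_time_s"].to_numpy(dtype=float)
               for uid, g in spk.groupby("unit_id", sort=False)}
    units: list[UnitRecording] = []
    for row in meta.itertuples(index=False):
        ap = None if pd.isna(row.ap_mm) else float(row.ap_mm)
        units.append(UnitRecording(
            unit_id=str(row.unit_id),
            region=str(row.region),
            spike_width_us=float(row.spike_width_us),
            group=str(row.group),
            spike_times_s=by_unit.get(str(row.unit_id), np.empty(0)),
            ap_mm=ap,
        ))
    return units


def write_units(units: Sequence[UnitRecording],
                units_path: str | Path, spikes_path: str | Path) -> None:
    meta = pd.DataFrame({
        "unit_id": [u.unit_id for u in units],
        "region": [u.region for u in units],
        "ap_mm": [u.ap_mm for u in units],
        "spike_width_us": [u.spike_width_us for u in units],
        "group": [u.group for u in units],
    })
    meta.to_csv(units_path, index=False)
    spk = pd.DataFrame({
        "unit_id": np.repeat([u.unit_id for u in units],
                             [u.n_spikes for u in units]),
        "spike_time_s": np.concatenate([u.spike_times_s for u in units])
        if units else np.empty(0),
    })
    spk.to_csv(spikes_path, index=False)


def _pair_intervals(starts: list[float], ends: list[float],
                    what: str, ctx: str) -> list[tuple[float, float]]:
    if len(starts) != len(ends):
        raise ValidationError(f"{ctx}: unbalanced {what} start/end events")
    out = []
    for a, b in zip(sorted(starts), sorted(ends)):
        if b <= a:
            raise ValidationError(f"{ctx}: {what} end at {b} precedes start at {a}")
        out.append((a, b))
    return out


def read_events(path: str | Path, session_id: str | None = None) -> SessionEvents:
    """Assemble a SessionEvents from the long event table.

    Rows are grouped by ``trial_id``; each trial must contain exactly one
    ``tone_onset``.  Interval event pairs (platform, freeze, shock, laser)
    are matched in time order within the trial.
    """
    path = str(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: {exc}") from exc
    _require_columns(df, ["trial_id", "event_type", "time_s"], path)
    bad = ~df["event_type"].isin(EVENT_TYPES)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ParseError(
            f"{path}: unknown event_type {df.loc[df.index[bad][0], 'event_type']!r} "
            f"at line {line}")
    if df["time_s"].isna().any():
        line = int(df.index[df['time_s'].isna()][0]) + 2
        raise ParseError(f"{path}: unparseable time_s at line {line}")

    trials: list[TrialEvents] = []
    for trial_id, g in df.groupby("trial_id", sort=True):
        ctx = f"trial {trial_id}"
        times = {et: sorted(g.loc[g["event_type"] == et, "time_s"].tolist())
                 for et in EVENT_TYPES}
        if len(times["tone_onset"]) != 1:
            raise ValidationError(
                f"{ctx}: expected exactly one tone_onset, got {len(times['tone_onset'])}")
        onset = times["tone_onset"][0]
        shocks = _pair_intervals(times["shock_on"], times["shock_off"], "shock", ctx)
        if len(shocks) > 1:
            raise ValidationError(f"{ctx}: more than one shock interval")
        trials.append(TrialEvents(
            trial_id=int(trial_id),
            tone_onset_s=onset,
            shock_interval_s=shocks[0] if shocks else None,
            platform_intervals_s=_pair_intervals(
                times["platform_entry"], times["platform_exit"], "platform", ctx),
            headturn_s=times["headturn"][0] if times["headturn"] else None,
            freezing_intervals_s=_pair_intervals(
                times["freeze_start"], times["freeze_end"], "freezing", ctx),
            press_times_s=np.asarray(times["press"], dtype=float),
            laser_intervals_s=_pair_intervals(
                times["laser_on"], times["laser_off"], "laser", ctx),
        ))
    trials.sort(key=lambda t: t.tone_onset_s)
    sid = session_id if session_id is not None else Path(path).stem
    return SessionEvents(session_id=sid, trials=trials)


def write_events(session: SessionEvents, path: str | Path) -> None:
    rows: list[tuple[int, str, float]] = []
    for t in session.trials:
        rows.append((t.trial_id, "tone_onset", t.tone_onset_s))
        if t.shock_interval_s is not None:
            rows.append((t.trial_id, "shock_on", t.shock_interval_s[0]))
            rows.append((t.trial_id, "shock_off", t.shock_interval_s[1]))
        for a, b in t.platform_intervals_s:
            rows.append((t.trial_id, "platform_entry", a))
            rows.append((t.trial_id, "platform_exit", b))
        if t.headturn_s is not None:
            rows.append((t.trial_id, "headturn", t.headturn_s))
        for a, b in t.freezing_intervals_s:
            rows.append((t.trial_id, "freeze_start", a))
            rows.append((t.trial_id, "freeze_end", b))
        for p in t.press_times_s:
            rows.append((t.trial_id, "press", float(p)))
        for a, b in t.laser_intervals_s:
            rows.append((t.trial_id, "laser_on", a))
            rows.append((t.trial_id, "laser_off", b))
    df = pd.DataFrame(rows, columns=["trial_id", "event_type", "time_s"])
    df = df.sort_values(["trial_id", "time_s"], kind="mergesort")
    df.to_csv(path, index=False)


__all__ = [
    "ClassifierConfig", "UnitRecording", "TrialEvents", "SessionEvents",
    "ValidationError", "ParseError", "REGIONS", "GROUPS", "EVENT_TYPES",
    "interval_overlap_s", "read_units", "write_units", "read_events",
    "write_events", "replace",
]
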