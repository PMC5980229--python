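"""Interspike-interval detection of inhibition onset latency.

Inhibition latency on a trial is the start of the first interspike
interval (ISI) beginning in the tone window that is significantly longer
than the average pretone ISI: z = (ISI − mean)/SD > 1.65, one-tailed
p < 0.05, with mean and sample SD taken over the ISIs of the 30-s pretone
window of that trial.  Only ISIs whose starting spike falls at/after tone
onset qualify (the ISI straddling onset starts pretone), so latencies are
non-negative and below the tone duration; the gap from the last in-window
spike to the window end is not an ISI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import (ClassifierConfig, SessionEvents, TrialEvents,
                         UnitRecording)


@dataclass(frozen=True)
class IsiBaseline:
    """Pretone ISI statistics for one unit on one trial."""

    unit_id: str
    trial_id: int
    mean_isi_s: float
    sd_isi_s: float
    n_isis: int

    @property
    def scorable(self) -> bool:
        return self.n_isis >= 2 and np.isfinite(self.sd_isi_s) and self.sd_isi_s > 0


def isi_baseline(unit: UnitRecording, trial: TrialEvents,
                 config: ClassifierConfig = ClassifierConfig()) -> IsiBaseline:
    """ISIs between consecutive spikes inside the 30-s pretone window."""
    on = trial.tone_onset_s
    t = unit.spike_times_s
    pre = t[(t >= on - config.isi_baseline_s) & (t < on)]
    isis = np.diff(pre)
    n = isis.size
    mean = float(np.mean(isis)) if n else np.nan
    sd = float(np.std(isis, ddof=1)) if n >= 2 else np.nan
    return IsiBaseline(unit.unit_id, trial.trial_id, mean, sd, int(n))


def inhibition_latency(unit: UnitRecording, trial: TrialEvents,
                       config: ClassifierConfig = ClassifierConfig(),
                       ) -> tuple[float | None, str]:
    """(latency_s, reason) for one unit on one trial.

    latency is None when the baseline is unscorable ('unscorable_baseline')
    or no tone-window ISI crosses the z criterion ('no_qualifying_isi');
    reason is 'ok' otherwise.
    """
    base = isi_baseline(unit, trial, config)
    if not base.scorable:
        return None, "unscorable_baseline"
    on = trial.tone_onset_s
    end = on + config.tone_duration_s
    t = unit.spike_times_s
    # consecutive spike pairs whose *starting* spike is inside the tone window
    idx = np.nonzero((t[:-1] >= on) & (t[:-1] < end))[0]
    for i in idx:
        isi = t[i + 1] - t[i]
        z = (isi - base.mean_isi_s) / base.sd_isi_s
        if z > config.isi_z:
            return float(t[i] - on), "ok"
    return None, "no_qualifying_isi"


def latency_records(units, session: SessionEvents,
                    config: ClassifierConfig = ClassifierConfig()) -> pd.DataFrame:
    """One row per unit × trial: inhibition latency paired with the trial's
    behavioral latencies (platform entry and headturn; missing as NaN)."""
    rows = []
    for unit in units:
        for trial in session.trials:
            lat, reason = inhibition_latency(unit, trial, config)
            entry = trial.first_platform_entry_s()
            rows.append({
                "unit_id": unit.unit_id,
                "trial_id": trial.trial_id,
                "inhibition_latency_s": np.nan if lat is None else lat,
                "reason": reason,
                "platform_latency_s": (np.nan if entry is None
                                       else entry - trial.tone_onset_s),
                "headturn_latency_s": (np.nan if trial.headturn_s is None
                                       else trial.headturn_s - trial.tone_onset_s),
                "avoided": entry is not None,
            })
    return pd.DataFrame(rows)


def per_cell_latency_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean inhibition / platform / headturn latency per cell over trials
    with successful avoidance and a detected inhibition latency.

    Cells with no qualifying trial are omitted; the returned frame reports
    the number of contributing trials per cell.
    """
    ok = records[records["avoided"] & records["inhibition_latency_s"].notna()]
    if ok.empty:
        return pd.DataFrame(columns=["unit_id", "mean_inhibition_latency_s",
                                     "mean_platform_latency_s",
                                     "mean_headturn_latency_s", "n_trials"])
    g = ok.groupby("unit_id", sort=True)
    out = pd.DataFrame({
        "mean_inhibition_latency_s": g["inhibition_latency_s"].mean(),
        "mean_platform_latency_s": g["platform_latency_s"].mean(),
        "mean_headturn_latency_s": g["headturn_latency_s"].mean(),
        "n_trials": g.size(),
    }).reset_index()
    return out


def latency_correlation(xs, ys) -> tuple[float, float]:
    """Pearson product-moment correlation with two-tailed p, pairwise
    complete (NaN pairs dropped)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    keep = np.isfinite(xs) & np.isfinite(ys)
    if keep.sum() < 3:
        return np.nan, np.nan
    x, y = xs[keep], ys[keep]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan      # correlation undefined for constant input
    r = sps.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


class InhibitionLatencyModel:
    """Trial-by-trial inhibition latency for a cohort in one session.

    ``fit()`` scans every unit × trial, returning per-trial records, the
    per-cell averages over successful-avoidance trials, and correlations
    between neural and behavioral latencies.
    """

    def __init__(self, units, session: SessionEvents,
                 config: ClassifierConfig = ClassifierConfig()):
        self.units = list(units)
        self.session = session
        self.config = config

    @classmethod
    def from_csv(cls, units_csv, spikes_csv, events_csv, **kwargs):
        from .data_model import read_events, read_units
        return cls(read_units(units_csv, spikes_csv), read_events(events_csv),
                   **kwargs)

    def fit(self) -> "InhibitionLatencyResults":
        records = latency_records(self.units, self.session, self.config)
        return InhibitionLatencyResults(self, records)


class InhibitionLatencyResults:
    """Fitted latency records with per-cell summaries and correlations."""

    def __init__(self, model: InhibitionLatencyModel, records: pd.DataFrame):
        self.model = model
        self.records = records
        self.per_cell = per_cell_latency_summary(records)

    def fraction_with_qualifying_isi(self) -> float:
        """Share of cells with ≥1 detected (tone-window) inhibition ISI,
        over any trial."""
        detected = (self.records.groupby("unit_id")["inhibition_latency_s"]
                    .apply(lambda s: s.notna().any()))
        return float(detected.mean()) if len(detected) else np.nan

    def correlation(self, behavior: str = "platform") -> tuple[float, float]:
        """Pearson r (and p) between per-cell mean inhibition latency and a
        behavioral latency ('platform' or 'headturn')."""
        col = {"platform": "mean_platform_latency_s",
               "headturn": "mean_headturn_latency_s"}[behavior]
        return latency_correlation(self.per_cell["mean_inhibition_latency_s"],
                                   self.per_cell[col])

    def summary(self) -> pd.DataFrame:
        return self.per_cell


__all__ = [
    "IsiBaseline", "isi_baseline", "inhibition_latency", "latency_records",
    "per_cell_latency_summary", "latency_correlation",
    "InhibitionLatencyModel", "InhibitionLatencyResults",
]
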