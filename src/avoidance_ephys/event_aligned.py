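"""Peri-event spike-train analysis: binning, z-scoring, classification.

The classifier follows the recording analysis convention: spike counts in
500-ms bins aligned to an event, converted to trial-averaged rates,
z-scored against the mean and SD of the 20 pretone (10 s) bins, and
thresholded — excitation if the first tone bin exceeds +2.58 (two-tailed
p<0.01), inhibition if either of the first two bins falls below −1.96
(two-tailed p<0.05; the longer latency allowance reflects multi-synaptic
inhibitory pathways).  Tone-onset alignment uses the first five trials;
platform-entry alignment uses all successful-avoidance trials whose entry
came at least 1 s after tone onset, z-scored against the pretone baseline
of those same trials.  The 2-s shock at tone end is masked by truncating
analysis windows at shock onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (ClassifierConfig, SessionEvents, TrialEvents,
                         UnitRecording, ValidationError)

ALIGNMENTS = ("tone_onset", "platform_entry")
LABELS = ("excited", "inhibited", "none", "unclassifiable")


@dataclass(frozen=True)
class ResponseLabel:
    """Classification of one unit at one alignment event."""

    unit_id: str
    alignment: str
    label: str
    trigger_bin: int | None = None   # 0 or 1: which early bin crossed threshold

    def __post_init__(self) -> None:
        if self.alignment not in ALIGNMENTS:
            raise ValidationError(f"unknown alignment {self.alignment!r}")
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")


@dataclass
class PeriEventCounts:
    """Per-trial spike counts in half-open peri-event bins.

    ``widths_s`` holds the effective bin widths after truncation at shock
    onset; a width of 0 marks a fully masked bin (rate NaN).
    """

    trial_ids: list[int]
    align_times_s: np.ndarray
    bin_edges_s: np.ndarray
    counts: np.ndarray               # trials x bins
    widths_s: np.ndarray             # trials x bins

    @property
    def rates_hz(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.counts / self.widths_s
        r[self.widths_s <= 0] = np.nan
        return r

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)


def _qualifying_trials(session: SessionEvents, alignment: str,
                       config: ClassifierConfig) -> list[tuple[TrialEvents, float]]:
    """(trial, align_time) pairs entering the analysis for an alignment."""
    out: list[tuple[TrialEvents, float]] = []
    if alignment == "tone_onset":
        for tr in session.trials[:config.n_trials_for_tone]:
            out.append((tr, tr.tone_onset_s))
    elif alignment == "platform_entry":
        for tr in session.trials:
            entry = tr.first_platform_entry_s()
            if entry is None:
                continue
            if entry - tr.tone_onset_s < config.min_platform_latency_s:
                continue                # tone-onset contamination guard
            out.append((tr, entry))
    else:
        raise ValidationError(f"unknown alignment {alignment!r}")
    return out


def peri_event_counts(unit: UnitRecording, session: SessionEvents,
                      alignment: str = "tone_onset",
                      config: ClassifierConfig = ClassifierConfig(),
                      ) -> PeriEventCounts:
    """Bin one unit's spikes around each qualifying alignment event.

    Bins are half-open ``[edge_i, edge_{i+1})`` relative to the event;
    any bin reaching into the trial's shock epoch is truncated at shock
    onset.  No qualifying trials yields an empty (0-trial) result, not an
    exception.
    """
    pairs = _qualifying_trials(session, alignment, config)
    edges = config.bin_edges_s
    nb = config.n_bins
    counts = np.zeros((len(pairs), nb))
    widths = np.zeros((len(pairs), nb))
    spikes = unit.spike_times_s
    for i, (tr, t0) in enumerate(pairs):
        cut = tr.shock_interval_s[0] if tr.shock_interval_s is not None else np.inf
        lo = t0 + edges[:-1]
        hi = np.minimum(t0 + edges[1:], cut)
        w = np.clip(hi - lo, 0.0, None)
        widths[i] = w
        valid = w > 0
        if valid.any() and spikes.size:
            counts[i, valid] = (np.searchsorted(spikes, hi[valid], side="left")
                                - np.searchsorted(spikes, lo[valid], side="left"))
    return PeriEventCounts(trial_ids=[tr.trial_id for tr, _ in pairs],
                           align_times_s=np.array([t for _, t in pairs]),
                           bin_edges_s=edges, counts=counts, widths_s=widths)


@dataclass
class ZRow:
    """One unit's z-scored peri-event profile.

    ``baseline_mean_hz``/``baseline_sd_hz`` are the per-unit estimates
    (mean and sample SD over the 20 pretone trial-averaged bin rates);
    ``z`` is the full −10 … +28 s profile.  A zero or undefined baseline
    SD flags the row unclassifiable (z all-NaN), never an error.
    """

    z: np.ndarray
    baseline_mean_hz: float
    baseline_sd_hz: float
    n_trials: int
    unclassifiable: bool


def zscore(counts: PeriEventCounts, config: ClassifierConfig = ClassifierConfig(),
           baseline: tuple[float, float] | None = None) -> ZRow:
    """Trial-average bin rates and z-score against the pretone baseline.

    ``baseline`` overrides the (mean, SD) pair, used for platform-entry
    alignment where the z-scores are computed against the pretone baseline
    of the same trials' tones.
    """
    nb0 = config.baseline_bins
    if counts.n_trials == 0:
        return ZRow(np.full(config.n_bins, np.nan), np.nan, np.nan, 0, True)
    valid = counts.widths_s > 0
    nvalid = valid.sum(axis=0)
    rates = np.where(valid, np.divide(counts.counts, counts.widths_s,
                                      out=np.zeros_like(counts.counts),
                                      where=valid), 0.0)
    with np.errstate(invalid="ignore"):
        r = np.where(nvalid > 0, rates.sum(axis=0) / np.maximum(nvalid, 1), np.nan)
    if baseline is not None:
        mu, sd = baseline
    else:
        base = r[:nb0]
        if np.isnan(base).any():
            return ZRow(np.full(config.n_bins, np.nan), np.nan, np.nan,
                        counts.n_trials, True)
        mu = float(np.mean(base))
        sd = float(np.std(base, ddof=1))
    if not np.isfinite(sd) or sd <= 0:
        return ZRow(np.full(config.n_bins, np.nan), mu, sd, counts.n_trials, True)
    return ZRow((r - mu) / sd, mu, sd, counts.n_trials, False)


def classify_response(zrow: ZRow, config: ClassifierConfig = ClassifierConfig(),
                      unit_id: str = "", alignment: str = "tone_onset",
                      ) -> ResponseLabel:
    """Threshold the first one (excitation) or two (inhibition) event bins.

    Excitation is evaluated first; a row crossing both thresholds (possible
    only for pathological profiles) is labeled excited.
    """
    if zrow.unclassifiable:
        return ResponseLabel(unit_id, alignment, "unclassifiable")
    b0 = config.baseline_bins
    z0, z1 = zrow.z[b0], zrow.z[b0 + 1]
    if np.isfinite(z0) and z0 > config.z_excite:
        return ResponseLabel(unit_id, alignment, "excited", trigger_bin=0)
    if np.isfinite(z0) and z0 < config.z_inhibit:
        return ResponseLabel(unit_id, alignment, "inhibited", trigger_bin=0)
    if np.isfinite(z1) and z1 < config.z_inhibit:
        return ResponseLabel(unit_id, alignment, "inhibited", trigger_bin=1)
    return ResponseLabel(unit_id, alignment, "none")


def inhibition_duration_class(zrow: ZRow,
                              config: ClassifierConfig = ClassifierConfig()) -> str:
    """'sustained' if inhibited in ≥ half the bins of the late tone window
    (10–28 s by default), else 'brief'."""
    lo, hi = config.sustained_window_s
    edges = config.bin_edges_s[:-1]
    sel = (edges >= lo) & (edges < hi)
    zsel = zrow.z[sel]
    zsel = zsel[np.isfinite(zsel)]
    if zsel.size == 0:
        return "brief"
    frac = float(np.mean(zsel < config.z_inhibit))
    return "sustained" if frac >= config.sustained_bin_fraction else "brief"


def time_resolved_proportions(z: np.ndarray,
                              config: ClassifierConfig = ClassifierConfig(),
                              ) -> pd.DataFrame:
    """Per-bin fraction of classifiable units above/below the thresholds.

    The denominator at each bin is the number of units with a finite
    z-score there (unclassifiable units, and bins masked by the shock,
    drop out); the output reports it per bin.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    finite = np.isfinite(z)
    n_bin = finite.sum(axis=0)
    denom = np.maximum(n_bin, 1)
    exc = np.where(n_bin > 0, (finite & (z > config.z_excite)).sum(axis=0) / denom, 0.0)
    inh = np.where(n_bin > 0, (finite & (z < config.z_inhibit)).sum(axis=0) / denom, 0.0)
    return pd.DataFrame({
        "bin_start_s": config.bin_edges_s[:-1],
        "frac_excited": exc,
        "frac_inhibited": inh,
        "n_classifiable": n_bin,
    })


def heatmap_matrix(z: np.ndarray, unit_ids: list[str],
                   config: ClassifierConfig = ClassifierConfig(),
                   ) -> tuple[np.ndarray, list[str]]:
    """Order rows by mean z over the first two event bins, descending.

    A pure reordering (the multiset of rows is preserved); ties broken by
    unit_id for stability.  NaN rows (unclassifiable) sort to the bottom.
    """
    z = np.asarray(z, dtype=float)
    b0 = config.baseline_bins
    key = np.mean(z[:, b0:b0 + 2], axis=1)
    key = np.where(np.isfinite(key), key, -np.inf)
    order = sorted(range(len(unit_ids)), key=lambda i: (-key[i], unit_ids[i]))
    return z[order], [unit_ids[i] for i in order]


def is_putative_projection(unit: UnitRecording, baseline_rate_hz: float,
                           config: ClassifierConfig = ClassifierConfig()) -> bool:
    """Projection-neuron criterion: spike width > 225 µs and baseline
    firing rate < 15 Hz (both strict)."""
    return (unit.spike_width_us > config.projection_width_us
            and baseline_rate_hz < config.projection_rate_hz)


def overlap_venn(tone_labels: dict[str, str], platform_labels: dict[str, str],
                 ) -> dict[str, dict[str, int]]:
    """Tone-only / platform-only / both counts, per response polarity."""
    out: dict[str, dict[str, int]] = {}
    for polarity in ("excited", "inhibited"):
        tset = {u for u, lab in tone_labels.items() if lab == polarity}
        pset = {u for u, lab in platform_labels.items() if lab == polarity}
        out[polarity] = {
            "tone_only": len(tset - pset),
            "platform_only": len(pset - tset),
            "both": len(tset & pset),
        }
    return out


# ---------------------------------------------------------------------------
# model / results


class PeriEventModel:
    """Peri-event response model for a cohort of units in one session.

    Parameters
    ----------
    units : sequence of UnitRecording
    session : SessionEvents
    alignment : 'tone_onset' or 'platform_entry'
    config : ClassifierConfig

    ``fit()`` estimates each unit's pretone baseline (mean, sample SD over
    the 20 pretone trial-averaged bin rates), z-scores the peri-event
    profile and classifies the response.
    """

    def __init__(self, units, session: SessionEvents,
                 alignment: str = "tone_onset",
                 config: ClassifierConfig = ClassifierConfig()):
        if alignment not in ALIGNMENTS:
            raise ValidationError(f"unknown alignment {alignment!r}")
        self.units = list(units)
        self.session = session
        self.alignment = alignment
        self.config = config

    @classmethod
    def from_csv(cls, units_csv, spikes_csv, events_csv, **kwargs):
        from .data_model import read_events, read_units
        return cls(read_units(units_csv, spikes_csv), read_events(events_csv),
                   **kwargs)

    def fit(self) -> "PeriEventResults":
        cfg = self.config
        nb = cfg.n_bins
        n = len(self.units)
        z = np.full((n, nb), np.nan)
        mu = np.full(n, np.nan)
        sd = np.full(n, np.nan)
        ntr = np.zeros(n, dtype=int)
        labels: list[ResponseLabel] = []
        for i, unit in enumerate(self.units):
            if self.alignment == "tone_onset":
                pec = peri_event_counts(unit, self.session, "tone_onset", cfg)
                zrow = zscore(pec, cfg)
            else:
                pec = peri_event_counts(unit, self.session, "platform_entry", cfg)
                zrow = self._platform_zrow(unit, pec, cfg)
            z[i] = zrow.z
            mu[i], sd[i] = zrow.baseline_mean_hz, zrow.baseline_sd_hz
            ntr[i] = zrow.n_trials
            labels.append(classify_response(zrow, cfg, unit.unit_id, self.alignment))
        return PeriEventResults(self, z, mu, sd, ntr, labels)

    def _platform_zrow(self, unit: UnitRecording, pec: PeriEventCounts,
                       cfg: ClassifierConfig) -> ZRow:
        """Platform-entry z-scores against the same trials' pretone baseline.

        The pretone segment of the profile (for heat maps) is tone-aligned;
        the response segment is entry-aligned; both share one baseline.
        """
        if pec.n_trials == 0:
            return ZRow(np.full(cfg.n_bins, np.nan), np.nan, np.nan, 0, True)
        qualifying = set(pec.trial_ids)
        tone_session = SessionEvents(
            session_id=self.session.session_id,
            trials=[t for t in self.session.trials if t.trial_id in qualifying])
        cfg_all = ClassifierConfig(**{
            **{f: getattr(cfg, f) for f in cfg.__dataclass_fields__},
            "n_trials_for_tone": len(tone_session.trials)})
        tone_pec = peri_event_counts(unit, tone_session, "tone_onset", cfg_all)
        tone_z = zscore(tone_pec, cfg_all)
        if tone_z.unclassifiable:
            return ZRow(np.full(cfg.n_bins, np.nan), tone_z.baseline_mean_hz,
                        tone_z.baseline_sd_hz, pec.n_trials, True)
        baseline = (tone_z.baseline_mean_hz, tone_z.baseline_sd_hz)
        entry_z = zscore(pec, cfg, baseline=baseline)
        z = entry_z.z.copy()
        z[:cfg.baseline_bins] = tone_z.z[:cfg.baseline_bins]
        return ZRow(z, baseline[0], baseline[1], pec.n_trials, False)


class PeriEventResults:
    """Fitted peri-event responses: baselines, z-profiles, labels."""

    def __init__(self, model: PeriEventModel, z: np.ndarray,
                 baseline_mean_hz: np.ndarray, baseline_sd_hz: np.ndarray,
                 n_trials_used: np.ndarray, labels: list[ResponseLabel]):
        self.model = model
        self.config = model.config
        self.alignment = model.alignment
        self.unit_ids = [u.unit_id for u in model.units]
        self.z = z
        self.baseline_mean_hz = baseline_mean_hz
        self.baseline_sd_hz = baseline_sd_hz
        self.n_trials_used = n_trials_used
        self.labels = labels

    # -- tabular views ------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """One row per unit: label, trigger bin, baseline estimates."""
        rows = []
        for unit, lab, mu, sd, nt, zrow in zip(
                self.model.units, self.labels, self.baseline_mean_hz,
                self.baseline_sd_hz, self.n_trials_used, self.z):
            duration = ""
            if lab.label == "inhibited":
                duration = inhibition_duration_class(
                    ZRow(zrow, mu, sd, nt, False), self.config)
            rows.append({
                "unit_id": unit.unit_id, "region": unit.region,
                "group": unit.group, "alignment": self.alignment,
                "label": lab.label,
                "trigger_bin": (np.nan if lab.trigger_bin is None
                                else float(lab.trigger_bin)),
                "inhibition_duration": duration,
                "baseline_mean_hz": mu, "baseline_sd_hz": sd,
                "n_trials": int(nt),
                "putative_projection": is_putative_projection(unit, mu, self.config)
                if np.isfinite(mu) else False,
            })
        return pd.DataFrame(rows)

    def label_counts(self) -> dict[str, int]:
        c = {lab: 0 for lab in LABELS}
        for lab in self.labels:
            c[lab.label] += 1
        return c

    def label_map(self) -> dict[str, str]:
        return {lab.unit_id: lab.label for lab in self.labels}

    def proportions(self) -> pd.DataFrame:
        return time_resolved_proportions(self.z, self.config)

    def heatmap(self) -> tuple[np.ndarray, list[str]]:
        return heatmap_matrix(self.z, self.unit_ids, self.config)

    # -- plotting -----------------------------------------------------

    def plot_heatmap(self, ax=None, cmap: str = "RdBu_r", vlim: float = 5.0):
        """Population heat map (one row per unit, 0.5-s bins)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        z, _ = self.heatmap()
        edges = self.config.bin_edges_s
        im = ax.imshow(z, aspect="auto", cmap=cmap, vmin=-vlim, vmax=vlim,
                       extent=[edges[0], edges[-1], z.shape[0], 0])
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_xlabel(f"time from {self.alignment.replace('_', ' ')} (s)")
        ax.set_ylabel("unit")
        return im


__all__ = [
    "ALIGNMENTS", "LABELS", "ResponseLabel", "PeriEventCounts", "ZRow",
    "peri_event_counts", "zscore", "classify_response",
    "inhibition_duration_class", "time_resolved_proportions",
    "heatmap_matrix", "is_putative_projection", "overlap_venn",
    "PeriEventModel", "PeriEventResults",
]
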