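"""End-to-end orchestration: simulate/load → classify → latency → behavior
→ population statistics, with a reproducible report bundle.

A single top-level seed fans out to per-stage child seeds through
``numpy.random.SeedSequence.spawn`` (stage 0: simulation), so each stage is
independently reproducible.  Every output file name is fixed and every
written table is fully determined by (inputs, seed, config); the report
carries the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import session_behavior
from .data_model import (ClassifierConfig, GROUPS, read_events, read_units)
from .event_aligned import PeriEventModel, overlap_venn
from .isi_latency import InhibitionLatencyModel
from .stats import chi_square, fisher_exact_2x2
from .synthetic import SimConfig, simulate_cohort, write_cohort

log = logging.getLogger("avoidance_ephys")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(*configs) -> str:
    """Stable short hash of the run configuration(s)."""
    payload = json.dumps([_jsonify(asdict(c)) for c in configs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def region_breakdown(summary: pd.DataFrame) -> dict:
    """Response counts by region (rPL vs cPL) with a Fisher exact
    comparison of inhibited proportions between regions."""
    counts = {}
    for region in ("rPL", "cPL"):
        sub = summary[summary["region"] == region]
        counts[region] = {
            "n": int(len(sub)),
            "excited": int((sub["label"] == "excited").sum()),
            "inhibited": int((sub["label"] == "inhibited").sum()),
        }
    out = {"counts": counts}
    for polarity in ("inhibited", "excited"):
        table = [[counts["rPL"][polarity], counts["rPL"]["n"] - counts["rPL"][polarity]],
                 [counts["cPL"][polarity], counts["cPL"]["n"] - counts["cPL"][polarity]]]
        if counts["rPL"]["n"] and counts["cPL"]["n"]:
            out[f"fisher_p_{polarity}"] = fisher_exact_2x2(table)
    return out


def _load_groups(data_dir: Path) -> dict:
    groups = {}
    for group in GROUPS:
        gdir = data_dir / group
        if not gdir.is_dir():
            continue
        for name in ("units.csv", "spikes.csv", "events.csv"):
            if not (gdir / name).exists():
                raise FileNotFoundError(f"{gdir / name} missing")
        units = read_units(gdir / "units.csv", gdir / "spikes.csv")
        session = read_events(gdir / "events.csv", session_id=f"{group}-01")
        groups[group] = (units, session)
    if not groups:
        raise FileNotFoundError(f"no group subdirectories under {data_dir}")
    return groups


def run_pipeline(out_dir: str | Path, seed: int,
                 sim_config: SimConfig | None = None,
                 data_dir: str | Path | None = None,
                 config: ClassifierConfig = ClassifierConfig()) -> dict:
    """Run the full analysis and write the report bundle under ``out_dir``.

    Either ``data_dir`` (per-group units/spikes/events CSV triplets) or a
    ``sim_config`` (cohort simulated at the stage seed) supplies the data.
    Returns the report dict (also written as report.json).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_config = sim_config if sim_config is not None else SimConfig()
    seeds = np.random.SeedSequence(seed).spawn(1)

    # -- stage: data -------------------------------------------------
    try:
        if data_dir is not None:
            groups = _load_groups(Path(data_dir))
        else:
            rng = np.random.default_rng(seeds[0])
            groups = simulate_cohort(sim_config, rng)
            write_cohort(groups, out_dir / "data")
    except Exception as exc:
        raise PipelineError(f"stage 'data': {exc}") from exc

    summaries, behavior_frames, latency_frames, percell_frames = [], [], [], []
    report: dict = {
        "seed": int(seed),
        "config_hash": config_hash(config, sim_config),
        "groups": {},
    }

    for group, (units, session) in groups.items():
        log.info("group %s: %d units, %d trials", group, len(units),
                 session.n_trials)
        # -- stage: classify ------------------------------------------
        try:
            tone = PeriEventModel(units, session, "tone_onset", config).fit()
            platform = PeriEventModel(units, session, "platform_entry",
                                      config).fit()
        except Exception as exc:
            raise PipelineError(f"stage 'classify' ({group}): {exc}") from exc
        st, sp = tone.summary(), platform.summary()
        summaries.extend([st, sp])
        # -- stage: latency -------------------------------------------
        try:
            lat = InhibitionLatencyModel(units, session, config).fit()
        except Exception as exc:
            raise PipelineError(f"stage 'latency' ({group}): {exc}") from exc
        rec = lat.records.copy()
        rec.insert(0, "group", group)
        latency_frames.append(rec)
        pc = lat.per_cell.copy()
        pc.insert(0, "group", group)
        percell_frames.append(pc)
        # -- stage: behavior ------------------------------------------
        try:
            beh = session_behavior(session, config)
        except Exception as exc:
            raise PipelineError(f"stage 'behavior' ({group}): {exc}") from exc
        beh.insert(0, "group", group)
        behavior_frames.append(beh)

        tone_counts = tone.label_counts()
        r_corr, r_p = lat.correlation("platform")
        report["groups"][group] = {
            "n_units": len(units),
            "tone": tone_counts,
            "platform_entry": platform.label_counts(),
            "region_breakdown_tone": region_breakdown(st),
            "venn": overlap_venn(tone.label_map(), platform.label_map()),
            "latency": {
                "fraction_cells_with_qualifying_isi":
                    lat.fraction_with_qualifying_isi(),
                "pearson_r_inhibition_vs_platform": r_corr,
                "pearson_p": r_p,
            },
            "behavior": {
                "mean_pct_platform": float(beh["pct_platform"].mean()),
                "median_avoid_latency_s": float(beh["avoid_latency_s"].median()),
                "mean_pct_freezing": float(beh["pct_freezing"].mean()),
                "mean_suppression": float(beh["suppression"].mean()),
            },
        }

    # -- stage: stats -------------------------------------------------
    try:
        tone_tables = {}
        for polarity in ("inhibited", "excited"):
            table = []
            for group in report["groups"]:
                c = report["groups"][group]["tone"]
                n = report["groups"][group]["n_units"]
                table.append([c[polarity], n - c[polarity]])
            if len(table) >= 2:
                res = chi_square(table)
                tone_tables[polarity] = {
                    "table": table, "chi_square": res.statistic,
                    "df": res.df, "p": res.p,
                }
        report["tone_response_by_group"] = tone_tables
    except Exception as exc:
        raise PipelineError(f"stage 'stats': {exc}") from exc

    # -- stage: write -------------------------------------------------
    try:
        responses = pd.concat(summaries, ignore_index=True)
        responses.to_csv(out_dir / "responses.csv", index=False)
        pd.concat(latency_frames, ignore_index=True).to_csv(
            out_dir / "latencies.csv", index=False)
        percell = [f for f in percell_frames if not f.empty]
        (pd.concat(percell, ignore_index=True) if percell
         else percell_frames[0]).to_csv(
            out_dir / "latency_per_cell.csv", index=False)
        pd.concat(behavior_frames, ignore_index=True).to_csv(
            out_dir / "behavior.csv", index=False)
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise PipelineError(f"stage 'write': {exc}") from exc
    n_resp = responses[responses["alignment"] == "tone_onset"].shape[0]
    n_units_total = sum(g["n_units"] for g in report["groups"].values())
    if n_resp != n_units_total:
        raise PipelineError(
            f"stage 'write': unit count mismatch ({n_resp} != {n_units_total})")
    return report


__all__ = ["run_pipeline", "region_breakdown", "config_hash", "PipelineError"]
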