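"""End-to-end orchestration: simulate -> detect -> classify -> TFA -> stats.

A run is deterministic given the seed in its SimConfig; the manifest records
the configuration echo, per-stage counts, and the main summary numbers so
two runs with the same seed produce byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classifier import FEATURE_NAMES, classify, extract_features, train_classifier
from .eeg import SEGMENT_HALF_S, bandpass_eeg, tfa_window
from .respiration import (
    PauseEvent,
    detect_breaths,
    filter_isolated,
    find_pauses,
    preprocess_respiration,
    select_baseline_window,
)
from .simulate import SimConfig, config_dict, make_labelled_candidates, simulate_cohort
from .stats import TMap, fdr_mask, fit_all_models, summarize_change, ttest_map
from .vitals import vitals_changes

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: Optional[str] = None
    n_train_true: int = 100
    n_train_false: int = 100
    detect_k: float = 0.5
    detect_w: int = 120
    min_pause_s: float = 5.0
    fdr_q: float = 0.01
    amp_limit_uv: float = 500.0
    stat_decim: int = 10  # time decimation of TFA segments kept for statistics
    compute_start_locked: bool = True


@dataclass
class RunResult:
    events: pd.DataFrame
    tmaps: dict  # (category, lock) -> TMap
    lmm: pd.DataFrame
    manifest: dict
    change_stacks: dict  # (category, lock) -> (event_stack, baseline_stack)


def _process_recording(rec, cfg: RunConfig, model):
    counts = {"candidates": 0, "classified_true": 0, "classified_false": 0, "excluded": 0}
    fs_r = rec.fs_resp
    thorax = preprocess_respiration(rec.resp["thorax"], fs_r)
    breaths = detect_breaths(thorax, fs_r, k=cfg.detect_k, w=cfg.detect_w)
    candidates = find_pauses(breaths, cfg.min_pause_s)
    counts["candidates"] = len(candidates)
    rec_sd = float(thorax.std())

    rows, kept_events = [], []
    feat_rows, feat_events = [], []
    for ev in candidates:
        try:
            f = extract_features(thorax, fs_r, ev, rec_sd)
        except ValueError:
            counts["excluded"] += 1
            continue
        feat_rows.append({n: getattr(f, n) for n in FEATURE_NAMES})
        feat_events.append(ev)
    if feat_rows:
        verdicts = classify(model, pd.DataFrame(feat_rows))
        for ev, (_, v) in zip(feat_events, verdicts.iterrows()):
            ev.extra["prob_true"] = float(v["prob_true"])
            if bool(v["verdict"]):
                counts["classified_true"] += 1
                kept_events.append(ev)
            else:
                counts["classified_false"] += 1

    kept_events = filter_isolated(kept_events, candidates)
    isolated = [e for e in kept_events if e.isolated]
    counts["isolated"] = len(isolated)

    for ev in isolated:
        bw = select_baseline_window(breaths, ev)
        ev.baseline_window = bw
        epoch_idx = min(int(ev.start_s // 30.0), len(rec.sleep_labels) - 1)
        row = {
            "recording_id": rec.recording_id,
            "infant_id": rec.infant_id,
            "pma_weeks": rec.pma_weeks,
            "start_s": ev.start_s,
            "end_s": ev.end_s,
            "duration_s": ev.duration_s,
            "category": ev.category,
            "prob_true": ev.extra.get("prob_true", np.nan),
            "sleep_state": rec.sleep_labels[epoch_idx],
            "baseline_start_s": bw[0] if bw else np.nan,
            "baseline_end_s": bw[1] if bw else np.nan,
        }
        if bw is not None:
            vc = vitals_changes(rec.hr, rec.spo2, rec.fs_vitals, ev.end_s, bw)
            row.update(
                hr_change=vc.hr_change if vc.hr_valid else np.nan,
                spo2_change=vc.spo2_change if vc.spo2_valid else np.nan,
                spo2_floor_hit=vc.floor_hit,
            )
        else:
            row.update(hr_change=np.nan, spo2_change=np.nan, spo2_floor_hit=False)
        rows.append((ev, row))
    counts["with_baseline"] = sum(1 for ev, _ in rows if ev.baseline_window is not None)
    return breaths, rows, counts


def _eeg_segments(rec, ev, cfg: RunConfig):
    """Decimated TFA segments for one event: end-/start-locked vs baseline."""
    half = SEGMENT_HALF_S[ev.category]
    fs = rec.fs_eeg
    eeg_f = rec.extra_filtered  # cached band-passed EEG
    d = cfg.stat_decim
    out = {}
    b0, b1 = ev.baseline_window
    base = tfa_window(eeg_f, fs, b0, b1)
    if base is None:
        return None
    base = base[::d]
    for lock, centre in (("end", ev.end_s), ("start", ev.start_s)):
        if lock == "start" and not cfg.compute_start_locked:
            continue
        seg = tfa_window(eeg_f, fs, centre - half, centre + half)
        if seg is None:
            return None
        seg = seg[::d]
        n = min(seg.shape[0], base.shape[0])
        out[lock] = (seg[:n], base[:n])
    # channel screen on the raw (unfiltered-scale) segment around the event
    i0 = max(0, int(round((ev.start_s - half) * fs)))
    i1 = min(rec.eeg.shape[0], int(round((ev.end_s + half) * fs)))
    keep = np.max(np.abs(rec.eeg[i0:i1]), axis=0) <= cfg.amp_limit_uv
    out["keep_channels"] = keep
    return out


def run_pipeline(cfg: RunConfig) -> RunResult:
    sim = cfg.sim
    train = make_labelled_candidates(sim, cfg.n_train_true, cfg.n_train_false)
    model, cv_report = train_classifier(train)
    pooled_ba = float(
        cv_report.loc[cv_report["fold"] == "pooled", "balanced_accuracy"].iloc[0]
    )

    all_rows = []
    stacks: dict = {}
    totals: dict = {}
    for rec, gt in simulate_cohort(sim):
        rec.extra_filtered = bandpass_eeg(rec.eeg, rec.fs_eeg)
        breaths, rows, counts = _process_recording(rec, cfg, model)
        for k, v in counts.items():
            totals[k] = totals.get(k, 0) + v
        for ev, row in rows:
            row["eeg_change"] = np.nan
            if ev.baseline_window is not None:
                segs = _eeg_segments(rec, ev, cfg)
                if segs is not None:
                    keep = segs["keep_channels"]
                    for lock in ("end", "start"):
                        if lock not in segs:
                            continue
                        seg, base = segs[lock]
                        seg = seg.copy()
                        seg[..., ~keep] = np.nan
                        key = (ev.category, lock)
                        stacks.setdefault(key, ([], []))
                        stacks[key][0].append(seg)
                        stacks[key][1].append(base)
                    if "end" in segs:
                        # scalar response: mean change over [-5, +5] s around
                        # the pause end (central slice of the end-locked segment)
                        seg, base = segs["end"]
                        fs_dec = rec.fs_eeg / cfg.stat_decim
                        n_t = seg.shape[0]
                        c = n_t // 2
                        hw = min(int(round(5.0 * fs_dec)), c)
                        sl = slice(c - hw, c + hw)
                        cmap = seg[sl] - base[sl]
                        row["eeg_change"] = summarize_change(cmap, keep)
            all_rows.append(row)
        del rec.extra_filtered

    events = pd.DataFrame(all_rows)
    totals["epochs_retained"] = int(events["eeg_change"].notna().sum()) if len(events) else 0

    tmaps = {}
    for key, (ev_list, bl_list) in stacks.items():
        n_t = min(s.shape[0] for s in ev_list)
        ev_stack = np.stack([s[:n_t] for s in ev_list])
        bl_stack = np.stack([s[:n_t] for s in bl_list])
        tm = ttest_map(ev_stack, bl_stack)
        tm.significant = fdr_mask(tm.p, cfg.fdr_q)
        tmaps[key] = tm
        stacks[key] = (ev_stack, bl_stack)

    lmm_rows = []
    if len(events):
        for res in fit_all_models(events):
            for term, b in res.beta1.items():
                lmm_rows.append(
                    {
                        "model": res.covariate,
                        "term": term,
                        "beta0": res.beta0,
                        "beta1": b,
                        "se": res.se_beta1[term],
                        "p": res.p_beta1,
                        "n": res.n_events,
                        "n_infants": res.n_infants,
                        "random_structure": res.random_structure,
                        "converged": res.converged,
                    }
                )
    lmm = pd.DataFrame(lmm_rows)

    cfg_echo = {"sim": config_dict(sim), "run": {
        k: getattr(cfg, k)
        for k in (
            "n_train_true", "n_train_false", "detect_k", "detect_w", "min_pause_s",
            "fdr_q", "amp_limit_uv", "stat_decim", "compute_start_locked",
        )
    }}
    cfg_json = json.dumps(cfg_echo, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "config": cfg_echo,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "counts": {k: int(v) for k, v in sorted(totals.items())},
        "classifier_pooled_balanced_accuracy": pooled_ba,
        "tmap_summary": {
            f"{cat}_{lock}": {
                "n_events": int(len(stacks[(cat, lock)][0])),
                "frac_significant": float(np.mean(tm.significant)),
                "mean_change": float(np.nanmean(stacks[(cat, lock)][0] - stacks[(cat, lock)][1])),
            }
            for (cat, lock), tm in sorted(tmaps.items())
        },
    }

    result = RunResult(events=events, tmaps=tmaps, lmm=lmm, manifest=manifest, change_stacks=stacks)
    if cfg.out_dir:
        _write_outputs(result, Path(cfg.out_dir))
    return result


def _write_outputs(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.events.to_csv(out / "events.csv", index=False, float_format="%.6g")
    result.lmm.to_csv(out / "lmm.csv", index=False, float_format="%.6g")
    with open(out / "manifest.json", "w") as f:
        json.dump(result.manifest, f, indent=2, sort_keys=True, default=str)
    rows = []
    for (cat, lock), tm in sorted(result.tmaps.items()):
        rows.append(
            {
                "category": cat,
                "lock": lock,
                "n_samples": int(np.isfinite(tm.p).sum()),
                "n_significant": int(tm.significant.sum()),
                "mean_t": float(np.nanmean(tm.t)) if np.isfinite(tm.t).any() else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(out / "tmaps.csv", index=False, float_format="%.6g")
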