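"""End-to-end pipeline driver: behavior → traces → events → population.

``analyze_session`` runs the full per-session analysis on trial records
plus ΔF/F traces; ``run_pipeline`` orchestrates a multi-mouse,
multi-day run — simulated when no input directory is configured — and
writes the result bundle (epochs CSV, lick-triggered CSV, zero-lag
cross-correlation CSV/HDF5, stability CSV, behavior JSON, manifest).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    TrialRecord, TrialType, classify_trial, reaction_time,
    session_performance,
)
from .config import PipelineConfig
from .events import epoch_quantify, align_trials, lick_triggered_average
from .population import pairwise_crosscorr, group_crosscorr, stability_r2
from .synthetic import SimParams, generate_session, simulate_dff
from .traces import stim_frame

__all__ = ["analyze_session", "run_pipeline"]

#: trial types whose aligned responses are quantified
QUANTIFIED_TYPES = ("WHIT", "WMISS", "AHIT", "AMISS")


def _trial_window_frames(frame_rate: float) -> tuple[int, int]:
    """Alignment window: 2 s before to 3.7 s after the stimulus frame."""
    return int(round(2.0 * frame_rate)), int(np.ceil(3.7 * frame_rate))


def analyze_session(
    trials: list[TrialRecord],
    dff: np.ndarray,
    class_labels: list[str],
    frame_rate: float,
    mouse: str = "m0",
    config: PipelineConfig | None = None,
) -> dict:
    """Per-session analysis on session-long ΔF/F traces.

    Returns a dict with keys ``performance``, ``epochs`` (tidy DataFrame:
    roi, class, mouse, trial_type, early/late/very_late/peak, n_trials),
    ``lick`` (DataFrame of lick-triggered pre/post values on false-alarm
    trials) and ``xcorr`` (CrossCorrSet on correct-rejection segments).
    """
    if config is None:
        config = PipelineConfig(frame_rate=frame_rate)
    dff = np.atleast_2d(dff)
    n_rois = dff.shape[0]
    classified = [(tr, classify_trial(tr)) for tr in trials]
    pre, post = _trial_window_frames(frame_rate)

    frames_by_type: dict[str, list[int]] = {t: [] for t in QUANTIFIED_TYPES}
    fa_lick_frames: list[int] = []
    cr_segments: list[tuple[int, int]] = []
    for tr, cls in classified:
        k0 = stim_frame(tr.stim_time, frame_rate)
        if cls.value in frames_by_type:
            frames_by_type[cls.value].append(k0)
        elif cls is TrialType.FA:
            rt = reaction_time(tr)
            fa_lick_frames.append(stim_frame(tr.stim_time + rt, frame_rate))
        elif cls is TrialType.CR:
            cr_segments.append((k0, min(k0 + post, dff.shape[1])))

    epoch_rows = []
    for i in range(n_rois):
        for tt, frames in frames_by_type.items():
            if not frames:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                aligned = align_trials(dff[i], frames, (pre, post))
            q = epoch_quantify(aligned, frame_rate, pre_frames=pre)
            epoch_rows.append(
                dict(roi=i, mouse=mouse, **{"class": class_labels[i]},
                     trial_type=tt, early=q.early, late=q.late,
                     very_late=q.very_late, peak=q.peak,
                     n_trials=q.n_trials)
            )
    epochs = pd.DataFrame(epoch_rows)

    lick_rows = []
    for i in range(n_rois):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lick_triggered_average(dff[i], fa_lick_frames, frame_rate)
        if res is not None:
            lick_rows.append(
                dict(roi=i, mouse=mouse, **{"class": class_labels[i]},
                     pre_value=res.pre_value, post_value=res.post_value,
                     n_trials=res.n_trials)
            )
    lick = pd.DataFrame(lick_rows)

    xcorr = None
    if n_rois >= 2 and cr_segments:
        xcorr = pairwise_crosscorr(
            dff, class_labels, segments=cr_segments,
            max_lag=config.xcorr_max_lag,
            normalization=config.xcorr_normalization, mouse=mouse,
        )
    return {
        "performance": session_performance(trials),
        "epochs": epochs,
        "lick": lick,
        "xcorr": xcorr,
    }


def _sim_params_for(config: PipelineConfig, seed: int) -> SimParams:
    return SimParams(
        n_s2p=config.n_s2p, n_m1p=config.n_m1p,
        frame_rate=config.frame_rate,
        session_length=config.session_length_s,
        quiet_window=config.quiet_window_s,
        reward_window=config.reward_window_s,
        neuropil_gain=0.7, seed=seed,
    )


def simulate_mouse_days(
    config: PipelineConfig, mouse_seed: int, n_days: int
) -> list[tuple]:
    """Simulate ``n_days`` sessions of one mouse.

    The neuron-level ground truth (class labels, evoked amplitudes) is
    drawn once from the first day's generator and shared across days, so
    day-to-day response differences come only from trial sampling and
    noise — the regime in which responses are expected to be stable.
    """
    days = []
    gt0 = None
    for d in range(n_days):
        params = _sim_params_for(config, mouse_seed + d)
        behavior, gt = generate_session(params)
        if gt0 is None:
            gt0 = gt
        else:  # share neuron identities across days
            gt.class_labels = gt0.class_labels
            gt.evoked_amp = gt0.evoked_amp
            gt.prelick_ramp = gt0.prelick_ramp
        dff = simulate_dff(behavior, gt, params)
        days.append((behavior, gt, dff, params))
    return days


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the result bundle to ``out_dir``.

    Without an ``input_dir`` the pipeline analyzes synthetic sessions at
    the configured scale (``n_mice`` × ``n_days``).  With one, sessions
    are loaded through :func:`wdi.deposit.load_external_deposit`.
    Deterministic given the config (including the seed).
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    warn_counts: dict[str, int] = {}

    sessions: dict[str, list[tuple]] = {}
    t0 = time.time()
    if config.input_dir is None:
        for m in range(config.n_mice):
            mouse = f"mouse{m:02d}"
            sessions[mouse] = simulate_mouse_days(
                config, config.seed + 1000 * m, config.n_days
            )
    else:
        from .deposit import load_external_deposit

        loaded = load_external_deposit(config.input_dir)
        for name, (trials, traceset) in loaded.items():
            sessions[name] = [
                (None, None, traceset.dff, None, trials, traceset)
            ]
    timings["load_or_simulate"] = time.time() - t0

    t0 = time.time()
    all_epochs, all_lick, perf = [], [], {}
    xcorr_rows = []
    stability_rows = []
    for mouse, days in sessions.items():
        day_results = []
        for d, day in enumerate(days):
            if config.input_dir is None:
                behavior, gt, dff, params = day
                trials = behavior.trials
                labels = gt.class_labels
            else:
                _, _, dff, _, trials, traceset = day
                labels = traceset.class_labels
            res = analyze_session(
                trials, dff, labels, config.frame_rate, mouse=mouse,
                config=config,
            )
            res["epochs"]["day"] = d + 1
            day_results.append(res)
            all_epochs.append(res["epochs"])
            all_lick.append(res["lick"])
            perf[f"{mouse}_day{d + 1}"] = asdict(res["performance"])
            if res["xcorr"] is not None and d == 0:
                for p in res["xcorr"].pairs:
                    xcorr_rows.append(
                        dict(mouse=mouse, roi_i=p.roi_i, roi_j=p.roi_j,
                             pair_class=p.pair_class, zero_lag=p.zero_lag,
                             valid=p.valid)
                    )
        # cross-day stability of whisker-hit peak responses
        if len(day_results) >= 2:
            for cls in ("S2p", "M1p"):
                frames = []
                for res in day_results:
                    e = res["epochs"]
                    sel = e[(e["trial_type"] == "WHIT")
                            & (e["class"] == cls)]
                    frames.append(sel.set_index("roi")["peak"])
                for i in range(len(frames)):
                    for j in range(i + 1, len(frames)):
                        common = frames[i].index.intersection(
                            frames[j].index
                        )
                        if len(common) >= 3:
                            st = stability_r2(
                                frames[i][common].to_numpy(),
                                frames[j][common].to_numpy(),
                            )
                            stability_rows.append(
                                dict(mouse=mouse, **{"class": cls},
                                     day_i=i + 1, day_j=j + 1,
                                     slope=st.slope,
                                     intercept=st.intercept,
                                     r_squared=st.r_squared, n=st.n)
                            )
    timings["analysis"] = time.time() - t0

    t0 = time.time()
    epochs_df = pd.concat(all_epochs, ignore_index=True)
    lick_df = pd.concat(all_lick, ignore_index=True)
    xcorr_df = pd.DataFrame(xcorr_rows)
    stability_df = pd.DataFrame(stability_rows)
    epochs_df.to_csv(out / "epochs.csv", index=False)
    lick_df.to_csv(out / "lick_triggered.csv", index=False)
    xcorr_df.to_csv(out / "xcorr_zero_lag.csv", index=False)
    stability_df.to_csv(out / "stability.csv", index=False)
    (out / "behavior.json").write_text(json.dumps(perf, indent=2))
    timings["write"] = time.time() - t0

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t_start, 3),
        "warnings": warn_counts,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "epochs": epochs_df,
        "lick": lick_df,
        "xcorr": xcorr_df,
        "stability": stability_df,
        "performance": perf,
        "manifest": manifest,
    }
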