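"""Stimulus-aligned trial averaging, epoch quantification and
lick-triggered averages.

All quantification windows are given in milliseconds relative to the
alignment event and mapped onto frames by frame start time: frame ``k``
covers ``[k/fr, (k+1)/fr)`` seconds, and a frame belongs to the window
``[a, b)`` ms when its start time lies in the window.  At 30 Hz the
standard post-stimulus epochs are early = [33, 233) ms (frames 1–6),
late = [233, 1000) ms (frames 7–29), and very late = [1000, 3600) ms
(frames 30–107); the peak is the maximum of the trial-averaged trace
over (0, 1000] ms, i.e. within the 1 s reward window.  The stimulus
frame itself (frame 0) belongs to no epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EPOCH_WINDOWS_MS",
    "EpochQuantification",
    "LickTriggeredResult",
    "align_trials",
    "window_frames",
    "epoch_quantify",
    "lick_triggered_average",
    "aggregate_by_mouse",
]

#: Post-stimulus quantification windows, ms, half-open [a, b).
EPOCH_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "early": (33.0, 233.0),
    "late": (233.0, 1000.0),
    "very_late": (1000.0, 3600.0),
}

#: Peak search window, ms, half-open (0, 1000].
PEAK_WINDOW_MS: tuple[float, float] = (0.0, 1000.0)

#: Lick-triggered quantification windows, ms relative to the first lick.
LICK_PRE_MS: tuple[float, float] = (-100.0, -33.0)
LICK_POST_MS: tuple[float, float] = (33.0, 167.0)
LICK_BASELINE_MS: tuple[float, float] = (-1200.0, -466.0)


def align_trials(
    trace: np.ndarray,
    event_frames: Sequence[int],
    window: tuple[int, int],
) -> np.ndarray:
    """Event-aligned matrix of a trace: one row per event.

    Row *t* holds ``trace[event_frames[t] - pre : event_frames[t] + post
    + 1]`` for ``window = (pre, post)`` in frames; column ``pre`` is the
    event frame for every row.  Events whose window exceeds the trace
    bounds are dropped with a warning.
    """
    trace = np.asarray(trace, dtype=float)
    pre, post = window
    rows = []
    dropped = 0
    for ev in event_frames:
        a, b = ev - pre, ev + post + 1
        if a < 0 or b > len(trace):
            dropped += 1
            continue
        rows.append(trace[a:b])
    if dropped:
        warnings.warn(
            f"dropped {dropped} trial(s) whose window exceeds the session",
            stacklevel=2,
        )
    if not rows:
        return np.empty((0, pre + post + 1))
    return np.vstack(rows)


def window_frames(
    window_ms: tuple[float, float],
    frame_rate: float,
    closed: str = "left",
) -> np.ndarray:
    """Frame offsets (relative to the event frame) inside a ms window.

    A frame belongs to the window when its start time ``k/fr`` lies in
    ``[a, b)`` ms (``closed="left"``, epoch convention) or ``(a, b]``
    (``closed="right"``, peak convention).
    """
    a, b = window_ms
    lo = a / 1000.0 * frame_rate
    hi = b / 1000.0 * frame_rate
    k = np.arange(int(np.floor(lo)) - 1, int(np.ceil(hi)) + 1)
    if closed == "left":
        sel = (k >= lo) & (k < hi)
    else:
        sel = (k > lo) & (k <= hi)
    return k[sel]


@dataclass
class EpochQuantification:
    """Early/late/very-late/peak ΔF/F summaries of an averaged response."""

    early: float | None
    late: float | None
    very_late: float | None
    peak: float | None
    n_trials: int


def epoch_quantify(
    aligned: np.ndarray,
    frame_rate: float,
    pre_frames: int = 0,
    per_trial_peak: bool = False,
) -> EpochQuantification:
    """Quantify a stimulus-aligned response matrix in the standard epochs.

    The trial-averaged trace is computed first; each epoch value is the
    mean of the averaged trace over the frames of that window, and the
    peak is the maximum of the averaged trace within the 1 s reward
    window.  (``per_trial_peak=True`` instead takes each trial's maximum
    and averages the maxima.)  Epochs whose window extends past the
    available post-event frames are ``None`` (undefined), never 0.

    ``pre_frames`` is the number of pre-event columns in ``aligned``
    (the event sits in column ``pre_frames``).
    """
    aligned = np.atleast_2d(np.asarray(aligned, dtype=float))
    n_trials, n_cols = aligned.shape
    if n_trials == 0:
        return EpochQuantification(None, None, None, None, 0)
    avg = aligned.mean(axis=0)
    n_post = n_cols - pre_frames  # frames 0 .. n_post-1 after the event

    def mean_over(window_ms, closed="left"):
        k = window_frames(window_ms, frame_rate, closed=closed)
        if len(k) == 0 or k.max() >= n_post:
            return None
        return float(avg[pre_frames + k].mean())

    values = {
        name: mean_over(win) for name, win in EPOCH_WINDOWS_MS.items()
    }
    kpk = window_frames(PEAK_WINDOW_MS, frame_rate, closed="right")
    if len(kpk) == 0 or kpk.max() >= n_post:
        peak = None
    elif per_trial_peak:
        peak = float(aligned[:, pre_frames + kpk].max(axis=1).mean())
    else:
        peak = float(avg[pre_frames + kpk].max())
    return EpochQuantification(
        early=values["early"],
        late=values["late"],
        very_late=values["very_late"],
        peak=peak,
        n_trials=n_trials,
    )


@dataclass
class LickTriggeredResult:
    """Lick-aligned average response of one ROI on false-alarm trials.

    ``pre_value`` and ``post_value`` are means over the 100–33 ms before
    and the 33–167 ms after the first lick, both relative to a baseline
    window 1200–466 ms before the lick.
    """

    average: np.ndarray
    pre_frames: int
    pre_value: float
    post_value: float
    n_trials: int


def lick_triggered_average(
    trace: np.ndarray,
    first_lick_frames: Sequence[int],
    frame_rate: float,
    window: tuple[int, int] | None = None,
) -> LickTriggeredResult | None:
    """Average a ROI's ΔF/F around the first lick of false-alarm trials.

    Returns ``None`` when no lick events survive windowing (the
    quantification is undefined without false-alarm trials).
    """
    if window is None:
        pre = int(np.ceil(1.3 * frame_rate))
        post = int(np.ceil(1.0 * frame_rate))
        window = (pre, post)
    aligned = align_trials(trace, first_lick_frames, window)
    if aligned.shape[0] == 0:
        return None
    avg = aligned.mean(axis=0)
    pre_frames = window[0]

    def rel_mean(window_ms):
        k = window_frames(window_ms, frame_rate, closed="left")
        return float(avg[pre_frames + k].mean())

    baseline = rel_mean(LICK_BASELINE_MS)
    return LickTriggeredResult(
        average=avg,
        pre_frames=pre_frames,
        pre_value=rel_mean(LICK_PRE_MS) - baseline,
        post_value=rel_mean(LICK_POST_MS) - baseline,
        n_trials=aligned.shape[0],
    )


def aggregate_by_mouse(
    values: pd.DataFrame,
    value_cols: Sequence[str] = ("early", "late", "very_late", "peak"),
) -> pd.DataFrame:
    """Per-mouse, per-class means of per-neuron epoch values.

    ``values`` must carry one row per neuron with columns ``mouse`` and
    ``class`` plus the value columns.  Missing mouse or class labels
    raise; a mouse lacking neurons of one class is simply absent from
    that (mouse, class) cell, and paired across-mice tests must handle
    the gap (a warning is emitted).
    """
    required = {"mouse", "class"} | set(value_cols)
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if values["mouse"].isna().any() or values["class"].isna().any():
        raise ValueError("every neuron needs a mouse and class label")
    out = (
        values.groupby(["mouse", "class"])[list(value_cols)]
        .mean()
        .reset_index()
    )
    classes = values["class"].unique()
    for mouse in values["mouse"].unique():
        present = set(out.loc[out["mouse"] == mouse, "class"])
        for cls in classes:
            if cls not in present:
                warnings.warn(
                    f"mouse {mouse} has no {cls} neurons; excluded from "
                    "paired tests",
                    stacklevel=2,
                )
    return out
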