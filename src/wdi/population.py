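"""Pairwise spontaneous cross-correlations, cross-day stability, and
Wilcoxon group comparisons.

Spontaneous coupling between simultaneously imaged neurons is measured
on correct-rejection trials (no stimulus, no lick): per ROI, the ΔF/F
segments of all correct-rejection trials are concatenated, the ROI's
mean over those segments is subtracted, and the cross-correlogram is
computed for each pair.  With the default ``"coeff"`` normalization each
trace's zero-lag autocorrelation is 1, so zero-lag values are
correlation coefficients in [-1, 1]; ``"none"`` gives the raw
(unnormalized) sliding dot product for strict comparison against
MATLAB's ``xcorr`` default.

Cross-day stability is the ordinary least-squares fit of one day's peak
responses on another day's, summarized by slope, intercept and R².
Group comparisons use the Wilcoxon rank-sum test for unpaired
(per-neuron) data and the Wilcoxon signed-rank test for paired
(per-mouse) data; no multiple-testing correction is applied — p-values
are reported raw.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal, stats

__all__ = [
    "PairCorrelation",
    "CrossCorrSet",
    "StabilityResult",
    "pairwise_crosscorr",
    "group_crosscorr",
    "stability_r2",
    "compare_groups",
    "pair_class",
]


def pair_class(label_i: str, label_j: str) -> str:
    """Unordered pair class: S2p-S2p, S2p-M1p or M1p-M1p."""
    order = {"S2p": 0, "M1p": 1, "unlabeled": 2}
    a, b = sorted((label_i, label_j), key=lambda s: order.get(s, 3))
    return f"{a}-{b}"


@dataclass
class PairCorrelation:
    roi_i: int
    roi_j: int
    pair_class: str
    lags: np.ndarray  # frames, -max_lag .. +max_lag
    correlogram: np.ndarray
    zero_lag: float
    mouse: str | None = None
    valid: bool = True


@dataclass
class CrossCorrSet:
    """Cross-correlograms of all ROI pairs of one session."""

    pairs: list[PairCorrelation]
    max_lag: int
    normalization: str

    def by_class(self) -> dict[str, list[PairCorrelation]]:
        out: dict[str, list[PairCorrelation]] = {}
        for p in self.pairs:
            out.setdefault(p.pair_class, []).append(p)
        return out


def _xcorr(x: np.ndarray, y: np.ndarray, max_lag: int,
           normalization: str) -> np.ndarray:
    """Cross-correlation of two mean-subtracted traces over ±max_lag.

    Sign convention: a positive lag means ``y`` lags (is delayed
    relative to) ``x`` — for ``y[t] = x[t - d]`` the correlogram peaks at
    lag ``+d``.
    """
    full = signal.correlate(y, x, mode="full", method="auto")
    mid = len(x) - 1
    c = full[mid - max_lag : mid + max_lag + 1]
    if normalization == "coeff":
        denom = np.sqrt(np.dot(x, x) * np.dot(y, y))
        c = c / denom if denom > 0 else np.full_like(c, np.nan)
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return c


def pairwise_crosscorr(
    traces: np.ndarray,
    class_labels: Sequence[str],
    segments: Sequence[tuple[int, int]] | None = None,
    max_lag: int = 30,
    normalization: str = "coeff",
    roi_ids: Sequence[int] | None = None,
    mouse: str | None = None,
) -> CrossCorrSet:
    """Zero-lag cross-correlation structure of spontaneous activity.

    Parameters
    ----------
    traces : (n_rois, T) array
        ΔF/F traces (typically the full session).
    segments : list of (start, stop) frame pairs, optional
        Correct-rejection trial segments; they are concatenated per ROI
        before the per-ROI mean across trials is subtracted.  ``None``
        uses the whole trace.
    max_lag : int
        Correlogram half-width in frames.
    normalization : {"coeff", "none"}
        ``"coeff"`` scales each pair so a trace's zero-lag
        autocorrelation is 1.

    A zero-variance trace makes every pair involving it undefined
    (``valid=False``, NaN values) rather than raising.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n = traces.shape[0]
    if n < 2:
        raise ValueError("at least two ROIs are required")
    if len(class_labels) != n:
        raise ValueError("one class label per ROI is required")
    if roi_ids is None:
        roi_ids = list(range(n))
    if segments is not None:
        parts = [traces[:, a:b] for a, b in segments]
        if not parts:
            raise ValueError("no segments supplied")
        cat = np.concatenate(parts, axis=1)
    else:
        cat = traces
    centered = cat - cat.mean(axis=1, keepdims=True)
    sds = centered.std(axis=1)
    lags = np.arange(-max_lag, max_lag + 1)
    pairs = []
    for i, j in itertools.combinations(range(n), 2):
        pc = pair_class(class_labels[i], class_labels[j])
        if sds[i] == 0 or sds[j] == 0:
            pairs.append(
                PairCorrelation(
                    roi_i=roi_ids[i], roi_j=roi_ids[j], pair_class=pc,
                    lags=lags, correlogram=np.full(len(lags), np.nan),
                    zero_lag=np.nan, mouse=mouse, valid=False,
                )
            )
            continue
        c = _xcorr(centered[i], centered[j], max_lag, normalization)
        pairs.append(
            PairCorrelation(
                roi_i=roi_ids[i], roi_j=roi_ids[j], pair_class=pc,
                lags=lags, correlogram=c, zero_lag=float(c[max_lag]),
                mouse=mouse, valid=True,
            )
        )
    return CrossCorrSet(pairs=pairs, max_lag=max_lag,
                        normalization=normalization)


def group_crosscorr(
    xcorr_set: CrossCorrSet,
    by: str = "pair",
) -> dict[str, tuple[float, float, int]]:
    """Per-class zero-lag mean ± sd.

    ``by="pair"`` pools all valid pairs of a class; ``by="mouse"``
    averages within each mouse first and reports the mean and sd of the
    per-mouse means.  Classes with no valid pairs are omitted.
    """
    out: dict[str, tuple[float, float, int]] = {}
    for cls, plist in xcorr_set.by_class().items():
        valid = [p for p in plist if p.valid]
        if not valid:
            continue
        if by == "pair":
            vals = np.array([p.zero_lag for p in valid])
        elif by == "mouse":
            mice: dict[str, list[float]] = {}
            for p in valid:
                mice.setdefault(p.mouse, []).append(p.zero_lag)
            vals = np.array([np.mean(v) for v in mice.values()])
        else:
            raise ValueError("by must be 'pair' or 'mouse'")
        out[cls] = (float(vals.mean()), float(vals.std(ddof=0)), len(vals))
    return out


@dataclass
class StabilityResult:
    """OLS fit of day-j responses on day-i responses for one cell class."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def stability_r2(
    values_day_i: np.ndarray,
    values_day_j: np.ndarray,
) -> StabilityResult:
    """Least-squares linear fit of one day's responses on another's.

    Both arrays must hold the same ROIs in the same order (n ≥ 3).
    R² = 1 - SS_res/SS_tot of the fit of day j on day i.  Zero variance
    on day i leaves the fit undefined and raises ``ValueError``.
    """
    x = np.asarray(values_day_i, dtype=float)
    y = np.asarray(values_day_j, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("day vectors must be 1-D and matched")
    if len(x) < 3:
        raise ValueError("need at least 3 ROIs for a stability fit")
    if x.std() == 0:
        raise ValueError("zero variance on the reference day; fit undefined")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return StabilityResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        n=len(x),
    )


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    paired: bool = False,
) -> dict:
    """Wilcoxon comparison of two groups (two-sided).

    Unpaired data (per-neuron comparisons) use the rank-sum test;
    paired data (per-mouse comparisons, matched ordering) use the
    signed-rank test with the exact null distribution at small n.
    Returns a dict with ``statistic``, ``p_value``, ``test`` and
    ``method`` (exact vs. asymptotic), so small-sample caveats are
    visible to the caller.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired comparison requires matched samples")
        d = a - b
        if np.all(d == 0):
            return {"statistic": 0.0, "p_value": 1.0,
                    "test": "wilcoxon_signed_rank", "method": "degenerate"}
        method = "exact" if len(d) <= 25 and not np.any(d == 0) else "auto"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
        used = method if method != "auto" else "approx"
        return {"statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "test": "wilcoxon_signed_rank", "method": used}
    res = stats.ranksums(a, b, alternative="two-sided")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "test": "wilcoxon_rank_sum", "method": "asymptotic"}
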