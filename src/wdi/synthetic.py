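"""Ground-truthed synthetic sessions for the detection-task pipeline.

This module simulates everything the analysis consumes: a behavioral
session (trial sequence with whisker/auditory/catch trials, reaction
times, spontaneous licks and quiet-window aborts), per-neuron ΔF/F
traces with GCaMP6f-like kernel dynamics, and optionally a small rendered
movie with neuropil contamination, rigid frame-to-frame motion and shot
noise.  Every stochastic choice flows from a single seeded generator, so
a ``SimParams`` value fully determines the output, and a ``GroundTruth``
record carries the latent quantities (class labels, evoked amplitudes,
pre-lick ramps, motion shifts, contamination gain) that downstream
stages are expected to recover.

The task structure mirrors the behavioral protocol the analysis targets:
stimuli at random 11–14 s inter-stimulus intervals, 30–40% catch trials,
a 3 s pre-stimulus quiet window that aborts the trial when licked in,
and a 1 s reward window.  Projection-class structure is built in: cells
labeled S2p respond with larger evoked amplitudes than M1p cells, carry
a pre-lick activity ramp, and share a slow common input that induces
pairwise correlations during spontaneous activity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .behavior import Stimulus, TrialRecord, classify_trial, TrialType
from .traces import RoiMask, check_disjoint

__all__ = [
    "SimParams",
    "GroundTruth",
    "SessionBehavior",
    "generate_session",
    "spikes_to_fluorescence",
    "simulate_dff",
    "layout_rois",
    "render_movie",
]


@dataclass
class SimParams:
    """Parameters of a simulated session.

    Defaults reproduce the task statistics of the behavioral protocol
    (inter-stimulus intervals 11–14 s, 35% catch trials, 3 s quiet
    window, 1 s reward window, expert-level hit and false-alarm rates,
    modality-specific reaction times) and literature-typical GCaMP6f
    kinetics (rise 50 ms, decay 400 ms) at 30 Hz.
    """

    n_s2p: int = 30
    n_m1p: int = 30
    frame_rate: float = 30.0
    session_length: float = 600.0
    isi_range: tuple[float, float] = (11.0, 14.0)
    catch_prob: float = 0.35
    quiet_window: float = 3.0
    reward_window: float = 1.0
    p_hit_whisker: float = 0.81
    p_hit_auditory: float = 0.77
    fa_rate: float = 0.046
    rt_whisker_ms: tuple[float, float] = (240.0, 74.0)
    rt_auditory_ms: tuple[float, float] = (195.0, 56.0)
    rt_fa_ms: tuple[float, float] = (537.0, 75.0)
    spont_lick_rate_hz: float = 0.01
    amp_s2p: float = 0.15
    amp_m1p: float = 0.05
    #: evoked-amplitude scaling per trial outcome, relative to the class
    #: amplitude (whisker hit = 1); misses evoke weaker responses and the
    #: auditory stimulus evokes a smaller response than whisker deflection.
    evoked_scale: dict = field(
        default_factory=lambda: {
            "WHIT": 1.0, "WMISS": 0.5, "AHIT": 0.6, "AMISS": 0.3,
            "FA": 0.0, "CR": 0.0,
        }
    )
    amp_cv: float = 0.25  # per-neuron lognormal amplitude variability
    prelick_ramp_s2p: float = 0.2  # ΔF/F per second, over ramp_duration_s
    ramp_duration_s: float = 0.5
    common_input_weight_s2p: float = 0.033
    common_input_weight_m1p: float = 0.01
    common_input_tau_s: float = 0.3
    kernel_rise_ms: float = 50.0
    kernel_decay_ms: float = 400.0
    noise_sd: float = 0.05
    neuropil_gain: float = 0.7
    motion_sd_px: float = 1.0
    shot_noise: bool = True
    fov_shape: tuple[int, int] = (128, 128)
    px_size_um: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("catch_prob", "p_hit_whisker", "p_hit_auditory",
                     "fa_rate", "neuropil_gain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not self.isi_range[0] < self.isi_range[1]:
            raise ValueError("isi_range low must be < high")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.kernel_rise_ms <= 0 or self.kernel_decay_ms <= 0:
            raise ValueError("kernel constants must be positive")

    @property
    def n_neurons(self) -> int:
        return self.n_s2p + self.n_m1p

    @property
    def n_frames(self) -> int:
        return int(round(self.session_length * self.frame_rate))

    def _latent_corr(self, w: float) -> float:
        return w**2 / (w**2 + self.noise_sd**2) if self.noise_sd > 0 else 1.0

    @property
    def latent_corr_s2p(self) -> float:
        """Expected zero-lag correlation between S2p pairs at rest."""
        return self._latent_corr(self.common_input_weight_s2p)

    @property
    def latent_corr_m1p(self) -> float:
        """Expected zero-lag correlation between M1p pairs at rest."""
        return self._latent_corr(self.common_input_weight_m1p)


@dataclass
class GroundTruth:
    """Latent quantities of a simulated session, one record per neuron."""

    class_labels: list[str]
    evoked_amp: dict  # trial type -> (n_neurons,) ΔF/F amplitudes
    prelick_ramp: np.ndarray  # (n_neurons,) ΔF/F per s
    latent_corr_s2p: float
    latent_corr_m1p: float
    neuropil_coef: float
    negative_amp: np.ndarray  # flags: any negative evoked amplitude
    motion_shifts: np.ndarray | None = None  # (T, 2) (d_row, d_col) px
    clean_dff: np.ndarray | None = None  # (n, T) noise-free ΔF/F

    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_labels": self.class_labels,
            "evoked_amp": {k: v.tolist() for k, v in self.evoked_amp.items()},
            "prelick_ramp": self.prelick_ramp.tolist(),
            "latent_corr_s2p": self.latent_corr_s2p,
            "latent_corr_m1p": self.latent_corr_m1p,
            "neuropil_coef": self.neuropil_coef,
            "negative_amp": self.negative_amp.astype(bool).tolist(),
            "motion_shifts": (
                None if self.motion_shifts is None
                else self.motion_shifts.tolist()
            ),
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class SessionBehavior:
    """Trial sequence of one simulated session."""

    trials: list[TrialRecord]
    session_length: float
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return int(round(self.session_length * self.frame_rate))

    def stim_frames(self) -> np.ndarray:
        return np.array(
            [int(np.floor(t.stim_time * self.frame_rate))
             for t in self.trials]
        )


def _draw_rt(rng: np.random.Generator, mean_ms: float, sd_ms: float,
             reward_window: float) -> float:
    """Reaction time in seconds, truncated to the reward window."""
    rt = rng.normal(mean_ms, sd_ms) / 1000.0
    return float(np.clip(rt, 0.03, reward_window))


def generate_session(params: SimParams) -> tuple[SessionBehavior, GroundTruth]:
    """Simulate one behavioral session and its neuron-level ground truth.

    Stimulus (or virtual-stimulus) times are placed at uniform random
    inter-stimulus intervals from ``params.isi_range``; each trial is a
    catch trial with probability ``catch_prob``, otherwise whisker or
    auditory with equal probability.  Hits occur with the per-modality
    hit probability and carry a Gaussian reaction-time lick; catch trials
    become false alarms with probability ``fa_rate``.  A homogeneous
    Poisson process of spontaneous licks covers the quiet window, so a
    fraction of trials are aborted.  The output is fully determined by
    ``params`` (including the seed).
    """
    rng = np.random.default_rng(params.seed)
    margin = 5.0  # post-stimulus span kept inside the session
    trials: list[TrialRecord] = []
    t = max(params.quiet_window, 60.0 / params.frame_rate)
    t += rng.uniform(*params.isi_range)
    if t + margin > params.session_length:
        raise ValueError(
            f"session_length {params.session_length} s too short for a "
            "single trial"
        )
    trial_id = 0
    while t + margin <= params.session_length:
        u = rng.uniform()
        if u < params.catch_prob:
            stim = Stimulus.CATCH
        elif u < params.catch_prob + (1 - params.catch_prob) / 2:
            stim = Stimulus.WHISKER
        else:
            stim = Stimulus.AUDITORY
        licks: list[float] = []
        # spontaneous licks during the quiet window (possible aborts)
        n_spont = rng.poisson(params.spont_lick_rate_hz * params.quiet_window)
        licks += list(
            t - rng.uniform(0, params.quiet_window, size=n_spont)
        )
        # response lick
        if stim is Stimulus.WHISKER and rng.uniform() < params.p_hit_whisker:
            licks.append(t + _draw_rt(rng, *params.rt_whisker_ms,
                                      params.reward_window))
        elif (stim is Stimulus.AUDITORY
              and rng.uniform() < params.p_hit_auditory):
            licks.append(t + _draw_rt(rng, *params.rt_auditory_ms,
                                      params.reward_window))
        elif stim is Stimulus.CATCH and rng.uniform() < params.fa_rate:
            licks.append(t + _draw_rt(rng, *params.rt_fa_ms,
                                      params.reward_window))
        trials.append(
            TrialRecord(
                trial_id=trial_id,
                stimulus=stim,
                stim_time=float(t),
                lick_times=tuple(sorted(licks)),
                quiet_window=params.quiet_window,
                reward_window=params.reward_window,
            )
        )
        trial_id += 1
        t += rng.uniform(*params.isi_range)

    # neuron-level ground truth
    labels = ["S2p"] * params.n_s2p + ["M1p"] * params.n_m1p
    base = np.where(
        np.array(labels) == "S2p", params.amp_s2p, params.amp_m1p
    )
    gain = rng.lognormal(
        mean=-0.5 * np.log(1 + params.amp_cv**2),
        sigma=np.sqrt(np.log(1 + params.amp_cv**2)),
        size=params.n_neurons,
    )
    evoked = {
        tt: base * gain * scale for tt, scale in params.evoked_scale.items()
    }
    ramp = np.where(
        np.array(labels) == "S2p", params.prelick_ramp_s2p, 0.0
    )
    neg = np.zeros(params.n_neurons, dtype=bool)
    for v in evoked.values():
        neg |= v < 0
    gt = GroundTruth(
        class_labels=labels,
        evoked_amp=evoked,
        prelick_ramp=ramp,
        latent_corr_s2p=params.latent_corr_s2p,
        latent_corr_m1p=params.latent_corr_m1p,
        neuropil_coef=params.neuropil_gain,
        negative_amp=neg,
    )
    behavior = SessionBehavior(
        trials=trials,
        session_length=params.session_length,
        frame_rate=params.frame_rate,
    )
    return behavior, gt


def _kernel(params: SimParams, n_frames: int) -> np.ndarray:
    """Difference-of-exponentials calcium kernel, peak-normalized to 1."""
    t = np.arange(n_frames) / params.frame_rate
    tr = params.kernel_rise_ms / 1000.0
    td = params.kernel_decay_ms / 1000.0
    h = np.exp(-t / td) - np.exp(-t / tr)
    peak = h.max()
    return h / peak if peak > 0 else h


def spikes_to_fluorescence(
    event_times: Sequence[float],
    amplitudes: Sequence[float],
    params: SimParams,
    n_frames: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forward model: event train -> ΔF/F trace sampled at the frame rate.

    Each event contributes a causal difference-of-exponentials transient
    (rise ``kernel_rise_ms``, decay ``kernel_decay_ms``) with the stated
    peak ΔF/F amplitude; white noise of sd ``noise_sd`` is added on top.
    Negative amplitudes are allowed (suppression) and surface in the
    ground truth's ``negative_amp`` flags.
    """
    if n_frames is None:
        n_frames = params.n_frames
    event_times = list(event_times)
    amplitudes = list(amplitudes)
    if len(event_times) != len(amplitudes):
        raise ValueError("event_times and amplitudes must match in length")
    trace = np.zeros(n_frames)
    if event_times:
        if min(event_times) < 0 or max(event_times) * params.frame_rate >= n_frames:
            raise ValueError("event times must lie within the session")
        kern = _kernel(params, n_frames)
        for te, amp in zip(event_times, amplitudes):
            k0 = int(np.floor(te * params.frame_rate))
            n = n_frames - k0
            trace[k0:] += amp * kern[:n]
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        trace = trace + rng.normal(0.0, params.noise_sd, size=n_frames)
    return trace


def _lowpass_noise(rng: np.random.Generator, n: int, tau_s: float,
                   frame_rate: float) -> np.ndarray:
    """Unit-variance AR(1) (exponentially filtered white) noise."""
    a = float(np.exp(-1.0 / (tau_s * frame_rate)))
    w = rng.normal(size=n)
    z = np.empty(n)
    z[0] = w[0]
    for i in range(1, n):
        z[i] = a * z[i - 1] + np.sqrt(1 - a**2) * w[i]
    sd = z.std()
    return z / sd if sd > 0 else z


def simulate_dff(
    behavior: SessionBehavior,
    gt: GroundTruth,
    params: SimParams,
) -> np.ndarray:
    """Noise-free-plus-noise ΔF/F traces, (n_neurons, n_frames).

    Per neuron, non-aborted stimulus trials contribute an evoked calcium
    transient with the ground-truth amplitude for the trial's behavioral
    category; S2p cells additionally ramp up linearly over the
    ``ramp_duration_s`` before the first lick of hit and false-alarm
    trials.  S2p cells share a slow common input of weight
    ``common_input_weight_s2p``; independent white noise of sd
    ``noise_sd`` is added to every cell.  The noise-free traces are
    stored on the ground-truth record (``clean_dff``).
    """
    rng = np.random.default_rng(params.seed + 1)
    n_frames = behavior.n_frames
    fr = params.frame_rate
    n = len(gt.class_labels)
    clean = np.zeros((n, n_frames))
    kern = _kernel(params, n_frames)

    per_trial = [
        (tr, classify_trial(tr)) for tr in behavior.trials
    ]
    tgrid = np.arange(n_frames) / fr
    for i in range(n):
        tr_events: list[tuple[int, float]] = []
        for tr, cls in per_trial:
            if cls is TrialType.ABORTED:
                continue
            amp = gt.evoked_amp.get(cls.value, np.zeros(n))[i]
            if amp != 0 and tr.stimulus is not Stimulus.CATCH:
                k0 = int(np.floor(tr.stim_time * fr))
                tr_events.append((k0, amp))
            # pre-lick ramp for lick trials
            if gt.prelick_ramp[i] != 0 and cls in (
                TrialType.WHIT, TrialType.AHIT, TrialType.FA
            ):
                in_win = [t for t in tr.lick_times
                          if tr.stim_time < t
                          <= tr.stim_time + tr.reward_window]
                t_lick = min(in_win)
                ramp = np.clip(
                    (tgrid - (t_lick - params.ramp_duration_s))
                    * gt.prelick_ramp[i],
                    0.0, gt.prelick_ramp[i] * params.ramp_duration_s,
                )
                # decay back after the lick with the kernel decay constant
                td = params.kernel_decay_ms / 1000.0
                post = tgrid > t_lick
                ramp[post] = (
                    gt.prelick_ramp[i] * params.ramp_duration_s
                    * np.exp(-(tgrid[post] - t_lick) / td)
                )
                clean[i] += ramp
        for k0, amp in tr_events:
            m = n_frames - k0
            clean[i, k0:] += amp * kern[:m]

    labels = np.array(gt.class_labels)
    weights = {
        "S2p": params.common_input_weight_s2p,
        "M1p": params.common_input_weight_m1p,
    }
    if any(w > 0 for w in weights.values()):
        z = _lowpass_noise(rng, n_frames, params.common_input_tau_s, fr)
        for cls, w in weights.items():
            if w > 0 and (labels == cls).any():
                clean[labels == cls] += w * z

    gt.clean_dff = clean.copy()
    dff = clean + rng.normal(0.0, params.noise_sd, size=clean.shape)
    return dff


def layout_rois(
    n_neurons: int,
    labels: Sequence[str],
    fov_shape: tuple[int, int] = (128, 128),
    soma_radius_px: int = 3,
    spacing_px: int = 12,
    margin_px: int = 10,
) -> list[RoiMask]:
    """Place disjoint disk-shaped somata on a grid inside the field of view."""
    H, W = fov_shape
    centers = []
    r = margin_px
    while r <= H - margin_px and len(centers) < n_neurons:
        c = margin_px
        while c <= W - margin_px and len(centers) < n_neurons:
            centers.append((r, c))
            c += spacing_px
        r += spacing_px
    if len(centers) < n_neurons:
        raise ValueError(
            f"field of view {fov_shape} too small for {n_neurons} ROIs "
            f"at spacing {spacing_px}"
        )
    rows, cols = np.mgrid[0:H, 0:W]
    masks = []
    for i, (cr, cc) in enumerate(centers):
        disk = np.hypot(rows - cr, cols - cc) <= soma_radius_px
        masks.append(
            RoiMask(roi_id=i, pixels=np.argwhere(disk),
                    class_label=labels[i])
        )
    check_disjoint(masks)
    return masks


def render_movie(
    traces: np.ndarray,
    rois: Sequence[RoiMask],
    params: SimParams,
    gt: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
    shifts: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render ΔF/F traces into a movie with contamination, motion, noise.

    Each frame is a static textured baseline, plus each soma's brightness
    modulated by its trace, plus a spatially uniform neuropil signal
    scaled by ``neuropil_gain`` added everywhere (contaminating the
    somata), rigidly shifted by a per-frame Gaussian displacement of sd
    ``motion_sd_px``, with Poisson shot noise when ``shot_noise`` is set.
    Returns ``(movie, shifts)``; shifts are also written into ``gt``.
    A ``shifts`` array (T, 2) may be supplied to override the random
    draw — e.g. zeros to render a motion-free reference, or a constant
    displacement for round-trip checks.

    Raises ``ValueError`` when ROI footprints overlap (somata are
    disjoint by construction).
    """
    check_disjoint(rois)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if len(rois) != traces.shape[0]:
        raise ValueError("one trace per ROI is required")
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    H, W = params.fov_shape
    T = traces.shape[1]
    from scipy import ndimage

    base = 100.0 + 20.0 * ndimage.gaussian_filter(
        rng.normal(size=(H, W)), sigma=4.0
    )
    soma_gain = 50.0
    masks_img = [m.to_bool_image((H, W)) for m in rois]
    # slow global neuropil signal; its stochastic part scales with
    # noise_sd so a fully noise-free render is time-invariant
    npil = _lowpass_noise(rng, T, 0.5, params.frame_rate) \
        * 2.0 * params.noise_sd + traces.mean(axis=0) * 0.5
    if shifts is not None:
        shifts = np.asarray(shifts, dtype=float)
        if shifts.shape != (T, 2):
            raise ValueError("shifts must have shape (n_frames, 2)")
    elif params.motion_sd_px > 0:
        shifts = rng.normal(0.0, params.motion_sd_px, size=(T, 2))
    else:
        shifts = np.zeros((T, 2))
    movie = np.empty((T, H, W), dtype=float)
    for t in range(T):
        frame = base + params.neuropil_gain * soma_gain * npil[t]
        for img, trace in zip(masks_img, traces):
            frame = frame + img * soma_gain * (1.0 + trace[t])
        if shifts[t, 0] != 0 or shifts[t, 1] != 0:
            frame = ndimage.shift(frame, shifts[t], order=1,
                                  mode="nearest")
        if params.shot_noise:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
        movie[t] = frame
    if gt is not None:
        gt.motion_shifts = shifts
    return movie, shifts
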