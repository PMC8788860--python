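"""Go/no-go trial classification and behavioral performance metrics.

A trial in the whisker/auditory detection task is defined by its stimulus
(whisker deflection, auditory tone, or no stimulus on catch trials), the
stimulus time, and the animal's lick times.  Each trial falls into exactly
one of six behavioral categories -- whisker hit/miss, auditory hit/miss,
false alarm, correct rejection -- plus an explicit ABORTED label for trials
in which the animal licked during the pre-stimulus quiet window.

Conventions
-----------
* The reward window is half-open on the left: a lick counts as a response
  if it lies in ``(stim_time, stim_time + reward_window]``.  A lick exactly
  at stimulus onset cannot be stimulus-driven and does not count.
* The quiet window is ``[stim_time - quiet_window, stim_time)``; any lick
  inside it aborts the trial regardless of later events.
* Catch trials carry a *virtual* stimulus time (where a stimulus would have
  been delivered) against which false-alarm licks are scored.
* Aborted trials are excluded from every performance denominator.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stimulus",
    "TrialType",
    "TrialRecord",
    "PerformanceSummary",
    "classify_trial",
    "session_performance",
    "block_performance",
    "read_trials_csv",
    "write_trials_csv",
]


class Stimulus(str, enum.Enum):
    WHISKER = "whisker"
    AUDITORY = "auditory"
    CATCH = "catch"


class TrialType(str, enum.Enum):
    WHIT = "WHIT"
    WMISS = "WMISS"
    AHIT = "AHIT"
    AMISS = "AMISS"
    FA = "FA"
    CR = "CR"
    ABORTED = "ABORTED"


#: Trial types whose reaction time is defined (first lick in the window).
_LICK_TYPES = {TrialType.WHIT, TrialType.AHIT, TrialType.FA}


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial.

    Parameters
    ----------
    trial_id : int
        Index of the trial within the session.
    stimulus : Stimulus
        Delivered stimulus; ``CATCH`` for no-stimulus trials.
    stim_time : float
        Stimulus time in seconds from session start.  For catch trials this
        is the virtual stimulus time from the behavior log.
    lick_times : tuple of float
        All lick times of the trial, seconds, ascending.
    quiet_window : float
        Pre-stimulus no-lick period in seconds (default 3 s).
    reward_window : float
        Response window after the stimulus in seconds (default 1 s).
    particle_on : bool
        Whether the magnetic particle was attached to the whisker; in
        particle-off control blocks the magnetic pulse alone is delivered.
    """

    trial_id: int
    stimulus: Stimulus
    stim_time: float
    lick_times: tuple[float, ...] = ()
    quiet_window: float = 3.0
    reward_window: float = 1.0
    particle_on: bool = True

    def __post_init__(self):
        licks = tuple(float(t) for t in self.lick_times)
        if any(b < a for a, b in zip(licks, licks[1:])):
            raise ValueError("lick_times must be sorted ascending")
        object.__setattr__(self, "lick_times", licks)
        object.__setattr__(self, "stimulus", Stimulus(self.stimulus))
        if self.stim_time < self.quiet_window:
            raise ValueError(
                f"stim_time {self.stim_time} precedes the quiet window "
                f"({self.quiet_window} s)"
            )

    @property
    def aborted(self) -> bool:
        return classify_trial(self) is TrialType.ABORTED


def classify_trial(trial: TrialRecord) -> TrialType:
    """Classify a trial into one of the six task categories or ABORTED.

    A lick in the quiet window aborts the trial.  Otherwise a lick inside
    ``(stim_time, stim_time + reward_window]`` makes a stimulus trial a hit
    and a catch trial a false alarm; the absence of such a lick makes a
    stimulus trial a miss and a catch trial a correct rejection.  Licks
    after the reward window never change the outcome.
    """
    t0 = trial.stim_time
    for t in trial.lick_times:
        if t0 - trial.quiet_window <= t < t0:
            return TrialType.ABORTED
    responded = any(
        t0 < t <= t0 + trial.reward_window for t in trial.lick_times
    )
    if trial.stimulus is Stimulus.WHISKER:
        return TrialType.WHIT if responded else TrialType.WMISS
    if trial.stimulus is Stimulus.AUDITORY:
        return TrialType.AHIT if responded else TrialType.AMISS
    return TrialType.FA if responded else TrialType.CR


def reaction_time(trial: TrialRecord) -> float | None:
    """First-lick latency from the (virtual) stimulus time, in seconds.

    Defined only for hit and false-alarm trials; ``None`` otherwise.
    """
    if classify_trial(trial) not in _LICK_TYPES:
        return None
    t0 = trial.stim_time
    in_window = [
        t - t0 for t in trial.lick_times if t0 < t <= t0 + trial.reward_window
    ]
    return min(in_window)


@dataclass
class PerformanceSummary:
    """Session-level behavioral performance.

    Rates are percentages over non-aborted trials of the relevant type;
    a rate whose denominator is empty is ``None`` (undefined), never 0.
    Reaction times are in milliseconds (mean and SD over first-lick
    latencies of hit / false-alarm trials).
    """

    n_trials: int
    counts: dict[str, int]
    whisker_hit_rate: float | None
    auditory_hit_rate: float | None
    fa_rate: float | None
    rt_whisker_ms: tuple[float, float] | None
    rt_auditory_ms: tuple[float, float] | None
    rt_fa_ms: tuple[float, float] | None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _rate(hits: int, misses: int) -> float | None:
    n = hits + misses
    return None if n == 0 else 100.0 * hits / n


def _rt_stats(rts_s: Sequence[float]) -> tuple[float, float] | None:
    if not rts_s:
        return None
    arr = np.asarray(rts_s) * 1000.0
    return float(arr.mean()), float(arr.std(ddof=0))


def session_performance(trials: Iterable[TrialRecord]) -> PerformanceSummary:
    """Compute hit rates, false-alarm rate and reaction times for a session."""
    trials = list(trials)
    counts: dict[str, int] = {t.value: 0 for t in TrialType}
    rts: dict[TrialType, list[float]] = {t: [] for t in _LICK_TYPES}
    for tr in trials:
        cls = classify_trial(tr)
        counts[cls.value] += 1
        if cls in _LICK_TYPES:
            rts[cls].append(reaction_time(tr))
    return PerformanceSummary(
        n_trials=len(trials),
        counts=counts,
        whisker_hit_rate=_rate(counts["WHIT"], counts["WMISS"]),
        auditory_hit_rate=_rate(counts["AHIT"], counts["AMISS"]),
        fa_rate=_rate(counts["FA"], counts["CR"]),
        rt_whisker_ms=_rt_stats(rts[TrialType.WHIT]),
        rt_auditory_ms=_rt_stats(rts[TrialType.AHIT]),
        rt_fa_ms=_rt_stats(rts[TrialType.FA]),
    )


def block_performance(
    trials: Sequence[TrialRecord],
) -> dict[str, PerformanceSummary]:
    """Split a session into contiguous particle-on / particle-off blocks.

    Returns a dict with keys ``"particle_on"`` and (if present)
    ``"particle_off"``.  The particle-off whisker "hit rate" measures
    licking to the magnetic pulse alone.  Each flag value must form a
    single contiguous run; interleaved flags raise ``ValueError``.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("empty session")
    flags = [tr.particle_on for tr in trials]
    n_transitions = sum(a != b for a, b in zip(flags, flags[1:]))
    if n_transitions > 1:
        raise ValueError(
            "particle_on blocks must be contiguous "
            f"(found {n_transitions + 1} blocks)"
        )
    out: dict[str, PerformanceSummary] = {}
    for flag, key in ((True, "particle_on"), (False, "particle_off")):
        block = [tr for tr in trials if tr.particle_on is flag]
        if block:
            out[key] = session_performance(block)
    return out


# ---------------------------------------------------------------------------
# CSV trial-table I/O (schema shared with the synthetic session generator)

_CSV_COLUMNS = [
    "trial_id",
    "type_intended",
    "stim_time_s",
    "lick_times_s",
    "aborted",
    "particle_on",
]


def write_trials_csv(trials: Sequence[TrialRecord], path: str | Path) -> None:
    rows = []
    for tr in trials:
        rows.append(
            {
                "trial_id": tr.trial_id,
                "type_intended": tr.stimulus.value,
                "stim_time_s": tr.stim_time,
                "lick_times_s": ";".join(f"{t:.6g}" for t in tr.lick_times),
                "aborted": int(tr.aborted),
                "particle_on": int(tr.particle_on),
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_trials_csv(
    path: str | Path,
    quiet_window: float = 3.0,
    reward_window: float = 1.0,
) -> list[TrialRecord]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"trial table {path} lacks columns {sorted(missing)}")
    trials = []
    for _, row in df.iterrows():
        raw = row["lick_times_s"]
        licks = () if pd.isna(raw) or raw == "" else tuple(
            float(x) for x in str(raw).split(";")
        )
        trials.append(
            TrialRecord(
                trial_id=int(row["trial_id"]),
                stimulus=Stimulus(row["type_intended"]),
                stim_time=float(row["stim_time_s"]),
                lick_times=licks,
                quiet_window=quiet_window,
                reward_window=reward_window,
                particle_on=bool(row.get("particle_on", 1)),
            )
        )
    return trials
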