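"""Loader for an externally deposited dataset copy.

Maps a local directory of deposited intermediate data into the package's
trial-table and trace-set schemas.  The loader expects one directory per
session::

    deposit_root/
      session_name/
        trials.csv    # trial table (trial_id, type_intended, stim_time_s,
                      #              lick_times_s, aborted[, particle_on])
        traces.h5     # per-ROI groups with f_soma / f_corrected / dff
                      # datasets and frame_rate / a_neuropil attributes

Sessions live either in subdirectories or directly at the root (a single
session).  Anything else in the tree is reported, never silently
dropped; an unrecognized layout raises with the list of files found.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .behavior import TrialRecord, read_trials_csv
from .traces import DffTraceSet

__all__ = ["load_external_deposit"]

logger = logging.getLogger(__name__)


def _load_session(d: Path) -> tuple[list[TrialRecord], DffTraceSet]:
    trials = read_trials_csv(d / "trials.csv")
    traceset = DffTraceSet.from_hdf5(d / "traces.h5")
    extras = [
        p.name for p in d.iterdir()
        if p.name not in ("trials.csv", "traces.h5")
    ]
    if extras:
        logger.warning("session %s: unmapped files %s", d.name, extras)
    return trials, traceset


def load_external_deposit(
    path: str | Path,
) -> dict[str, tuple[list[TrialRecord], DffTraceSet]]:
    """Load a local copy of a deposited dataset into pipeline structures.

    Returns ``{session_name: (trials, trace_set)}``.  Raises
    ``FileNotFoundError`` for an absent path and ``ValueError`` (listing
    the files found) for a layout the loader does not recognize.
    """
    root = Path(path)
    if not root.exists():
        raise FileNotFoundError(f"deposit path {root} does not exist")
    if (root / "trials.csv").exists() and (root / "traces.h5").exists():
        return {root.name or "session": _load_session(root)}
    sessions = {}
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        if (d / "trials.csv").exists() and (d / "traces.h5").exists():
            sessions[d.name] = _load_session(d)
    if not sessions:
        found = sorted(str(p.relative_to(root)) for p in root.rglob("*"))
        raise ValueError(
            "unrecognized deposit layout: expected per-session "
            "trials.csv + traces.h5; found: " + ", ".join(found[:50])
        )
    return sessions
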