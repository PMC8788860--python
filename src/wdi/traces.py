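"""ROI fluorescence extraction, neuropil correction and ΔF/F.

The somatic fluorescence of a neuron is the per-frame mean over its ROI
pixels.  Out-of-focus neuropil contamination is estimated in a ~40 µm
radius disk around the ROI centroid, excluding all detected ROIs, and
removed as

    F_corrected = F_soma - a_neuropil * (F_neuropil - median(F_neuropil))

with contamination coefficient ``a_neuropil = 0.7`` by default.  The
median is taken over the full session trace, so a constant neuropil
signal leaves the somatic trace untouched.  Calcium signals are then
expressed as relative fluorescence change ΔF/F = (F - F0)/F0 where F0 is
the mean corrected fluorescence over the 60 frames (2 s at 30 Hz)
immediately preceding each trial's (possibly virtual) stimulus event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

__all__ = [
    "RoiMask",
    "DffTraceSet",
    "extract_trace",
    "build_neuropil_ring",
    "neuropil_correct",
    "compute_dff",
    "stim_frame",
    "write_rois_json",
    "read_rois_json",
]

DEFAULT_NEUROPIL_COEF = 0.7
DEFAULT_RING_RADIUS_UM = 40.0
DEFAULT_N_BASELINE = 60


@dataclass
class RoiMask:
    """A labeled set of pixels belonging to one neuron's soma.

    Pixels are (row, col) integer coordinates, origin at the top-left.
    ``class_label`` identifies the projection target of the neuron:
    ``"S2p"`` (projects to secondary somatosensory cortex), ``"M1p"``
    (projects to primary motor cortex) or ``"unlabeled"``.
    """

    roi_id: int
    pixels: np.ndarray  # (N, 2) int array of (row, col)
    class_label: str = "unlabeled"
    lost: bool = False  # set when a mask maps outside the frame

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=int).reshape(-1, 2)
        if px.shape[0] == 0 and not self.lost:
            raise ValueError(f"ROI {self.roi_id}: empty pixel set")
        self.pixels = px
        if self.class_label not in ("S2p", "M1p", "unlabeled"):
            raise ValueError(f"unknown class label {self.class_label!r}")

    @property
    def centroid(self) -> tuple[float, float]:
        r, c = self.pixels.mean(axis=0)
        return float(r), float(c)

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]

    def to_bool_image(self, shape: tuple[int, int]) -> np.ndarray:
        img = np.zeros(shape, dtype=bool)
        rows, cols = self.pixels[:, 0], self.pixels[:, 1]
        ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
        img[rows[ok], cols[ok]] = True
        return img

    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}


def check_disjoint(masks: Sequence[RoiMask]) -> None:
    """Raise if any two ROI masks share a pixel (somata are disjoint)."""
    seen: dict[tuple[int, int], int] = {}
    for m in masks:
        for p in m.pixel_set():
            if p in seen:
                raise ValueError(
                    f"ROIs {seen[p]} and {m.roi_id} overlap at pixel {p}"
                )
            seen[p] = m.roi_id


def extract_trace(movie: np.ndarray, mask: RoiMask) -> np.ndarray:
    """Per-frame arithmetic mean of the movie over the mask pixels.

    Parameters
    ----------
    movie : (T, H, W) array
    mask : RoiMask
        All pixels must lie within the frame.
    """
    frames = np.asarray(movie)
    if frames.ndim != 3:
        raise ValueError("movie must be a T x H x W stack")
    H, W = frames.shape[1:]
    rows, cols = mask.pixels[:, 0], mask.pixels[:, 1]
    if rows.min() < 0 or rows.max() >= H or cols.min() < 0 or cols.max() >= W:
        raise ValueError(f"ROI {mask.roi_id} extends outside the frame")
    return frames[:, rows, cols].mean(axis=1)


def build_neuropil_ring(
    mask: RoiMask,
    all_masks: Sequence[RoiMask],
    frame_shape: tuple[int, int],
    radius_um: float = DEFAULT_RING_RADIUS_UM,
    px_size_um: float = 1.0,
    inner_margin_px: float = 0.0,
) -> RoiMask:
    """Neuropil region: a disk around the ROI centroid minus all ROIs.

    The disk has radius ``radius_um`` (default 40 µm) centered on the
    target ROI's centroid; pixels belonging to *any* detected ROI
    (including the target soma itself) are excluded.  An optional inner
    exclusion margin widens the gap around the soma.

    Raises ``ValueError`` if the radius does not reach beyond the soma or
    if the resulting region is empty.
    """
    radius_px = radius_um / px_size_um
    cr, cc = mask.centroid
    d_soma = np.hypot(mask.pixels[:, 0] - cr, mask.pixels[:, 1] - cc)
    if radius_px < d_soma.max():
        raise ValueError(
            f"ring radius {radius_px:.1f} px smaller than soma extent "
            f"{d_soma.max():.1f} px for ROI {mask.roi_id}"
        )
    H, W = frame_shape
    rows, cols = np.mgrid[0:H, 0:W]
    dist = np.hypot(rows - cr, cols - cc)
    region = dist <= radius_px
    if inner_margin_px > 0:
        region &= dist > (d_soma.max() + inner_margin_px)
    for other in all_masks:
        region &= ~other.to_bool_image(frame_shape)
    if not region.any():
        raise ValueError(f"empty neuropil ring for ROI {mask.roi_id}")
    return RoiMask(
        roi_id=mask.roi_id,
        pixels=np.argwhere(region),
        class_label="unlabeled",
    )


def neuropil_correct(
    f_soma: np.ndarray,
    f_neuropil: np.ndarray,
    a_neuropil: float = DEFAULT_NEUROPIL_COEF,
) -> np.ndarray:
    """F_corrected = F_soma - a * (F_neuropil - median(F_neuropil)).

    The median is taken over the full (session-length) neuropil trace.
    With a constant neuropil trace, or ``a_neuropil = 0``, the somatic
    trace is returned unchanged.
    """
    f_soma = np.asarray(f_soma, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_soma.shape != f_neuropil.shape:
        raise ValueError(
            f"trace length mismatch: {f_soma.shape} vs {f_neuropil.shape}"
        )
    if not np.isfinite(a_neuropil):
        raise ValueError("a_neuropil must be finite")
    return f_soma - a_neuropil * (f_neuropil - np.median(f_neuropil))


def stim_frame(stim_time_s: float, frame_rate: float) -> int:
    """Frame index containing a stimulus time: frame k covers [k/fr, (k+1)/fr)."""
    return int(np.floor(stim_time_s * frame_rate))


def compute_dff(
    f_corrected: np.ndarray,
    trial_start_frame: int,
    n_frames: int | None = None,
    n_baseline: int = DEFAULT_N_BASELINE,
) -> np.ndarray | None:
    """Trial-local ΔF/F with F0 = mean over the pre-trial baseline frames.

    F0 is the mean of ``f_corrected`` over the ``n_baseline`` frames
    (default 60, i.e. 2 s at 30 Hz) immediately preceding
    ``trial_start_frame`` (the stimulus or virtual-stimulus frame).
    Returns ΔF/F for frames ``trial_start_frame .. trial_start_frame +
    n_frames`` (to end of trace if ``n_frames`` is None), or ``None`` when
    F0 <= 0, in which case the trial is invalid and must be excluded.
    """
    f = np.asarray(f_corrected, dtype=float)
    if trial_start_frame < n_baseline:
        raise ValueError(
            f"trial start frame {trial_start_frame} leaves fewer than "
            f"{n_baseline} baseline frames"
        )
    f0 = f[trial_start_frame - n_baseline : trial_start_frame].mean()
    if not np.isfinite(f0) or f0 <= 0:
        return None
    stop = len(f) if n_frames is None else trial_start_frame + n_frames
    return (f[trial_start_frame:stop] - f0) / f0


@dataclass
class DffTraceSet:
    """Per-ROI fluorescence traces for one session.

    All arrays are indexed (roi, frame).  ``dff`` is the *session-long*
    ΔF/F trace assembled trial-by-trial (frames outside any trial are
    NaN); per-trial views are produced by the event-analysis module.
    """

    roi_ids: list[int]
    class_labels: list[str]
    f_soma: np.ndarray
    f_neuropil: np.ndarray | None
    f_corrected: np.ndarray
    dff: np.ndarray
    frame_rate: float
    a_neuropil: float = DEFAULT_NEUROPIL_COEF
    invalid_trials: dict[int, list[int]] = field(default_factory=dict)

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def n_frames(self) -> int:
        return self.f_corrected.shape[1]

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as h5:
            h5.attrs["frame_rate"] = self.frame_rate
            h5.attrs["a_neuropil"] = self.a_neuropil
            for i, roi_id in enumerate(self.roi_ids):
                g = h5.create_group(f"roi_{roi_id:04d}")
                g.attrs["roi_id"] = roi_id
                g.attrs["class_label"] = self.class_labels[i]
                g.create_dataset("f_soma", data=self.f_soma[i])
                if self.f_neuropil is not None:
                    g.create_dataset("f_neuropil", data=self.f_neuropil[i])
                g.create_dataset("f_corrected", data=self.f_corrected[i])
                g.create_dataset("dff", data=self.dff[i])

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "DffTraceSet":
        with h5py.File(path, "r") as h5:
            keys = sorted(k for k in h5 if k.startswith("roi_"))
            roi_ids, labels, fs, fn, fc, dff = [], [], [], [], [], []
            has_np = all("f_neuropil" in h5[k] for k in keys)
            for k in keys:
                g = h5[k]
                roi_ids.append(int(g.attrs["roi_id"]))
                labels.append(str(g.attrs["class_label"]))
                fs.append(g["f_soma"][:])
                fc.append(g["f_corrected"][:])
                dff.append(g["dff"][:])
                if has_np:
                    fn.append(g["f_neuropil"][:])
            return cls(
                roi_ids=roi_ids,
                class_labels=labels,
                f_soma=np.array(fs),
                f_neuropil=np.array(fn) if has_np else None,
                f_corrected=np.array(fc),
                dff=np.array(dff),
                frame_rate=float(h5.attrs["frame_rate"]),
                a_neuropil=float(h5.attrs["a_neuropil"]),
            )


# ---------------------------------------------------------------------------
# ROI mask JSON I/O (run-length encoded rows)


def _rle_encode(mask: RoiMask) -> list[list[int]]:
    """Per-row runs [row, col_start, length] sorted by (row, col)."""
    runs = []
    order = np.lexsort((mask.pixels[:, 1], mask.pixels[:, 0]))
    px = mask.pixels[order]
    start = prev = None
    row0 = None
    for r, c in px:
        if row0 == r and c == prev + 1:
            prev = c
        else:
            if start is not None:
                runs.append([int(row0), int(start), int(prev - start + 1)])
            row0, start, prev = r, c, c
    if start is not None:
        runs.append([int(row0), int(start), int(prev - start + 1)])
    return runs


def write_rois_json(masks: Sequence[RoiMask], path: str | Path) -> None:
    payload = [
        {
            "roi_id": m.roi_id,
            "class_label": m.class_label,
            "runs": _rle_encode(m),
        }
        for m in masks
    ]
    Path(path).write_text(json.dumps(payload))


def read_rois_json(path: str | Path) -> list[RoiMask]:
    payload = json.loads(Path(path).read_text())
    masks = []
    for item in payload:
        pixels = []
        for row, col, length in item["runs"]:
            for c in range(col, col + length):
                pixels.append((row, c))
        masks.append(
            RoiMask(
                roi_id=int(item["roi_id"]),
                pixels=np.array(pixels),
                class_label=item.get("class_label", "unlabeled"),
            )
        )
    return masks
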