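"""Movie preprocessing: background subtraction, rigid motion correction,
reference images, and affine session-to-master registration.

Coordinate conventions (used everywhere in this package): pixel indices
are 0-based ``(row, col)`` with the origin at the top-left; shifts are
reported as ``(d_row, d_col)`` in pixels, the displacement of the frame
*relative to the reference* — a frame whose content sits 3 px lower than
the reference has shift ``(+3, 0)`` and is corrected by translating it by
``(-3, 0)``.  Pixels translated in from outside the frame are filled with
0, the background level after subtraction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .traces import RoiMask

__all__ = [
    "AffineTransform2D",
    "RegistrationError",
    "subtract_background",
    "estimate_rigid_shift",
    "correct_motion",
    "mean_image",
    "register_sessions",
    "map_rois",
]


class RegistrationError(RuntimeError):
    """Affine registration failed to reach an acceptable correlation."""


def subtract_background(
    movie: np.ndarray,
    trial_boundaries: Sequence[int] | None = None,
) -> np.ndarray:
    """Subtract the per-trial scalar minimum from each trial segment.

    The background of each trial is defined as the minimum intensity over
    all pixels and frames of that trial's video segment.  With no
    boundaries the whole movie is one segment.  ``trial_boundaries`` are
    segment start frames; segment *i* spans ``[b_i, b_{i+1})``.  The
    operation is idempotent: each output segment has minimum exactly 0.
    """
    frames = np.asarray(movie, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("movie must be a non-empty T x H x W stack")
    T = frames.shape[0]
    if trial_boundaries is None:
        bounds = [0]
    else:
        bounds = sorted(int(b) for b in trial_boundaries)
        if not bounds or bounds[0] != 0:
            bounds = [0] + bounds
    edges = bounds + [T]
    out = frames.copy()
    for a, b in zip(edges, edges[1:]):
        if b <= a or a >= T:
            raise ValueError(f"empty trial segment [{a}, {b})")
        out[a:b] -= out[a:b].min()
    return out


def estimate_rigid_shift(
    frame: np.ndarray,
    reference: np.ndarray,
    upsample: int = 10,
) -> tuple[float, float]:
    """Subpixel rigid translation of ``frame`` relative to ``reference``.

    Estimated by cross-correlation in the Fourier domain, refined to
    1/``upsample`` pixel.  Returns ``(d_row, d_col)`` such that the frame
    content equals the reference translated by that amount.  A flat
    (zero-variance) frame yields ``(0, 0)`` with a warning.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have the same shape")
    if frame.std() == 0 or reference.std() == 0:
        warnings.warn("flat frame: returning zero shift", stacklevel=2)
        return (0.0, 0.0)
    # phase_cross_correlation returns the shift registering frame onto the
    # reference, i.e. the negative of the frame's displacement.
    shift, _, _ = phase_cross_correlation(
        reference, frame, upsample_factor=upsample, normalization=None
    )
    return (-float(shift[0]), -float(shift[1]))


def translate_frame(
    frame: np.ndarray,
    shift: tuple[float, float],
    order: int = 1,
) -> np.ndarray:
    """Translate a frame by (d_row, d_col) px, filling borders with 0."""
    if shift == (0.0, 0.0):
        return np.asarray(frame, dtype=float).copy()
    return ndimage.shift(
        np.asarray(frame, dtype=float), shift, order=order, mode="constant",
        cval=0.0,
    )


def correct_motion(
    movie: np.ndarray,
    reference: np.ndarray | None = None,
    upsample: int = 10,
    n_reference_frames: int = 300,
    interp_order: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid 2-D motion correction of a movie against a reference image.

    Each frame's translation relative to the reference is estimated by
    subpixel cross-correlation and undone.  The reference defaults to the
    mean of the first ``n_reference_frames`` frames.  Returns the
    corrected movie and the (T, 2) sequence of estimated ``(d_row,
    d_col)`` shifts for quality control.
    """
    frames = np.asarray(movie, dtype=float)
    if frames.ndim != 3:
        raise ValueError("movie must be a T x H x W stack")
    if reference is None:
        reference = frames[: min(n_reference_frames, len(frames))].mean(axis=0)
    shifts = np.zeros((len(frames), 2))
    corrected = np.empty_like(frames)
    for t, frame in enumerate(frames):
        s = estimate_rigid_shift(frame, reference, upsample=upsample)
        shifts[t] = s
        corrected[t] = translate_frame(frame, (-s[0], -s[1]),
                                       order=interp_order)
    return corrected, shifts


def mean_image(
    movie: np.ndarray,
    frame_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Pixelwise mean over a frame range (session reference image)."""
    frames = np.asarray(movie, dtype=float)
    if frames.ndim != 3:
        raise ValueError("movie must be a T x H x W stack")
    if frame_range is None:
        frame_range = (0, len(frames))
    a, b = frame_range
    if a < 0 or b > len(frames) or b <= a:
        raise ValueError(f"frame range [{a}, {b}) outside movie of length "
                         f"{len(frames)}")
    return frames[a:b].mean(axis=0)


@dataclass(frozen=True)
class AffineTransform2D:
    """2-D affine map ``y = A x + t`` in (row, col) pixel coordinates.

    Covers translation, rotation, isotropic scale and shear.  ``A`` is the
    2x2 linear part, ``t`` the translation in pixels.
    """

    A: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float).reshape(2, 2)
        t = np.asarray(self.t, dtype=float).reshape(2)
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("linear part must be invertible")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def from_params(
        cls,
        translation: tuple[float, float] = (0.0, 0.0),
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        shear: float = 0.0,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        """Rotation/scale/shear about ``center``, then translation.

        ``A = R(theta) @ [[1, shear], [0, 1]] @ (scale * I)``.
        """
        th = np.deg2rad(rotation_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        S = np.array([[1.0, shear], [0.0, 1.0]])
        A = R @ S * scale
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float) + c - A @ c
        return cls(A, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) points (row, col) through the transform."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts @ self.A.T + self.t

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return self ∘ other (apply ``other`` first)."""
        return AffineTransform2D(self.A @ other.A, self.A @ other.t + self.t)

    def inverse(self) -> "AffineTransform2D":
        Ainv = np.linalg.inv(self.A)
        return AffineTransform2D(Ainv, -Ainv @ self.t)

    def warp_image(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        """Resample ``image`` so that output(y) = image(T⁻¹ y)."""
        inv = self.inverse()
        return ndimage.affine_transform(
            np.asarray(image, dtype=float), inv.A, inv.t, order=order,
            mode="constant", cval=0.0,
        )

    def to_json(self, path: str | Path) -> None:
        mat = np.hstack([self.A, self.t[:, None]])
        Path(path).write_text(json.dumps({"matrix_2x3": mat.tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform2D":
        mat = np.asarray(json.loads(Path(path).read_text())["matrix_2x3"])
        return cls(mat[:, :2], mat[:, 2])


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation over pixels where both images are set."""
    valid = (a != 0) & (b != 0)
    if valid.sum() < 16:
        return -1.0
    av, bv = a[valid], b[valid]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        return -1.0
    return float((av * bv).sum() / denom)


def register_sessions(
    session_ref: np.ndarray,
    master_ref: np.ndarray,
    min_correlation: float = 0.5,
    interp_order: int = 1,
) -> AffineTransform2D:
    """Affine registration of a session reference image to the master.

    Returns the transform mapping session coordinates into master
    coordinates (translation + rotation + isotropic scale + shear),
    estimated by intensity-based optimization of normalized
    cross-correlation with a translation pre-alignment and a
    multi-resolution refinement.  Raises :class:`RegistrationError` when
    the final correlation falls below ``min_correlation``.
    """
    session = np.asarray(session_ref, dtype=float)
    master = np.asarray(master_ref, dtype=float)
    if session.shape != master.shape:
        raise ValueError("session and master reference must share a shape")
    center = ((session.shape[0] - 1) / 2.0, (session.shape[1] - 1) / 2.0)

    # coarse translation initialisation from phase correlation
    d0 = estimate_rigid_shift(session, master)
    x0 = np.array([-d0[0], -d0[1], 0.0, 1.0, 0.0])

    def build(p):
        return AffineTransform2D.from_params(
            translation=(p[0], p[1]), rotation_deg=p[2], scale=p[3],
            shear=p[4], center=center,
        )

    def cost(p, sess, mast):
        ctr = ((sess.shape[0] - 1) / 2.0, (sess.shape[1] - 1) / 2.0)
        tf = AffineTransform2D.from_params(
            translation=(p[0], p[1]), rotation_deg=p[2], scale=p[3],
            shear=p[4], center=ctr,
        )
        return -_ncc(tf.warp_image(sess, order=interp_order), mast)

    # multi-resolution: optimize on a 2x-downsampled pair, then refine
    p = x0.copy()
    for factor in (2, 1):
        if factor > 1:
            sess = session[::factor, ::factor]
            mast = master[::factor, ::factor]
            p_level = p.copy()
            p_level[0] /= factor
            p_level[1] /= factor
        else:
            sess, mast, p_level = session, master, p.copy()
        res = optimize.minimize(
            cost, p_level, args=(sess, mast), method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-6, "maxiter": 2000},
        )
        p = res.x.copy()
        if factor > 1:
            p[0] *= factor
            p[1] *= factor
    tform = build(p)
    final = _ncc(tform.warp_image(session, order=interp_order), master)
    if final < min_correlation:
        raise RegistrationError(
            f"registration correlation {final:.3f} below threshold "
            f"{min_correlation}; params {p.tolist()}"
        )
    return tform


def map_rois(
    rois: Sequence[RoiMask],
    transform: AffineTransform2D,
    frame_shape: tuple[int, int],
) -> list[RoiMask]:
    """Map ROI masks through an affine transform and re-rasterize.

    Each mask is rendered as a binary image, resampled with
    nearest-neighbour interpolation through the transform, and converted
    back to a pixel set; identities and class labels are preserved.  A
    mask whose image falls entirely outside the frame is returned with
    ``lost=True`` (never silently dropped).
    """
    out = []
    for m in rois:
        src = m.to_bool_image(frame_shape).astype(float)
        warped = transform.warp_image(src, order=0) > 0.5
        pixels = np.argwhere(warped)
        if pixels.shape[0] == 0:
            out.append(RoiMask(roi_id=m.roi_id, pixels=pixels,
                               class_label=m.class_label, lost=True))
        else:
            out.append(RoiMask(roi_id=m.roi_id, pixels=pixels,
                               class_label=m.class_label))
    return out
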