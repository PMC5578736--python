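"""Recovery kinetics and directional-transport detection for FRAP stacks.

A bleached disk refilling by pure diffusion recovers isotropically and
its centroid stays put; convective flow makes the upstream sector
recover first and drags the darkened spot downstream.  This module
extracts:

* the normalized recovery curve and its half-time t_1/2,
* per-quadrant recovery and an asymmetry index,
* intensity time courses at distal positions,
* the bleached-spot centroid per frame (scanning-circle tracker with
  sub-pixel refinement), and
* a null-calibrated upper bound on convective velocity.

Normalization convention: F(t) = (I(t) - I0) / (I_pre - I0) with I0 the
first post-bleach ROI mean and I_pre the pre-bleach mean, so F runs
from 0 (post-bleach floor) to 1 (full recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.registration import phase_cross_correlation

from .errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "ImageStack",
    "RecoveryCurve",
    "CentroidTrace",
    "recovery_curve",
    "quadrant_recovery",
    "distal_timecourses",
    "track_centroid",
    "velocity_upper_bound",
    "compare_halftimes",
    "effect_size",
    "register_stack",
]


@dataclass
class ImageStack:
    """Time-lapse of 2-D frames with physical calibration.

    ``frames``: (T, H, W) array ordered in time; ``pixel_size`` um;
    ``frame_interval`` s; the first ``prebleach_count`` frames precede
    the bleach.  Times are measured from the first post-bleach frame.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    prebleach_count: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be a (T, H, W) array")
        if not self.pixel_size > 0:
            raise InvalidParameterError("pixel_size must be > 0")
        if not self.frame_interval > 0:
            raise InvalidParameterError("frame_interval must be > 0")
        if self.prebleach_count < 0 or self.prebleach_count >= len(self.frames):
            raise InvalidParameterError("prebleach_count out of range")

    @property
    def n_post(self) -> int:
        return len(self.frames) - self.prebleach_count

    @property
    def post_times(self) -> np.ndarray:
        """Seconds from the bleach for each post-bleach frame."""
        return np.arange(self.n_post) * self.frame_interval

    @property
    def prebleach_mean(self) -> np.ndarray:
        if self.prebleach_count == 0:
            raise DegenerateInputError("stack has no pre-bleach frames")
        return self.frames[: self.prebleach_count].mean(axis=0)

    @property
    def post_frames(self) -> np.ndarray:
        return self.frames[self.prebleach_count :]

    def extent_um(self) -> tuple[float, float]:
        h, w = self.frames.shape[1:]
        return (h * self.pixel_size, w * self.pixel_size)


@dataclass
class RecoveryCurve:
    """Normalized fluorescence recovery F(t) with its half-time."""

    times: np.ndarray
    F: np.ndarray
    t_half: float | None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.F = np.asarray(self.F, dtype=float)


@dataclass
class CentroidTrace:
    """Bleached-spot centre per post-bleach frame, in um."""

    times: np.ndarray
    positions: np.ndarray  # (T, 2) as (x, y)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)

    @property
    def displacement(self) -> np.ndarray:
        """Distance from the initial position per frame (um)."""
        return np.linalg.norm(self.positions - self.positions[0], axis=1)

    @property
    def end_to_end(self) -> float:
        return float(self.displacement[-1])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def fitted_velocity(self) -> tuple[float, np.ndarray]:
        """Speed (um/min) and direction from a linear least-squares fit
        of position against time — uses every frame, unlike the
        end-to-end displacement, so it averages down tracking noise."""
        t = self.times
        A = np.vstack([t, np.ones_like(t)]).T
        slopes = np.linalg.lstsq(A, self.positions, rcond=None)[0][0]  # um/s
        speed = float(np.linalg.norm(slopes)) * 60.0
        direction = slopes / (np.linalg.norm(slopes) + 1e-300)
        return speed, direction


def _disk_mask(
    shape: tuple[int, int], pixel_size: float, center_um: tuple[float, float], diameter_um: float
) -> np.ndarray:
    h, w = shape
    ys = (np.arange(h) + 0.5) * pixel_size
    xs = (np.arange(w) + 0.5) * pixel_size
    cy, cx = center_um[1], center_um[0]
    d2 = (ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2
    return d2 <= (diameter_um / 2.0) ** 2


def _check_roi(stack: ImageStack, roi_center, roi_diameter) -> None:
    ey, ex = stack.extent_um()
    cx, cy = roi_center
    r = roi_diameter / 2.0
    if not (r <= cx <= ex - r and r <= cy <= ey - r):
        raise InvalidParameterError("ROI extends outside the image")


def _curve_from_means(times: np.ndarray, means: np.ndarray, i_pre: float, label="") -> RecoveryCurve:
    i0 = means[0]
    if abs(i_pre - i0) < 1e-12 * max(abs(i_pre), 1.0):
        raise DegenerateInputError(
            "pre-bleach and post-bleach intensities coincide; no bleach to recover from"
        )
    F = (means - i0) / (i_pre - i0)
    return RecoveryCurve(times=times, F=F, t_half=_half_time(times, F), label=label)


def _half_time(times: np.ndarray, F: np.ndarray) -> float | None:
    """Earliest time F crosses 0.5, linearly interpolated; None if it
    never does (no extrapolation)."""
    above = np.nonzero(F >= 0.5)[0]
    if above.size == 0:
        return None
    j = above[0]
    if j == 0:
        return float(times[0])
    t0, t1 = times[j - 1], times[j]
    f0, f1 = F[j - 1], F[j]
    return float(t0 + (0.5 - f0) * (t1 - t0) / (f1 - f0))


def recovery_curve(
    stack: ImageStack, roi_center: tuple[float, float], roi_diameter: float
) -> RecoveryCurve:
    """Normalized recovery of the mean intensity inside a circular ROI.

    ``roi_center`` is (x, y) in um.  Raises
    :class:`DegenerateInputError` if the stack shows no bleach.
    """
    _check_roi(stack, roi_center, roi_diameter)
    mask = _disk_mask(stack.frames.shape[1:], stack.pixel_size, roi_center, roi_diameter)
    i_pre = float(stack.prebleach_mean[mask].mean())
    means = stack.post_frames[:, mask].mean(axis=1)
    return _curve_from_means(stack.post_times, means, i_pre)


def quadrant_recovery(
    stack: ImageStack,
    roi_center: tuple[float, float],
    roi_diameter: float,
    rotation_deg: float = 0.0,
) -> tuple[list[RecoveryCurve], float]:
    """Recovery per 90-degree sector of the bleached disk, plus an
    asymmetry index.

    Sectors are numbered 0..3 counter-clockwise starting from the +x
    axis (rotatable by ``rotation_deg``).  The asymmetry index is the
    maximum over sector pairs of |t_half_i - t_half_j| divided by the
    mean t_half; isotropic recovery gives 0.
    """
    _check_roi(stack, roi_center, roi_diameter)
    h, w = stack.frames.shape[1:]
    ys = (np.arange(h) + 0.5) * stack.pixel_size
    xs = (np.arange(w) + 0.5) * stack.pixel_size
    cy, cx = roi_center[1], roi_center[0]
    dy = ys[:, None] - cy
    dx = xs[None, :] - cx
    in_disk = dy**2 + dx**2 <= (roi_diameter / 2.0) ** 2
    ang = np.degrees(np.arctan2(dy, dx)) - rotation_deg
    sector = np.floor(((ang % 360.0) / 90.0)).astype(int)
    curves: list[RecoveryCurve] = []
    for s in range(4):
        mask = in_disk & (sector == s)
        if not mask.any():
            raise InvalidParameterError("empty quadrant; ROI too small for the pixel grid")
        i_pre = float(stack.prebleach_mean[mask].mean())
        means = stack.post_frames[:, mask].mean(axis=1)
        curves.append(_curve_from_means(stack.post_times, means, i_pre, label=f"Q{s}"))
    t_halves = [c.t_half for c in curves]
    if any(t is None for t in t_halves):
        index = float("nan")
    else:
        th = np.asarray(t_halves, dtype=float)
        index = float((th.max() - th.min()) / th.mean()) if th.mean() > 0 else 0.0
    return curves, index


def distal_timecourses(
    stack: ImageStack,
    positions: Sequence[tuple[float, float]],
    window_diameter: float = 3.0,
) -> list[RecoveryCurve]:
    """Pre-bleach-normalized intensity time course in a small window at
    each position ((x, y) um).

    Unlike :func:`recovery_curve`, normalization is simply
    I(t)/I_pre — distal windows were never bleached to a floor, the
    interesting signature is their transient dip as bleached molecules
    arrive.  Raises if a window is clipped by the image border.
    """
    out = []
    for pos in positions:
        _check_roi(stack, pos, window_diameter)
        mask = _disk_mask(stack.frames.shape[1:], stack.pixel_size, pos, window_diameter)
        if not mask.any():
            raise InvalidParameterError(f"window at {pos} covers no pixels")
        i_pre = float(stack.prebleach_mean[mask].mean())
        if i_pre == 0:
            raise DegenerateInputError("zero pre-bleach intensity at distal window")
        rel = stack.post_frames[:, mask].mean(axis=1) / i_pre
        out.append(
            RecoveryCurve(times=stack.post_times, F=rel, t_half=None, label=f"{pos}")
        )
    return out


def _disk_kernel(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    k = (y**2 + x**2 <= radius_px**2).astype(float)
    return k / k.sum()


def _quadratic_subpixel(score: np.ndarray, ij: tuple[int, int]) -> tuple[float, float]:
    """1-D quadratic refinement along each axis of the 3x3 neighbourhood
    of a grid maximum; offsets clipped to +-0.5 cell."""
    i, j = ij
    out = []
    for axis, idx in ((0, i), (1, j)):
        if idx <= 0 or idx >= score.shape[axis] - 1:
            out.append(0.0)
            continue
        if axis == 0:
            sm, s0, sp = score[i - 1, j], score[i, j], score[i + 1, j]
        else:
            sm, s0, sp = score[i, j - 1], score[i, j], score[i, j + 1]
        denom = sm - 2 * s0 + sp
        off = 0.0 if denom == 0 else 0.5 * (sm - sp) / denom
        out.append(float(np.clip(off, -0.5, 0.5)))
    return out[0], out[1]


def track_centroid(
    stack: ImageStack,
    prebleach_reference: np.ndarray | None = None,
    scan_diameter: float = 10.0,
    search_factor: float = 2.0,
) -> CentroidTrace:
    """Track the bleached-spot centre by scanning a circle across each
    frame and locating the maximum mean decrease from baseline.

    The difference image (reference - frame) is convolved with a
    normalized disk of ``scan_diameter``; the per-frame position is the
    grid argmax refined to sub-pixel by a quadratic fit.  From the
    second frame on, the search is restricted to a window of
    ``search_factor`` x scan_diameter around the previous position, and
    ties are broken toward the smallest displacement from the previous
    frame.  Raises :class:`DegenerateInputError` when the difference
    image carries no signal at all.
    """
    ref = stack.prebleach_mean if prebleach_reference is None else np.asarray(prebleach_reference, float)
    px = stack.pixel_size
    radius_px = (scan_diameter / 2.0) / px
    kernel = _disk_kernel(radius_px)
    half_window_px = search_factor * scan_diameter / 2.0 / px
    positions = []
    prev: tuple[float, float] | None = None  # (row, col) float px
    for frame in stack.post_frames:
        diff = ref - frame
        if np.allclose(diff, 0):
            raise DegenerateInputError("difference image is zero: no bleach detected")
        score = ndimage.convolve(diff, kernel, mode="nearest")
        mask = np.zeros(score.shape, dtype=bool)
        if prev is None:
            mask[:] = True
        else:
            r0, c0 = prev
            lo_r = max(0, int(np.floor(r0 - half_window_px)))
            hi_r = min(score.shape[0], int(np.ceil(r0 + half_window_px)) + 1)
            lo_c = max(0, int(np.floor(c0 - half_window_px)))
            hi_c = min(score.shape[1], int(np.ceil(c0 + half_window_px)) + 1)
            mask[lo_r:hi_r, lo_c:hi_c] = True
        masked = np.where(mask, score, -np.inf)
        m = masked.max()
        cand = np.argwhere(masked >= m - 1e-12 * max(abs(m), 1.0))
        if prev is not None and len(cand) > 1:
            d2 = (cand[:, 0] - prev[0]) ** 2 + (cand[:, 1] - prev[1]) ** 2
            best = cand[np.argmin(d2)]
        else:
            best = cand[0]
        di, dj = _quadratic_subpixel(score, (int(best[0]), int(best[1])))
        pos = (best[0] + di, best[1] + dj)
        positions.append(pos)
        prev = pos
    pos_px = np.asarray(positions)  # (T, 2) row, col
    pos_um = np.stack(
        [(pos_px[:, 1] + 0.5) * px, (pos_px[:, 0] + 0.5) * px], axis=1
    )  # (x, y)
    return CentroidTrace(times=stack.post_times, positions=pos_um)


def velocity_upper_bound(
    trace: CentroidTrace | None,
    null_traces: Sequence[CentroidTrace],
    percentile: float = 95.0,
) -> tuple[float, bool | None]:
    """Detection floor for convective velocity, calibrated on null
    (v = 0) traces at matched noise.

    The bound is the ``percentile``-th percentile of the nulls'
    end-to-end displacement divided by the observation time, in um/min.
    Returns ``(bound, directional)`` where ``directional`` flags an
    observed trace whose apparent velocity exceeds the bound (None when
    no trace is supplied).
    """
    if len(null_traces) < 10:
        raise InvalidParameterError("need >= 10 null traces for calibration")
    for nt in null_traces:
        if nt.duration <= 0:
            raise InvalidParameterError("null trace has nonpositive observation time")
    disp = np.asarray([nt.end_to_end for nt in null_traces])
    minutes = np.asarray([nt.duration / 60.0 for nt in null_traces])
    bound = float(np.percentile(disp / minutes, percentile))
    directional = None
    if trace is not None:
        if trace.duration <= 0:
            raise InvalidParameterError("observation time must be > 0")
        directional = bool(trace.end_to_end / (trace.duration / 60.0) > bound)
    return bound, directional


def compare_halftimes(groups: Sequence[Sequence[RecoveryCurve]], labels=None) -> dict:
    """Group means +- SEM of t_1/2 and a two-sided t-test (routine
    statistics; thin wrapper over scipy)."""
    if len(groups) < 2:
        raise InvalidParameterError("need at least two groups")
    values = []
    for g in groups:
        th = [c.t_half for c in g]
        if len(th) < 2:
            raise InvalidParameterError("each group needs >= 2 curves")
        if any(t is None for t in th):
            raise DegenerateInputError("a curve never reached half-recovery")
        values.append(np.asarray(th, dtype=float))
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    summary = {
        lab: {"mean": float(v.mean()), "sem": float(stats.sem(v)), "n": len(v)}
        for lab, v in zip(labels, values)
    }
    t, p = stats.ttest_ind(values[0], values[1])
    summary["t_test"] = {"t": float(t), "p": float(p)}
    return summary


def effect_size(percent_change: float, sd_percent: float) -> float:
    """Cohen's d for a power calculation: expected percent change in
    the measured rate divided by its percent standard deviation."""
    if not sd_percent > 0:
        raise InvalidParameterError("sd_percent must be > 0")
    return percent_change / sd_percent


def register_stack(stack: ImageStack, upsample: int = 20) -> ImageStack:
    """Rigidly re-align every frame to the pre-bleach reference by
    phase cross-correlation, removing heartbeat-like jitter."""
    ref = stack.prebleach_mean
    ref_z = ref - ref.mean()
    aligned = []
    for frame in stack.frames:
        shift, _, _ = phase_cross_correlation(
            ref_z, frame - frame.mean(), upsample_factor=upsample, normalization=None
        )
        aligned.append(ndimage.shift(frame, shift, order=1, mode="nearest"))
    return ImageStack(
        frames=np.asarray(aligned),
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
        prebleach_count=stack.prebleach_count,
        metadata={**stack.metadata, "registered": True},
    )
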