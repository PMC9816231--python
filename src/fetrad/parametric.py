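"""Parametric imaging for dynamic amino-acid brain PET.

Two voxel-wise parametric maps are derived from a 4D dynamic acquisition:

* **TBR** (tumor-to-background ratio): the 20-40 min post-injection summation
  image divided by the mean activity of a healthy-hemisphere background VOI.
* **TTP** (time-to-peak): each voxel's time-activity curve (TAC) is classified
  by the time frame in which it reaches its maximum, into six ordinal groups
  (<5, 5-10, 10-15, 15-20, 20-30, 30-40 min).  Frames centred before 2.7 min
  post-injection are excluded to suppress the early blood-pool flush, and a
  voxel whose late TAC (15-40 min) still rises is assigned to the last group
  regardless of its nominal peak frame.

Tumor VOIs are segmented by thresholding the TBR map at 1.6 and keeping the
largest 26-connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "ParametricImage",
    "TTP_GROUP_EDGES",
    "DEFAULT_EXCLUDE_BEFORE_MIN",
    "DEFAULT_LATE_WINDOW_MIN",
    "default_schedule",
    "ttp_group_of_time",
    "summation_image",
    "background_mean",
    "tbr_image",
    "classify_ttp",
    "ttp_image",
    "segment_tumor",
]

#: Upper edges (minutes) of the six ordinal time-to-peak groups.
TTP_GROUP_EDGES = (5.0, 10.0, 15.0, 20.0, 30.0, 40.0)

#: Frames whose midpoint falls before this time (min p.i.) are excluded from
#: peak classification (early blood-flush suppression).
DEFAULT_EXCLUDE_BEFORE_MIN = 2.7

#: Window (min p.i.) over which the late slope is assessed.
DEFAULT_LATE_WINDOW_MIN = (15.0, 40.0)

#: Fill value written outside the ROI in masked TTP maps. 0 is not a valid
#: group, so downstream feature extraction can never confuse it with tissue.
TTP_FILL_VALUE = 0


class AlignmentError(ValueError):
    """A requested time window does not align with frame boundaries."""


class DegenerateScheduleError(ValueError):
    """All frames were excluded; no peak classification is possible."""


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous dynamic-PET frame timing in minutes post-injection.

    ``frame_ends[i] == frame_starts[i + 1]`` for all i; durations positive.
    """

    frame_starts: Tuple[float, ...]
    frame_ends: Tuple[float, ...]

    def __post_init__(self):
        starts = np.asarray(self.frame_starts, dtype=float)
        ends = np.asarray(self.frame_ends, dtype=float)
        if starts.ndim != 1 or starts.shape != ends.shape or starts.size == 0:
            raise ValueError("frame_starts and frame_ends must be equal-length 1D sequences")
        if np.any(ends <= starts):
            raise ValueError("every frame must have positive duration")
        if starts.size > 1 and not np.allclose(starts[1:], ends[:-1]):
            raise ValueError("frames must be contiguous: frame_ends[i] == frame_starts[i+1]")
        object.__setattr__(self, "frame_starts", tuple(float(s) for s in starts))
        object.__setattr__(self, "frame_ends", tuple(float(e) for e in ends))

    @property
    def n_frames(self) -> int:
        return len(self.frame_starts)

    @property
    def starts(self) -> np.ndarray:
        return np.asarray(self.frame_starts)

    @property
    def ends(self) -> np.ndarray:
        return np.asarray(self.frame_ends)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_minutes(self) -> float:
        return float(self.frame_ends[-1])

    def to_dict(self) -> dict:
        return {
            "frame_starts_min": list(self.frame_starts),
            "frame_ends_min": list(self.frame_ends),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        return cls(tuple(d["frame_starts_min"]), tuple(d["frame_ends_min"]))


def default_schedule() -> FrameSchedule:
    """Default 0-40 min schedule: 1-min frames to 5 min, 5-min frames to
    20 min, 10-min frames to 40 min (10 frames).

    The boundaries resolve every TTP group edge exactly.
    """
    edges = [0, 1, 2, 3, 4, 5, 10, 15, 20, 30, 40]
    return FrameSchedule(tuple(edges[:-1]), tuple(edges[1:]))


@dataclass
class DynamicImage:
    """4D dynamic PET volume: ``data[x, y, z, frame]`` activity concentration."""

    data: np.ndarray
    voxel_size: Tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic image must be 4D (x, y, z, frame)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"frame axis length {self.data.shape[3]} != schedule length "
                f"{self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("activity values must be finite")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class ParametricImage:
    """3D parametric map (TBR: nonnegative real; TTP: ordinal groups 1-6)."""

    data: np.ndarray
    kind: str  # "TBR" or "TTP"
    voxel_size: Tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("parametric image must be 3D")
        if self.kind not in ("TBR", "TTP"):
            raise ValueError("kind must be 'TBR' or 'TTP'")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)


def summation_image(dyn: DynamicImage, window: Sequence[float] = (20.0, 40.0)) -> np.ndarray:
    """Duration-weighted mean of the frames inside ``window`` (min p.i.).

    Window boundaries must coincide with frame boundaries; a misaligned
    boundary raises :class:`AlignmentError` naming the offending edge.
    """
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("window end must exceed window start")
    starts, ends = dyn.schedule.starts, dyn.schedule.ends
    for edge in (lo, hi):
        if not (np.any(np.isclose(starts, edge)) or np.any(np.isclose(ends, edge))):
            raise AlignmentError(
                f"window boundary {edge} min does not align with any frame boundary"
            )
    inside = (starts >= lo - 1e-9) & (ends <= hi + 1e-9)
    if not np.any(inside):
        raise AlignmentError(f"no frames lie within window [{lo}, {hi}] min")
    durs = dyn.schedule.durations[inside]
    frames = dyn.data[..., inside]
    return np.tensordot(frames, durs, axes=([3], [0])) / durs.sum()


def background_mean(volume: np.ndarray, crescent_mask: np.ndarray) -> float:
    """Mean activity over the healthy-hemisphere background VOI."""
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(crescent_mask).astype(bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    if not mask.any():
        raise ValueError("background mask is empty")
    mean = float(volume[mask].mean())
    if mean <= 0:
        raise ValueError(f"background mean must be positive, got {mean}")
    return mean


def tbr_image(sum_20_40: np.ndarray, bg_mean: float,
              voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)) -> ParametricImage:
    """Normalize a 20-40 min summation image by the background mean."""
    if bg_mean <= 0:
        raise ValueError("background mean must be positive")
    return ParametricImage(
        data=np.asarray(sum_20_40, dtype=float) / float(bg_mean),
        kind="TBR",
        voxel_size=voxel_size,
        provenance={"background_mean": float(bg_mean), "window_min": [20.0, 40.0]},
    )


def ttp_group_of_time(t_min: float) -> int:
    """Map a peak time (minutes p.i.) to its ordinal TTP group 1-6."""
    if t_min <= 0 or t_min > TTP_GROUP_EDGES[-1]:
        raise ValueError(f"peak time {t_min} min outside (0, {TTP_GROUP_EDGES[-1]}]")
    # intervals are closed below, open above, except the last which is closed
    group = int(np.searchsorted(TTP_GROUP_EDGES, t_min, side="right")) + 1
    return min(group, 6)


def _late_slope_weights(schedule: FrameSchedule,
                        window: Tuple[float, float]) -> Tuple[np.ndarray, np.ndarray]:
    """OLS slope of value-vs-midpoint as a linear functional of frame values.

    Returns (frame index array, weight array) such that
    ``slope = weights @ values[idx]``; empty if fewer than two frames fall in
    the window.
    """
    mid = schedule.midpoints
    idx = np.where((mid >= window[0]) & (mid <= window[1]))[0]
    if idx.size < 2:
        return idx, np.zeros(0)
    t = mid[idx]
    tc = t - t.mean()
    return idx, tc / (tc @ tc)


def classify_ttp(
    tac: Sequence[float],
    schedule: FrameSchedule,
    exclude_before_min: float = DEFAULT_EXCLUDE_BEFORE_MIN,
    late_window: Tuple[float, float] = DEFAULT_LATE_WINDOW_MIN,
) -> int:
    """Classify one TAC into a TTP group 1-6.

    1. Frames whose midpoint precedes ``exclude_before_min`` are dropped.
    2. If the OLS slope of frame values against frame midpoints over the late
       window is strictly positive, the voxel is group 6.
    3. Otherwise the earliest remaining frame attaining the maximum defines
       the peak; its midpoint is mapped through the group intervals.
    """
    tac = np.asarray(tac, dtype=float)
    if tac.shape != (schedule.n_frames,):
        raise ValueError("TAC length does not match schedule")
    mid = schedule.midpoints
    keep = mid >= exclude_before_min
    if not keep.any():
        raise DegenerateScheduleError("all frames excluded by the early cut-off")
    idx, w = _late_slope_weights(schedule, late_window)
    if w.size and float(w @ tac[idx]) > 0:
        return 6
    kept_idx = np.where(keep)[0]
    peak = kept_idx[int(np.argmax(tac[kept_idx]))]
    return ttp_group_of_time(float(mid[peak]))


def ttp_image(
    dyn: DynamicImage,
    roi_mask: Optional[np.ndarray] = None,
    exclude_before_min: float = DEFAULT_EXCLUDE_BEFORE_MIN,
    late_window: Tuple[float, float] = DEFAULT_LATE_WINDOW_MIN,
) -> ParametricImage:
    """Voxel-wise TTP classification (vectorized over the grid).

    Voxels outside ``roi_mask`` (if given) are set to ``TTP_FILL_VALUE`` (0),
    which is outside the valid group range and must be excluded from feature
    extraction by the accompanying mask.
    """
    mid = dyn.schedule.midpoints
    keep = mid >= exclude_before_min
    if not keep.any():
        raise DegenerateScheduleError("all frames excluded by the early cut-off")
    kept_idx = np.where(keep)[0]

    data = dyn.data
    # group of each kept frame midpoint, precomputed once
    frame_groups = np.array([ttp_group_of_time(float(m)) for m in mid[kept_idx]])

    peak_local = np.argmax(data[..., kept_idx], axis=3)  # earliest max wins
    groups = frame_groups[peak_local]

    sl_idx, w = _late_slope_weights(dyn.schedule, late_window)
    if w.size:
        slope = np.tensordot(data[..., sl_idx], w, axes=([3], [0]))
        groups = np.where(slope > 0, 6, groups)

    out = groups.astype(np.int16)
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask).astype(bool)
        if roi_mask.shape != dyn.grid_shape:
            raise ValueError("ROI mask grid does not match image grid")
        out = np.where(roi_mask, out, TTP_FILL_VALUE).astype(np.int16)
    return ParametricImage(
        data=out,
        kind="TTP",
        voxel_size=dyn.voxel_size,
        provenance={
            "schedule": dyn.schedule.to_dict(),
            "exclude_before_min": exclude_before_min,
            "late_window_min": list(late_window),
            "fill_value": TTP_FILL_VALUE,
        },
    )


def segment_tumor(
    tbr: ParametricImage,
    threshold: float = 1.6,
    largest_component_only: bool = True,
) -> np.ndarray:
    """Threshold a TBR map (TBR >= threshold, inclusive) into a tumor VOI.

    By default only the largest 26-connected component is kept, since the
    target lesion is a single VOI and pure thresholding can pick up specks.
    An all-false mask is a valid result (no FET-positive tumor).
    """
    if tbr.kind != "TBR":
        raise ValueError("segment_tumor expects a TBR parametric image")
    mask = np.asarray(tbr.data) >= threshold
    if not mask.any() or not largest_component_only:
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))
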