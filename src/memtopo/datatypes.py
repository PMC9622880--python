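"""Domain containers shared by all analysis stages.

The unit of observation is one experimental session ("sample"): a
participant watching ~300 of their own one-second memory videos in the
scanner, each annotated afterwards with the memory's age (days before the
scan), geographic location, memory-strength and emotion ratings (1-5), and
content labels (people/place familiarity). The brain-side input is a
per-video voxel statistic stack (the t-statistic of a first-level GLM beta
per video, within a brain mask); producing those maps is upstream of this
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .geo import geodesic_km

RATING_LEVELS = (1, 2, 3, 4, 5)

#: Behavioral predictors usable in the voxelwise regressions.
PREDICTORS = ("age_days", "memory_strength", "emotion", "distance_km")


@dataclass
class VideoRecord:
    """One memory video's behavioral annotation."""

    video_id: str
    age_days: float
    memory_strength: int
    emotion: int
    has_people: bool
    people_new: bool
    contains_self: bool
    place_new: bool
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    #: geodesic distance to the scan site; derived by SampleSession.
    distance_km: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.age_days) or self.age_days < 0:
            raise ValueError(f"video {self.video_id}: age_days must be >= 0")
        for name in ("memory_strength", "emotion"):
            v = getattr(self, name)
            if v not in RATING_LEVELS:
                raise ValueError(
                    f"video {self.video_id}: {name}={v!r} outside 1-5 rating scale"
                )
        if (self.latitude is None) != (self.longitude is None):
            raise ValueError(
                f"video {self.video_id}: latitude and longitude must both be "
                "present or both missing"
            )
        if (self.people_new or self.contains_self) and not self.has_people:
            raise ValueError(
                f"video {self.video_id}: people_new/contains_self require has_people"
            )

    @property
    def has_location(self) -> bool:
        return self.latitude is not None

    def people_category(self) -> Optional[str]:
        """Content category with the documented precedence new > self >
        familiar; None when no people are present."""
        if not self.has_people:
            return None
        if self.people_new:
            return "new"
        if self.contains_self:
            return "self"
        return "familiar"


@dataclass
class SampleSession:
    """One experimental session: a participant, a scan site, and its videos.

    Distances are (re)derived against this session's scan site on
    construction; videos without coordinates keep ``distance_km`` missing
    and are dropped from distance-using analyses downstream.
    """

    sample_id: str
    participant_id: str
    scan_lat: float
    scan_lon: float
    videos: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.videos) < 1:
            raise ValueError(f"session {self.sample_id}: needs at least one video")
        ids = [v.video_id for v in self.videos]
        if len(set(ids)) != len(ids):
            raise ValueError(f"session {self.sample_id}: duplicate video ids")
        for v in self.videos:
            if v.has_location:
                v.distance_km = geodesic_km(
                    v.latitude, v.longitude, self.scan_lat, self.scan_lon
                )
            else:
                v.distance_km = None

    @property
    def n_videos(self) -> int:
        return len(self.videos)

    @property
    def video_ids(self) -> list:
        return [v.video_id for v in self.videos]

    def predictor(self, name: str) -> np.ndarray:
        """Predictor vector in raw units; missing distances become NaN."""
        if name not in PREDICTORS:
            raise KeyError(f"unknown predictor {name!r}; expected one of {PREDICTORS}")
        vals = [getattr(v, name) for v in self.videos]
        return np.array([np.nan if x is None else float(x) for x in vals])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.videos:
            rows.append(
                {
                    "video_id": v.video_id,
                    "age_days": v.age_days,
                    "latitude": v.latitude,
                    "longitude": v.longitude,
                    "memory_strength": v.memory_strength,
                    "emotion": v.emotion,
                    "has_people": v.has_people,
                    "people_new": v.people_new,
                    "contains_self": v.contains_self,
                    "place_new": v.place_new,
                    "distance_km": v.distance_km,
                }
            )
        return pd.DataFrame(rows)

    def subset(self, keep: Sequence[bool]) -> "SampleSession":
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.n_videos,):
            raise ValueError("keep mask length must equal n_videos")
        vids = [v for v, k in zip(self.videos, keep) if k]
        return SampleSession(
            sample_id=f"{self.sample_id}",
            participant_id=self.participant_id,
            scan_lat=self.scan_lat,
            scan_lon=self.scan_lon,
            videos=vids,
        )


@dataclass
class BetaStack:
    """Per-video voxel statistics inside a brain mask.

    ``values`` holds one row per video and one column per in-mask voxel,
    in the C-order scan of ``mask`` (see :meth:`voxel_index_map`).
    """

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    video_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3-D boolean array")
        n_mask = int(self.mask.sum())
        if self.values.ndim != 2 or self.values.shape[1] != n_mask:
            raise ValueError(
                f"values has {self.values.shape} but mask has {n_mask} true voxels"
            )
        if len(self.video_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.video_ids)} video ids for {self.values.shape[0]} volumes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stack values must be finite")

    @property
    def n_videos(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def voxel_index_map(self) -> np.ndarray:
        """[n_voxels x 3] array mapping column index to (i, j, k)."""
        return np.argwhere(self.mask)

    def check_aligned(self, session: SampleSession) -> None:
        if self.video_ids != session.video_ids:
            raise ValueError(
                f"stack/session video order mismatch for session "
                f"{session.sample_id}"
            )

    def to_volume(self, column_values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-column vector back into a 3-D volume."""
        col = np.asarray(column_values, dtype=float)
        if col.shape != (self.n_voxels,):
            raise ValueError("column vector length must equal n_voxels")
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = col
        return vol


@dataclass
class RoiAtlas:
    """Named ROI masks congruent with a brain mask."""

    brain_mask: np.ndarray
    rois: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        rois = {}
        for name, m in dict(self.rois).items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.brain_mask.shape:
                raise ValueError(f"ROI {name!r} shape differs from brain mask")
            if np.any(m & ~self.brain_mask):
                raise ValueError(f"ROI {name!r} extends outside the brain mask")
            if not m.any():
                raise ValueError(f"ROI {name!r} is empty")
            rois[name] = m
        self.rois = rois

    def __contains__(self, name: str) -> bool:
        return name in self.rois

    def names(self) -> list:
        return list(self.rois)

    def mask(self, name: str) -> np.ndarray:
        if name not in self.rois:
            raise KeyError(f"unknown ROI {name!r}; have {sorted(self.rois)}")
        return self.rois[name]

    def columns(self, name: str) -> np.ndarray:
        """Column indices of an ROI within the brain-mask column layout."""
        flat_brain = self.brain_mask.ravel()
        flat_roi = self.mask(name).ravel()
        # position of each ROI voxel among the in-mask voxels (C order)
        idx = np.cumsum(flat_brain) - 1
        return idx[flat_roi & flat_brain]


@dataclass
class GroupStatMap:
    """Group-level per-voxel statistics for one predictor or contrast."""

    predictor: str
    mean_beta: np.ndarray
    t_value: np.ndarray
    p_value: np.ndarray
    cohens_d: np.ndarray
    n_samples: int
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        n = int(np.asarray(self.mask, dtype=bool).sum())
        for name in ("mean_beta", "t_value", "p_value", "cohens_d"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per in-mask voxel")
            setattr(self, name, arr)
        with np.errstate(invalid="ignore"):
            bad = (self.p_value < 0) | (self.p_value > 1)
        if np.any(bad & np.isfinite(self.p_value)):
            raise ValueError("p values outside [0, 1]")

    def to_volume(self, which: str = "t_value", fill: float = np.nan) -> np.ndarray:
        arr = getattr(self, which)
        vol = np.full(np.asarray(self.mask).shape, fill, dtype=float)
        vol[np.asarray(self.mask, dtype=bool)] = arr
        return vol


def roi_mean_series(stack: BetaStack, roi: np.ndarray) -> np.ndarray:
    """Per-video mean statistic within an ROI.

    ``roi`` is a 3-D boolean mask (must be nonempty and inside the stack's
    mask) or a vector of column indices.
    """
    roi = np.asarray(roi)
    if roi.ndim == 3:
        roi = roi.astype(bool)
        if roi.shape != stack.mask.shape:
            raise ValueError(
                f"ROI shape {roi.shape} differs from mask shape {stack.mask.shape}"
            )
        if np.any(roi & ~stack.mask):
            raise ValueError("ROI extends outside the stack's brain mask")
        if not roi.any():
            raise ValueError("ROI is empty")
        flat = np.cumsum(stack.mask.ravel()) - 1
        cols = flat[roi.ravel() & stack.mask.ravel()]
    else:
        cols = roi.astype(int)
        if cols.size == 0:
            raise ValueError("ROI is empty")
        if cols.min() < 0 or cols.max() >= stack.n_voxels:
            raise ValueError("ROI column indices outside the stack")
    return stack.values[:, cols].mean(axis=1)
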