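"""Spheroid segmentation and frame-to-frame tracking.

Segmentation: Gaussian smoothing, global Otsu threshold, hole filling,
8-connected labelling, small-object and border-object removal.  Global
thresholding is adequate because the imaging model keeps spheroid bodies
brighter than both matrix background and halo.

Tracking: greedy nearest-centroid linking between consecutive frames with
a hard displacement gate.  Objects that disappear simply end their track;
objects that appear start new tracks.  Split/merge events are not
resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

logger = logging.getLogger(__name__)

DEFAULT_SMOOTHING_SIGMA = 1.0  # stronger smoothing erodes the bright body
DEFAULT_MIN_AREA = 200       # px^2; rejects debris below spheroid scale
DEFAULT_MAX_DISPLACEMENT = 15.0  # px per frame


@dataclass
class SpheroidObservation:
    """One segmented object in one frame.

    The mask is stored cropped to its bounding box; ``bbox`` holds the
    (min_row, min_col, max_row, max_col) offsets into the full frame.
    Coordinates are 0-based (row, col); ``frame`` is the 1-based hour.
    """

    frame: int
    object_id: int
    centroid: tuple[float, float]
    area: int
    bbox: tuple[int, int, int, int]
    mask: np.ndarray
    experiment: str = ""
    condition: str = ""
    well: str = ""
    track_id: int = -1

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


@dataclass
class Track:
    """Ordered (frame, object_id) path of one spheroid."""

    track_id: int
    steps: list[tuple[int, int]] = field(default_factory=list)

    @property
    def birth_frame(self) -> int:
        return self.steps[0][0]

    @property
    def death_frame(self) -> int:
        return self.steps[-1][0]

    def __len__(self) -> int:
        return len(self.steps)


def segment_frame(image: np.ndarray,
                  smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA,
                  min_area: int = DEFAULT_MIN_AREA,
                  exclude_border: bool = True,
                  frame: int = 0) -> list[SpheroidObservation]:
    """Segment one grayscale frame into spheroid observations.

    Returns an empty list for blank or all-background frames.
    Deterministic: identical input gives identical labels.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    smoothed = ndimage.gaussian_filter(image, smoothing_sigma)
    if smoothed.max() - smoothed.min() < 1e-9:
        return []
    thr = filters.threshold_otsu(smoothed)
    fg = smoothed > thr
    fg = ndimage.binary_fill_holes(fg)
    labels, _ = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    obs: list[SpheroidObservation] = []
    oid = 0
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        if exclude_border and (r0 == 0 or c0 == 0
                               or r1 == image.shape[0]
                               or c1 == image.shape[1]):
            continue
        obs.append(SpheroidObservation(
            frame=frame, object_id=oid,
            centroid=(float(region.centroid[0]), float(region.centroid[1])),
            area=int(region.area), bbox=(r0, c0, r1, c1),
            mask=region.image.copy()))
        oid += 1
    return obs


def segment_stack(stack: np.ndarray, **kwargs) -> list[SpheroidObservation]:
    """Segment every frame of a (T, H, W) stack; frames are hours 1..T."""
    out: list[SpheroidObservation] = []
    for t in range(stack.shape[0]):
        out.extend(segment_frame(stack[t], frame=t + 1, **kwargs))
    return out


def link_tracks(observations: list[SpheroidObservation],
                max_displacement: float = DEFAULT_MAX_DISPLACEMENT
                ) -> list[Track]:
    """Greedy nearest-centroid linking across consecutive frames.

    Candidate (previous track, current object) pairs are sorted by
    (distance, current object id) and accepted greedily; pairs beyond
    ``max_displacement`` never link.  Unmatched current objects open new
    tracks.  Assigns ``track_id`` on the observations in place.
    """
    by_frame: dict[int, list[SpheroidObservation]] = {}
    for o in observations:
        by_frame.setdefault(o.frame, []).append(o)
    frames = sorted(by_frame)

    tracks: list[Track] = []
    # live tracks from the previous processed frame: [(track, last obs)]
    live: list[tuple[Track, SpheroidObservation]] = []
    prev_frame: int | None = None
    for f in frames:
        cur = by_frame[f]
        if prev_frame is not None and f != prev_frame + 1:
            live = []  # gap in time: no linking across missing frames
        assigned: dict[int, Track] = {}
        if live and cur:
            cand = []
            for ti, (tr, po) in enumerate(live):
                for o in cur:
                    d = float(np.hypot(po.centroid[0] - o.centroid[0],
                                       po.centroid[1] - o.centroid[1]))
                    if d <= max_displacement:
                        cand.append((d, o.object_id, ti, o))
            used_tracks: set[int] = set()
            for d, _, ti, o in sorted(cand, key=lambda x: (x[0], x[1])):
                if ti in used_tracks or o.object_id in assigned:
                    continue
                tr = live[ti][0]
                assigned[o.object_id] = tr
                used_tracks.add(ti)
        new_live: list[tuple[Track, SpheroidObservation]] = []
        for o in cur:
            tr = assigned.get(o.object_id)
            if tr is None:
                tr = Track(track_id=len(tracks))
                tracks.append(tr)
            tr.steps.append((f, o.object_id))
            o.track_id = tr.track_id
            new_live.append((tr, o))
        n_lost = len(live) - len(assigned)
        if n_lost:
            logger.debug("frame %d: %d track(s) ended", f, n_lost)
        live = new_live
        prev_frame = f
    return tracks


def observations_to_dataframe(observations: list[SpheroidObservation]
                              ) -> pd.DataFrame:
    """Tabulate observations (mask referenced by object id, not stored)."""
    return pd.DataFrame([{
        "experiment": o.experiment, "condition": o.condition, "well": o.well,
        "frame": o.frame, "object_id": o.object_id, "track_id": o.track_id,
        "centroid_row": o.centroid[0], "centroid_col": o.centroid[1],
        "area": o.area,
    } for o in observations])


def label_image(observations: list[SpheroidObservation],
                shape: tuple[int, int]) -> np.ndarray:
    """Render one frame's observations as a 16-bit label image
    (label = object_id + 1)."""
    out = np.zeros(shape, dtype=np.uint16)
    for o in observations:
        r0, c0, r1, c1 = o.bbox
        out[r0:r1, c0:c1][o.mask] = o.object_id + 1
    return out
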