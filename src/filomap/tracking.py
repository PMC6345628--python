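"""Tip-punctum detection, frame-to-frame linking and lifetime statistics.

A simplified spot tracker for MYO10 tip puncta in time-lapse movies:
Laplacian-of-Gaussian detection at the scale implied by an expected blob
diameter of 0.8 um with subpixel refinement, followed by frame-to-frame
optimal one-to-one assignment (minimum summed squared displacement) gated
at a linking max distance of 1 um, with gap closing structurally disabled —
a punctum missing for a single frame terminates its track.  Track lifetime,
(last - first + 1) frames times the frame interval, is the proxy for
filopodium stability; per-cell lifetime tables split tracks into stable and
unstable classes expressed as percentages of the cell's track count.

Quality unit: the detector reports a scale-normalized LoG peak response
divided by a fixed calibration divisor chosen so a reference punctum (peak
30000 over background 2000, FWHM 0.6 um at 0.16 um pixels) scores ~30 on
the same order as interactive tracking tools; the threshold is fully
configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .config import TrackingParams
from .enrichment import tukey_stats
from .errors import InsufficientDataError, ParameterError

logger = logging.getLogger("filomap")

__all__ = ["Detection", "SpotTrack", "detect_spots", "link_tracks",
           "lifetime_distribution", "track_movie"]

#: LoG scale from blob diameter: sigma = diameter / (2 * sqrt(2))
_LOG_SIGMA_FACTOR = 2.0 * math.sqrt(2.0)

#: Calibration divisor of the quality unit (see module docstring).
QUALITY_DIVISOR = 447.0


@dataclass
class Detection:
    """One subpixel spot detection in a single frame."""

    frame: int
    x_px: float
    y_px: float
    quality: float

    def position_um(self, pixel_size_um: float) -> tuple[float, float]:
        return self.x_px * pixel_size_um, self.y_px * pixel_size_um


@dataclass
class SpotTrack:
    """A linked trajectory: consecutive frames, gated displacements."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [d.frame for d in self.detections]

    @property
    def n_frames(self) -> int:
        return len(self.detections)

    def lifetime_s(self, frame_interval_s: float) -> float:
        """(last - first + 1) frames times the frame interval."""
        return (self.frames[-1] - self.frames[0] + 1) * frame_interval_s


def _subpixel_offset(r: np.ndarray, y: int, x: int) -> tuple[float, float]:
    """Quadratic-fit offset of a response maximum within its 3x3 neighborhood."""
    def axis_offset(m1, c, p1):
        denom = m1 - 2 * c + p1
        if denom >= 0:  # not a concave peak along this axis
            return 0.0
        return float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))

    dy = axis_offset(r[y - 1, x], r[y, x], r[y + 1, x])
    dx = axis_offset(r[y, x - 1], r[y, x], r[y, x + 1])
    return dx, dy


def detect_spots(
    frame: np.ndarray,
    params: TrackingParams | None = None,
    pixel_size_um: float = 0.16,
    frame_index: int = 0,
) -> list[Detection]:
    """LoG spot detection with subpixel localization on one frame.

    The response is the negated, scale-normalized Laplacian of Gaussian at
    sigma = blob_diameter / (2*sqrt(2)); strict local maxima above the
    quality threshold are kept and refined by a quadratic fit to the 3x3
    response neighborhood.
    """
    params = params or TrackingParams()
    if pixel_size_um <= 0:
        raise ParameterError("pixel_size_um must be positive")
    if params.blob_diameter_um / pixel_size_um < 2.0:
        raise ParameterError(
            f"blob diameter {params.blob_diameter_um} um is below 2 pixels at "
            f"{pixel_size_um} um/px"
        )
    sigma_px = params.blob_diameter_um / _LOG_SIGMA_FACTOR / pixel_size_um
    img = np.asarray(frame, dtype=np.float64)
    resp = -ndimage.gaussian_laplace(img, sigma_px) * sigma_px**2
    quality = resp / QUALITY_DIVISOR

    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbor_max = ndimage.maximum_filter(resp, footprint=footprint, mode="nearest")
    is_peak = (resp > neighbor_max) & (quality > params.quality_threshold)
    is_peak[0, :] = is_peak[-1, :] = False
    is_peak[:, 0] = is_peak[:, -1] = False

    detections = []
    for y, x in zip(*np.nonzero(is_peak)):
        dx, dy = _subpixel_offset(resp, y, x)
        detections.append(Detection(frame=frame_index, x_px=x + dx, y_px=y + dy,
                                    quality=float(quality[y, x])))
    return detections


def link_tracks(
    detections_per_frame: Sequence[Sequence[Detection]],
    params: TrackingParams | None = None,
    pixel_size_um: float = 0.16,
) -> list[SpotTrack]:
    """Frame-to-frame optimal assignment of detections into tracks.

    Between consecutive frames the one-to-one assignment minimizing summed
    squared displacement is solved exactly; links longer than the max link
    distance are forbidden.  Unmatched detections start new tracks and
    unmatched tracks terminate (no gap closing).  Every detection belongs to
    exactly one track.
    """
    params = params or TrackingParams()
    gate2 = (params.max_link_distance_um / pixel_size_um) ** 2
    big = 1e12
    tracks: list[SpotTrack] = []
    active: list[SpotTrack] = []
    next_id = 0
    for dets in detections_per_frame:
        dets = list(dets)
        if active and dets:
            prev = np.array([[t.detections[-1].x_px, t.detections[-1].y_px]
                             for t in active])
            curr = np.array([[d.x_px, d.y_px] for d in dets])
            cost = ((prev[:, None, :] - curr[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(cost <= gate2, cost, big)
            rows, cols = optimize.linear_sum_assignment(cost)
            matched_tracks, matched_dets = set(), set()
            for r, c in zip(rows, cols):
                if cost[r, c] < big:
                    active[r].detections.append(dets[c])
                    matched_tracks.add(r)
                    matched_dets.add(c)
            still_active = [t for i, t in enumerate(active) if i in matched_tracks]
            for c, d in enumerate(dets):
                if c not in matched_dets:
                    t = SpotTrack(next_id, [d])
                    next_id += 1
                    tracks.append(t)
                    still_active.append(t)
            active = still_active
        else:
            new = []
            for d in dets:
                t = SpotTrack(next_id, [d])
                next_id += 1
                tracks.append(t)
                new.append(t)
            active = new
    return tracks


def track_movie(
    stack: np.ndarray,
    params: TrackingParams | None = None,
    pixel_size_um: float = 0.16,
) -> list[SpotTrack]:
    """Detect and link spots across a (T, H, W) movie stack."""
    params = params or TrackingParams()
    dets = [detect_spots(stack[t], params, pixel_size_um, frame_index=t)
            for t in range(stack.shape[0])]
    tracks = link_tracks(dets, params, pixel_size_um)
    logger.info("tracked %d spots into %d tracks over %d frames",
                sum(len(d) for d in dets), len(tracks), stack.shape[0])
    return tracks


def lifetime_distribution(
    tracks_by_cell: dict[str, Sequence[SpotTrack]] | Sequence[SpotTrack],
    params: TrackingParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell lifetime classes as percentages of each cell's track count.

    Lifetimes are split at ``params.stable_cutoff_s`` into unstable and
    stable classes; each class is expressed as a percentage of the cell's
    total number of tracks, and the percentages are summarized across cells
    with Tukey statistics.  Returns (per-cell table, summary dict with the
    Tukey stats per class and the pooled lifetime list).
    """
    params = params or TrackingParams()
    if not isinstance(tracks_by_cell, dict):
        tracks_by_cell = {"cell_0": list(tracks_by_cell)}
    rows = []
    all_lifetimes = []
    for cell_id, tracks in tracks_by_cell.items():
        if not tracks:
            logger.info("cell %s excluded: zero tracks", cell_id)
            continue
        lifetimes = np.array([t.lifetime_s(params.frame_interval_s) for t in tracks])
        all_lifetimes.extend(lifetimes.tolist())
        n = len(lifetimes)
        n_stable = int(np.count_nonzero(lifetimes >= params.stable_cutoff_s))
        rows.append(dict(
            cell_id=cell_id, n_tracks=n,
            pct_stable=100.0 * n_stable / n,
            pct_unstable=100.0 * (n - n_stable) / n,
            median_lifetime_s=float(np.median(lifetimes)),
        ))
    if not rows:
        raise InsufficientDataError("no cells with tracks")
    table = pd.DataFrame(rows)
    summary = {
        "stable_cutoff_s": params.stable_cutoff_s,
        "n_cells": len(table),
        "lifetimes_s": all_lifetimes,
    }
    for cls in ("pct_stable", "pct_unstable"):
        try:
            summary[cls] = tukey_stats(table[cls])
        except InsufficientDataError:
            summary[cls] = None
    return table, summary
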