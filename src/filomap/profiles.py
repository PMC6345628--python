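"""Line-intensity profile sampling along tip-to-base filopodium traces.

A trace is an ordered polyline drawn from the filopodium tip to its base
(the intersection with the lamellipodium); traces are inputs, drawn by the
user or by the simulator, never auto-detected.  Profiles are sampled at
~1-pixel spacing with bilinear interpolation and single-pixel width.

Coordinate convention: 0-based pixel centers, x rightward, y downward.
Sample 0 is always the tip.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, IntegrityError
from .imaging import MultiChannelImage

logger = logging.getLogger("filomap")

__all__ = [
    "FilopodiumTrace", "LineProfile", "sample_profile", "profile_length",
    "export_profiles", "import_profiles", "write_traces_csv", "read_traces_csv",
]

_CSV_HEADER = (
    "# filomap line-intensity profiles\n"
    "# coordinates: 0-based pixel centers, x rightward, y downward\n"
    "# sampling: ~1 px spacing along the polyline, bilinear interpolation, 1 px width\n"
    "# sample_index 0 = filopodium tip; distance_um measured from the tip\n"
)


@dataclass
class FilopodiumTrace:
    """Ordered tip-to-base polyline in pixel coordinates.

    ``vertices`` is an (N, 2) array of (x, y); the first vertex is the tip,
    the last the base. Consecutive vertices must be distinct.
    """

    filopodium_id: str
    vertices: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError("vertices must be an (N, 2) array of (x, y)")
        if len(self.vertices) < 2:
            raise GeometryError("a trace needs at least 2 vertices")
        steps = np.diff(self.vertices, axis=0)
        if np.any(np.all(steps == 0, axis=1)):
            raise GeometryError("consecutive trace vertices must be distinct")
        if self.pixel_size_um <= 0:
            raise GeometryError("pixel_size_um must be positive")

    @property
    def arc_length_px(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    @property
    def arc_length_um(self) -> float:
        """Polyline arc length, tip to base, in micrometres."""
        return self.arc_length_px * self.pixel_size_um

    def reversed(self) -> "FilopodiumTrace":
        """The same polyline traversed base-to-tip (for symmetry checks)."""
        return FilopodiumTrace(self.filopodium_id, self.vertices[::-1].copy(),
                               self.pixel_size_um)


@dataclass
class LineProfile:
    """Per-channel intensities sampled along one trace, tip first."""

    filopodium_id: str
    intensities: dict[str, np.ndarray]
    sample_spacing_um: float

    def __post_init__(self) -> None:
        self.intensities = {k: np.asarray(v, dtype=np.float64)
                            for k, v in self.intensities.items()}
        lengths = {v.size for v in self.intensities.values()}
        if not self.intensities or any(v.size == 0 for v in self.intensities.values()):
            raise IntegrityError("profile has an empty channel vector")
        if len(lengths) != 1:
            raise IntegrityError("all channel vectors must have equal length")
        if self.n_samples < 2:
            raise IntegrityError("a profile needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return next(iter(self.intensities.values())).size

    @property
    def channels(self) -> list[str]:
        return list(self.intensities)


def _sample_points(trace: FilopodiumTrace) -> tuple[np.ndarray, np.ndarray, float]:
    """Equally spaced (x, y) sample positions covering the full polyline.

    The spacing is the arc length divided into ``round(arc_length_px)``
    steps, i.e. as close to 1 pixel as possible while keeping both the tip
    and the base as exact sample positions — which also makes sampling a
    reversed trace yield the exactly reversed profile.
    """
    seg = np.diff(trace.vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n_samples = max(2, int(round(total)) + 1)
    s = np.linspace(0.0, total, n_samples)
    xs = np.interp(s, cum, trace.vertices[:, 0])
    ys = np.interp(s, cum, trace.vertices[:, 1])
    return xs, ys, total / (n_samples - 1)


def sample_profile(
    image: MultiChannelImage,
    trace: FilopodiumTrace,
    require_normalized: bool = True,
) -> LineProfile:
    """Sample all channels along a trace at ~1-pixel spacing, tip first.

    Single-pixel width with bilinear interpolation, mirroring the line-profile
    convention of the interactive tooling the procedure derives from. Warns
    (or can be silenced) if the image has not been contrast-normalized.

    Raises
    ------
    GeometryError
        If any trace vertex falls outside the pixel-center bounds of the
        image.
    """
    h, w = image.shape
    v = trace.vertices
    if (v[:, 0].min() < 0 or v[:, 0].max() > w - 1
            or v[:, 1].min() < 0 or v[:, 1].max() > h - 1):
        raise GeometryError(
            f"trace {trace.filopodium_id!r} extends outside the image "
            f"({w}x{h} px)"
        )
    if require_normalized and not image.normalized:
        warnings.warn(
            "sampling profiles from an image that has not been auto-adjusted; "
            "detection thresholds assume normalized intensities",
            stacklevel=2,
        )
    xs, ys, spacing_px = _sample_points(trace)
    intensities = {}
    for name in image.channel_names:
        ch = image.channel(name).astype(np.float64)
        intensities[name] = ndimage.map_coordinates(ch, [ys, xs], order=1, mode="nearest")
    return LineProfile(
        filopodium_id=trace.filopodium_id,
        intensities=intensities,
        sample_spacing_um=spacing_px * trace.pixel_size_um,
    )


def profile_length(profile: LineProfile) -> float:
    """Filopodium length in micrometres, read directly off the profile."""
    return (profile.n_samples - 1) * profile.sample_spacing_um


def export_profiles(
    profiles: Sequence[LineProfile],
    path: str | Path,
    poi_name: str = "POI",
    cell_id: str = "cell_0",
) -> pd.DataFrame:
    """Write profiles as a long-format CSV and return the table.

    Columns: poi_name, cell_id, filopodium_id, channel, sample_index,
    distance_um, intensity. The export is re-importable losslessly via
    :func:`import_profiles`.
    """
    if not profiles:
        raise IntegrityError("no profiles to export")
    rows = []
    for p in profiles:
        for channel, values in p.intensities.items():
            for i, val in enumerate(values):
                rows.append((poi_name, cell_id, p.filopodium_id, channel,
                             i, i * p.sample_spacing_um, float(val)))
    df = pd.DataFrame(rows, columns=[
        "poi_name", "cell_id", "filopodium_id", "channel",
        "sample_index", "distance_um", "intensity",
    ])
    dup = df.duplicated(subset=["filopodium_id", "channel", "sample_index"])
    if dup.any():
        raise IntegrityError(
            "duplicate (filopodium_id, channel, sample_index) rows in export"
        )
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER)
        df.to_csv(fh, index=False)
    logger.info("exported %d profiles (%d rows) to %s", len(profiles), len(df), path)
    return df


def import_profiles(path: str | Path) -> list[LineProfile]:
    """Re-import a profile CSV written by :func:`export_profiles`."""
    df = pd.read_csv(path, comment="#")
    profiles = []
    for fid, group in df.groupby("filopodium_id", sort=False):
        intensities = {}
        spacing = np.nan
        for channel, cg in group.groupby("channel", sort=False):
            cg = cg.sort_values("sample_index")
            if cg["sample_index"].duplicated().any():
                raise IntegrityError(f"duplicate sample_index for {fid}/{channel}")
            intensities[channel] = cg["intensity"].to_numpy()
            if len(cg) > 1:
                spacing = float(np.diff(cg["distance_um"].to_numpy()).mean())
        profiles.append(LineProfile(str(fid), intensities, spacing))
    return profiles


def write_traces_csv(traces: Iterable[FilopodiumTrace], path: str | Path) -> None:
    """Write traces as CSV rows (filopodium_id, vertex_index, x_px, y_px), tip first."""
    rows = []
    for t in traces:
        for i, (x, y) in enumerate(t.vertices):
            rows.append((t.filopodium_id, i, x, y, t.pixel_size_um))
    pd.DataFrame(rows, columns=[
        "filopodium_id", "vertex_index", "x_px", "y_px", "pixel_size_um",
    ]).to_csv(path, index=False)


def read_traces_csv(path: str | Path, pixel_size_um: float | None = None) -> list[FilopodiumTrace]:
    """Read a trace CSV (tip-to-base row order per filopodium)."""
    df = pd.read_csv(path, comment="#")
    traces = []
    for fid, group in df.groupby("filopodium_id", sort=False):
        group = group.sort_values("vertex_index")
        px = pixel_size_um
        if px is None:
            if "pixel_size_um" not in group:
                raise IntegrityError("trace CSV lacks pixel_size_um; pass it explicitly")
            px = float(group["pixel_size_um"].iloc[0])
        traces.append(FilopodiumTrace(
            str(fid), group[["x_px", "y_px"]].to_numpy(), px,
        ))
    return traces
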