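"""Synthetic filopodia scenes, profile cohorts and tip-punctum movies.

No raw microscopy ships with the package, so every downstream stage is
exercised against simulated data with known ground truth.  The generator
emulates the geometry and contrast of SIM imaging of filopodia: protrusions
1-5 um long emanating from a bright cell body, rendered as Gaussian ridges
of 150 nm FWHM (mid-range of the 50-200 nm physical width), a tip-marker
(MYO10) channel with an isotropic Gaussian punctum of 300 nm FWHM at each
tip, and a protein-of-interest channel whose intensity along the filopodium
follows one of five localization classes: tip-enriched, shaft-enriched,
shaft-subdomain, uniform, or absent.  Camera noise is Poisson shot noise on
the signal followed by additive Gaussian read noise, on the 0-65535 scale.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import INTENSITY_MAX
from .errors import GeometryError, ParameterError
from .imaging import MultiChannelImage
from .profiles import FilopodiumTrace

logger = logging.getLogger("filomap")

__all__ = [
    "LocalizationClass", "IntensityParams", "NoiseParams", "SyntheticScene",
    "LifetimeMix", "localization_class", "generate_traces", "render_scene",
    "generate_binned_cohort", "generate_tip_movie", "write_movie", "read_movie",
]

# Gaussian ridge / punctum geometry (FWHM -> sigma factor 2*sqrt(2*ln 2))
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))
RIDGE_FWHM_UM = 0.150
TIP_PUNCTUM_FWHM_UM = 0.300
DEFAULT_PIXEL_SIZE_UM = 0.04  # typical SIM sampling

#: fraction of the filopodium length (from the tip) that the generator
#: treats as "tip" when a localization class elevates or depletes the tip;
#: roughly 6 of 40 bins.
TIP_FRACTION = 0.15


@dataclass
class LocalizationClass:
    """Ground-truth localization behaviour of a protein within filopodia.

    ``tip_fold`` is the ratio of tip to shaft intensity for filopodia where
    the protein is present (> 1 tip-enriched, < 1 shaft-enriched, 1 flat);
    ``detection_prob`` the fraction of filopodia carrying the protein at
    all; ``subdomain_fraction`` the portion of the shaft, measured from the
    base, that the protein occupies when ``name == "shaft_subdomain"``.
    """

    name: str
    tip_fold: float = 1.0
    detection_prob: float = 1.0
    subdomain_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.name not in ("tip_enriched", "shaft_enriched",
                             "shaft_subdomain", "uniform", "absent"):
            raise ParameterError(f"unknown localization class {self.name!r}")
        if self.tip_fold <= 0:
            raise ParameterError("tip_fold must be positive")
        if not (0 <= self.detection_prob <= 1):
            raise ParameterError("detection_prob must lie in [0, 1]")
        if not (0 < self.subdomain_fraction <= 1):
            raise ParameterError("subdomain_fraction must lie in (0, 1]")


_CLASS_PRESETS = {
    "tip_enriched": dict(tip_fold=4.0, detection_prob=0.9),
    "shaft_enriched": dict(tip_fold=0.25, detection_prob=0.9),
    "shaft_subdomain": dict(tip_fold=0.25, detection_prob=0.8,
                            subdomain_fraction=0.5),
    "uniform": dict(tip_fold=1.0, detection_prob=0.95),
    "absent": dict(tip_fold=1.0, detection_prob=0.05),
}


def localization_class(name: str, **overrides) -> LocalizationClass:
    """A :class:`LocalizationClass` preset by name, with optional overrides."""
    if name not in _CLASS_PRESETS:
        raise ParameterError(f"unknown localization class {name!r}")
    kwargs = dict(_CLASS_PRESETS[name])
    kwargs.update(overrides)
    return LocalizationClass(name=name, **kwargs)


@dataclass
class IntensityParams:
    """Absolute channel levels on the 0-65535 scale.

    ``shaft_level`` is the on-ridge POI intensity along the shaft (tips are
    scaled by the class ``tip_fold``), ``tip_peak`` the MYO10 punctum peak,
    ``membrane_level`` the cell-body plateau that anchors the downstream
    contrast normalization, ``background`` the off-cell level.
    """

    tip_peak: float = 30000.0
    shaft_level: float = 15000.0
    background: float = 1000.0
    membrane_level: float = 45000.0

    def __post_init__(self) -> None:
        for name in ("tip_peak", "shaft_level", "background", "membrane_level"):
            v = getattr(self, name)
            if not (0 <= v <= INTENSITY_MAX):
                raise ParameterError(f"{name} outside [0, {INTENSITY_MAX}]: {v}")


@dataclass
class NoiseParams:
    """Poisson shot noise (counts = intensity / gain) then Gaussian read noise.

    ``poisson_gain`` of 0 disables shot noise; ``gaussian_sd`` of 0 disables
    read noise.
    """

    poisson_gain: float = 4.0
    gaussian_sd: float = 200.0

    @classmethod
    def off(cls) -> "NoiseParams":
        return cls(poisson_gain=0.0, gaussian_sd=0.0)


@dataclass
class LifetimeMix:
    """Two-population tip-punctum lifetime model (stable vs unstable)."""

    stable_fraction: float = 0.5
    mean_stable_s: float = 180.0
    mean_unstable_s: float = 25.0

    def __post_init__(self) -> None:
        if not (0 <= self.stable_fraction <= 1):
            raise ParameterError("stable_fraction must lie in [0, 1]")


@dataclass
class SyntheticScene:
    """A rendered field of view with its traces and per-filopodium truth."""

    image: MultiChannelImage
    traces: list[FilopodiumTrace]
    truth: pd.DataFrame  # filopodium_id, class_name, present, tip_fold, length_um
    seed: int

    def __post_init__(self) -> None:
        if len(self.truth) != len(self.traces):
            raise GeometryError("truth must have one record per trace")


def generate_traces(
    n: int,
    length_range_um: tuple[float, float] = (1.0, 5.0),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    curvature: float = 0.15,
    seed: int = 0,
    image_shape: tuple[int, int] = (512, 512),
    edge_frac: float = 0.25,
    margin_px: float = 6.0,
) -> list[FilopodiumTrace]:
    """Random tip-to-base polylines protruding from the cell edge.

    Base points are spread evenly (with jitter) along a vertical cell edge at
    ``edge_frac`` of the image width; each filopodium grows outward with a
    heading that wanders with standard deviation ``curvature`` radians per
    micrometre of arc (0 = perfectly straight).  Arc lengths are uniform in
    ``length_range_um`` and exact; vertices are spaced ~1 pixel apart with
    the first vertex at the tip.
    """
    if n <= 0:
        raise ParameterError("n must be positive")
    lo, hi = length_range_um
    if not (0.5 <= lo <= hi <= 10.0):
        raise ParameterError("length_range_um must satisfy 0.5 <= lo <= hi <= 10 um")
    if pixel_size_um <= 0:
        raise ParameterError("pixel_size_um must be positive")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    edge_x = edge_frac * w
    base_ys = np.linspace(margin_px, h - 1 - margin_px, n)
    base_ys = base_ys + rng.uniform(-0.4, 0.4, size=n) * (base_ys[1] - base_ys[0] if n > 1 else 1.0)
    base_ys = np.clip(base_ys, margin_px, h - 1 - margin_px)

    traces = []
    for k in range(n):
        length_um = float(rng.uniform(lo, hi))
        length_px = length_um / pixel_size_um
        n_vertices = max(2, int(round(length_px)))
        step_um = length_um / (n_vertices - 1)
        step_px = step_um / pixel_size_um
        heading = float(rng.uniform(-0.35, 0.35))
        x, y = edge_x, float(base_ys[k])
        pts = [(x, y)]
        for _ in range(n_vertices - 1):
            if curvature > 0:
                heading += float(rng.normal(0.0, curvature * step_um))
            dx = math.cos(heading) * step_px
            dy = math.sin(heading) * step_px
            # steer back inside the margins rather than leaving the frame
            if not (margin_px <= y + dy <= h - 1 - margin_px):
                heading = -heading
                dy = -dy
            if x + dx > w - 1 - margin_px:
                heading = math.pi - heading
                dx = -dx
            x, y = x + dx, y + dy
            pts.append((x, y))
        vertices = np.asarray(pts)[::-1]  # tip first
        traces.append(FilopodiumTrace(f"filo_{k:04d}", vertices, pixel_size_um))
    return traces


def _poi_level(t_frac: np.ndarray, cls: LocalizationClass,
               intensity: IntensityParams) -> np.ndarray:
    """Absolute POI level at arc fraction ``t_frac`` (0 = tip) for a present protein."""
    s = intensity.shaft_level
    if cls.name == "uniform":
        return np.full_like(t_frac, s)
    if cls.name in ("tip_enriched", "shaft_enriched"):
        return np.where(t_frac <= TIP_FRACTION, cls.tip_fold * s, s)
    if cls.name == "shaft_subdomain":
        # occupies the shaft from the base inward; tip region empty
        return np.where(t_frac >= 1.0 - cls.subdomain_fraction, s,
                        intensity.background)
    return np.full_like(t_frac, intensity.background)  # absent but "present" never hits


def _splat_ridge(canvas: np.ndarray, trace: FilopodiumTrace,
                 level_at: np.ndarray | float, sigma_px: float,
                 background: float) -> None:
    """Max-composite a Gaussian ridge following ``trace`` onto ``canvas``.

    ``level_at`` gives the on-centerline absolute intensity per arc fraction
    (callable semantics are inlined: pass a per-vertex-arc level function
    result via :func:`_poi_level` on nearest-point arc fractions).
    """
    h, w = canvas.shape
    v = trace.vertices
    pad = int(math.ceil(4 * sigma_px)) + 1
    x0 = max(0, int(math.floor(v[:, 0].min())) - pad)
    x1 = min(w - 1, int(math.ceil(v[:, 0].max())) + pad)
    y0 = max(0, int(math.floor(v[:, 1].min())) - pad)
    y1 = min(h - 1, int(math.ceil(v[:, 1].max())) + pad)
    if x1 < x0 or y1 < y0:
        return
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(np.float64)

    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    best_d2 = np.full(len(pts), np.inf)
    best_arc = np.zeros(len(pts))
    for a, ab, L, s0 in zip(v[:-1], seg, seg_len, cum[:-1]):
        t = np.clip(((pts - a) @ ab) / (L * L), 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = np.sum((pts - proj) ** 2, axis=1)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_arc[closer] = s0 + t[closer] * L

    t_frac = best_arc / total
    level = level_at(t_frac) if callable(level_at) else np.full(len(pts), level_at)
    contrib = background + (level - background) * np.exp(-best_d2 / (2 * sigma_px**2))
    block = canvas[y0:y1 + 1, x0:x1 + 1]
    np.maximum(block, contrib.reshape(block.shape), out=block)


def _splat_punctum(canvas: np.ndarray, center: np.ndarray, peak: float,
                   sigma_px: float, background: float) -> None:
    """Max-composite an isotropic Gaussian punctum onto ``canvas``."""
    h, w = canvas.shape
    pad = int(math.ceil(4 * sigma_px)) + 1
    cx, cy = center
    x0, x1 = max(0, int(cx) - pad), min(w - 1, int(cx) + pad)
    y0, y1 = max(0, int(cy) - pad), min(h - 1, int(cy) + pad)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    contrib = background + (peak - background) * np.exp(-d2 / (2 * sigma_px**2))
    block = canvas[y0:y1 + 1, x0:x1 + 1]
    np.maximum(block, contrib, out=block)


def _apply_noise(clean: np.ndarray, noise: NoiseParams,
                 rng: np.random.Generator) -> np.ndarray:
    out = clean.astype(np.float64)
    if noise.poisson_gain > 0:
        out = rng.poisson(out / noise.poisson_gain) * noise.poisson_gain
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    return np.clip(np.round(out), 0, INTENSITY_MAX).astype(np.uint16)


def render_scene(
    traces: Sequence[FilopodiumTrace],
    poi_class: LocalizationClass,
    intensity: IntensityParams | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    image_shape: tuple[int, int] = (512, 512),
    edge_frac: float = 0.25,
) -> SyntheticScene:
    """Render a 3-channel (POI, MYO10, actin) 16-bit field of view.

    The cell body is a bright plateau filling the left ``edge_frac`` of the
    frame (the "brightest cellular structure" that contrast normalization
    keys on).  Filopodia are Gaussian ridges; the POI channel follows
    ``poi_class`` with the protein present in a ``detection_prob`` fraction
    of filopodia, the MYO10 channel carries a punctum at each tip, and the
    actin channel a uniform ridge along each filopodium.
    """
    if not traces:
        raise ParameterError("traces must be non-empty")
    intensity = intensity or IntensityParams()
    noise = noise or NoiseParams.off()
    rng = np.random.default_rng(seed)
    h, w = image_shape
    for t in traces:
        v = t.vertices
        if (v[:, 0].min() < 0 or v[:, 0].max() > w - 1
                or v[:, 1].min() < 0 or v[:, 1].max() > h - 1):
            raise GeometryError(f"trace {t.filopodium_id!r} outside image bounds")

    px = traces[0].pixel_size_um
    sigma_ridge = RIDGE_FWHM_UM / _FWHM / px
    sigma_spot = TIP_PUNCTUM_FWHM_UM / _FWHM / px
    edge_x = edge_frac * w

    bg = intensity.background
    channels = {name: np.full((h, w), bg, dtype=np.float64)
                for name in ("poi", "myo10", "actin")}
    for ch in channels.values():
        ch[:, : int(edge_x)] = intensity.membrane_level

    # per-image brightness variation (expression level / illumination); a
    # dimming-only factor so class-defined intensity ratios survive clipping
    brightness = float(rng.uniform(0.75, 1.0))

    present = rng.random(len(traces)) < poi_class.detection_prob
    records = []
    for trace, is_present in zip(traces, present):
        if is_present:
            _splat_ridge(channels["poi"], trace,
                         lambda tf: _poi_level(tf, poi_class, intensity),
                         sigma_ridge, bg)
        _splat_ridge(channels["actin"], trace, 1.2 * intensity.shaft_level,
                     sigma_ridge, bg)
        _splat_punctum(channels["myo10"], trace.vertices[0],
                       intensity.tip_peak, sigma_spot, bg)
        records.append(dict(
            filopodium_id=trace.filopodium_id, class_name=poi_class.name,
            present=bool(is_present), tip_fold=poi_class.tip_fold,
            length_um=trace.arc_length_um,
        ))

    data = np.stack([channels["poi"], channels["myo10"], channels["actin"]])
    data = data * brightness
    noisy = np.stack([_apply_noise(c, noise, rng) for c in data])
    image = MultiChannelImage(noisy, ["poi", "myo10", "actin"], px)
    return SyntheticScene(image=image, traces=list(traces),
                          truth=pd.DataFrame(records), seed=seed)


def generate_binned_cohort(
    n: int,
    poi_class: LocalizationClass,
    noise_sd: float = 0.0,
    seed: int = 0,
    shaft_level: float = 20000.0,
    background: float = 500.0,
    n_bins: int = 40,
    tip_last_bin: int = 6,
    poi_name: Optional[str] = None,
):
    """Profile-level shortcut: n 40-bin profiles drawn directly from a class.

    Bypasses rendering entirely: present filopodia (a ``detection_prob``
    fraction) get the class's bin pattern on the 0-65535 scale — tip bins
    scaled by ``tip_fold`` for tip/shaft-enriched classes — and absent ones
    sit at ``background``.  Gaussian noise of ``noise_sd`` is added and
    clipped; with noise off the patterns are exact.
    """
    from .mapping import BinnedProfile, POICohort  # avoid module cycle

    if n <= 0:
        raise ParameterError("n must be positive")
    rng = np.random.default_rng(seed)
    present = rng.random(n) < poi_class.detection_prob

    base = np.full(n_bins, shaft_level)
    if poi_class.name in ("tip_enriched", "shaft_enriched"):
        base[:tip_last_bin] = poi_class.tip_fold * shaft_level
    elif poi_class.name == "shaft_subdomain":
        base[:] = background
        n_shaft = n_bins - tip_last_bin
        k = int(round(poi_class.subdomain_fraction * n_shaft))
        if k > 0:
            base[n_bins - k:] = shaft_level
    elif poi_class.name == "absent":
        pass  # present (rare false positive) filopodia show a uniform level
    # keep the pattern inside the 16-bit range without clipping, like an
    # exposure adjustment: scaling preserves every ground-truth ratio
    if base.max() > INTENSITY_MAX:
        base = base * (INTENSITY_MAX / base.max())
    absent_pattern = np.full(n_bins, background)

    profiles, lengths = [], []
    for i in range(n):
        bins = base.copy() if present[i] else absent_pattern.copy()
        if noise_sd > 0:
            bins = bins + rng.normal(0.0, noise_sd, size=n_bins)
        bins = np.clip(bins, 0, INTENSITY_MAX)
        profiles.append(BinnedProfile(f"filo_{i:04d}", bins, n_samples=n_bins))
        lengths.append(float(rng.uniform(1.0, 5.0)))
    return POICohort(poi_name or poi_class.name, profiles, lengths_um=lengths)


def generate_tip_movie(
    n_spots: int,
    lifetime_mix: LifetimeMix | None = None,
    frame_interval_s: float = 5.0,
    n_frames: int = 60,
    drift_um_per_frame: float = 0.0,
    pixel_size_um: float = 0.16,
    image_shape: tuple[int, int] = (256, 256),
    peak: float = 30000.0,
    background: float = 2000.0,
    punctum_fwhm_um: float = 0.6,
    noise: NoiseParams | None = None,
    max_link_distance_um: float = 1.0,
    birth_window_frac: float = 1 / 3,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """A single-channel 16-bit movie of drifting tip puncta plus truth tracks.

    Each spot is born in the first third of the movie, lives an exponential
    lifetime drawn from the stable/unstable mixture, and drifts with a
    constant heading at ``drift_um_per_frame`` (so inter-frame displacement
    never exceeds that bound).  Returns the (T, H, W) stack and a truth
    table with one row per spot per live frame (track_id, frame, x_um, y_um)
    plus birth/death/lifetime columns.
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be at least 2")
    if frame_interval_s <= 0:
        raise ParameterError("frame_interval_s must be positive")
    if n_spots <= 0:
        raise ParameterError("n_spots must be positive")
    lifetime_mix = lifetime_mix or LifetimeMix()
    noise = noise or NoiseParams.off()
    rng = np.random.default_rng(seed)
    h, w = image_shape
    sigma_px = punctum_fwhm_um / _FWHM / pixel_size_um

    area_um2 = (h * pixel_size_um) * (w * pixel_size_um)
    if n_spots / area_um2 > 1.0 / (math.pi * max_link_distance_um**2):
        warnings.warn(
            "spot density is high relative to the linking max distance; "
            "tracks may be ambiguous", stacklevel=2,
        )

    margin_px = max(4.0, 4 * sigma_px, n_frames * drift_um_per_frame / pixel_size_um / 4)
    margin_px = min(margin_px, 0.4 * min(h, w))
    rows = []
    for k in range(n_spots):
        birth = int(rng.integers(0, max(1, int(n_frames * birth_window_frac))))
        stable = rng.random() < lifetime_mix.stable_fraction
        mean = lifetime_mix.mean_stable_s if stable else lifetime_mix.mean_unstable_s
        drawn_s = float(rng.exponential(mean))
        n_live = max(1, int(math.ceil(drawn_s / frame_interval_s)))
        death = min(birth + n_live - 1, n_frames - 1)
        x = float(rng.uniform(margin_px, w - 1 - margin_px))
        y = float(rng.uniform(margin_px, h - 1 - margin_px))
        heading = float(rng.uniform(0, 2 * math.pi))
        step_px = drift_um_per_frame / pixel_size_um
        for frame in range(birth, death + 1):
            rows.append(dict(
                track_id=k, frame=frame,
                x_um=x * pixel_size_um, y_um=y * pixel_size_um,
                x_px=x, y_px=y, birth=birth, death=death, stable=stable,
                lifetime_s=(death - birth + 1) * frame_interval_s,
                drawn_lifetime_s=drawn_s,
            ))
            nx, ny = x + math.cos(heading) * step_px, y + math.sin(heading) * step_px
            if not (2.0 <= nx <= w - 3.0):
                heading = math.pi - heading
                nx = x + math.cos(heading) * step_px
            if not (2.0 <= ny <= h - 3.0):
                heading = -heading
                ny = y + math.sin(heading) * step_px
            x, y = nx, ny
    truth = pd.DataFrame(rows)

    stack = np.empty((n_frames, h, w), dtype=np.uint16)
    for frame in range(n_frames):
        canvas = np.full((h, w), background, dtype=np.float64)
        live = truth[truth["frame"] == frame]
        for _, spot in live.iterrows():
            _splat_punctum(canvas, np.array([spot.x_px, spot.y_px]),
                           peak, sigma_px, background)
        stack[frame] = _apply_noise(canvas, noise, rng)
    return stack, truth


def write_movie(stack: np.ndarray, path: str | Path, pixel_size_um: float,
                frame_interval_s: float) -> None:
    """Write a (T, H, W) uint16 stack as a multi-frame TIFF with calibration."""
    tifffile.imwrite(str(path), stack.astype(np.uint16), metadata={
        "axes": "TYX",
        "pixel_size_um": float(pixel_size_um),
        "frame_interval_s": float(frame_interval_s),
    })


def read_movie(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-frame TIFF movie; returns the stack and its metadata."""
    with tifffile.TiffFile(str(path)) as tif:
        stack = tif.asarray()
        meta = dict(tif.shaped_metadata[0]) if tif.shaped_metadata else {}
    if stack.ndim == 2:
        stack = stack[None]
    return stack, meta
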