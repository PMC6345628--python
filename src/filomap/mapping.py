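"""The 40-bin filopodia map: binning, detection calls, categories, heatmap.

Filopodia differ in length, so each tip-to-base profile is reduced to a
fixed 40-bin representation: sample ``i`` of ``n`` (0-based) joins bin
``floor(i * 40 / n)`` and each bin takes the median of its samples.  Bin 1
is the tip end.  A filopodium is positive for a protein when at least 3 of
the 40 bins reach 10000 on the 0-65535 scale; the fraction of positive
filopodia across a cohort places the protein in a detection-frequency
category (core >= 60%, accessory 10-40%, absent < 10%, the gap in between
reported explicitly as intermediate).  Averaging the binned profiles of a
cohort gives one row of the filopodia map, displayed as a heatmap with the
tip (bins 1-6) demarcated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import INTENSITY_MAX, EnrichmentParams, MappingParams
from .errors import IntegrityError, ParameterError, ShortProfileError
from .profiles import LineProfile, profile_length

logger = logging.getLogger("filomap")

__all__ = [
    "BinnedProfile", "POICohort", "POISummary", "FilopodiaMap",
    "bin_profile", "is_positive", "percent_positive", "classify_poi",
    "average_map_row", "summarize_cohort", "assemble_map", "plot_map",
]

CATEGORY_ORDER = ["absent", "accessory", "intermediate", "core"]


@dataclass
class BinnedProfile:
    """One filopodium's profile reduced to 40 bins, bin 1 at the tip."""

    filopodium_id: str
    bins: np.ndarray
    n_samples: int = 0
    interpolated: bool = False  # True when short-profile gaps were filled

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.float64)
        if self.bins.ndim != 1:
            raise IntegrityError("bins must be a 1-D vector")
        # tolerate sub-grey-level float excursions from interpolation
        if np.any(self.bins < -0.5) or np.any(self.bins > INTENSITY_MAX + 0.5):
            raise IntegrityError("bin values must lie in [0, 65535]")
        self.bins = np.clip(self.bins, 0, INTENSITY_MAX)

    @property
    def n_bins(self) -> int:
        return self.bins.size


@dataclass
class POICohort:
    """All binned profiles measured for one protein of interest."""

    poi_name: str
    profiles: list[BinnedProfile]
    lengths_um: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.profiles)


@dataclass
class POISummary:
    """Detection statistics and averaged map row for one protein."""

    poi_name: str
    n_filopodia: int
    percent_positive: float
    category: str
    map_row: np.ndarray
    lengths_um: list[float] = field(default_factory=list)


@dataclass
class FilopodiaMap:
    """Protein x bin matrix of averaged profiles plus display metadata."""

    matrix: pd.DataFrame  # index poi_name, columns bin_1..bin_40 (raw means)
    row_order: list[str]
    row_scaling: str  # "rowmax" or "none"

    def scaled(self) -> pd.DataFrame:
        """Matrix with the recorded row scaling applied (for display)."""
        if self.row_scaling == "none":
            return self.matrix.copy()
        maxima = self.matrix.max(axis=1).replace(0, 1.0)
        return self.matrix.div(maxima, axis=0)


def _bin_assignment(n_samples: int, n_bins: int) -> np.ndarray:
    """0-based bin index of each sample: floor(i * n_bins / n_samples)."""
    i = np.arange(n_samples)
    return (i * n_bins) // n_samples


def bin_profile(
    profile: LineProfile,
    channel: Optional[str] = None,
    params: MappingParams | None = None,
    allow_short: bool = False,
) -> BinnedProfile:
    """Reduce one channel of a line profile to the 40-bin representation.

    Samples are partitioned into ``n_bins`` contiguous index blocks (sample
    ``i`` of ``n`` into bin ``floor(i*n_bins/n)``) and each bin takes the
    median of its samples (an even count takes the mean of the two middle
    values). Bin 1 is the tip.

    Profiles shorter than ``n_bins`` samples leave some bins empty; by
    default they are rejected with :class:`ShortProfileError` so the caller
    can exclude and log them, or with ``allow_short`` the empty bins are
    filled by linear interpolation and the result flagged.
    """
    params = params or MappingParams()
    channel = channel or profile.channels[0]
    values = profile.intensities[channel]
    n = values.size
    if n < params.n_bins and not allow_short:
        raise ShortProfileError(
            f"profile {profile.filopodium_id!r} has {n} samples "
            f"(< {params.n_bins} bins)"
        )
    assign = _bin_assignment(n, params.n_bins)
    bins = np.full(params.n_bins, np.nan)
    for b in range(params.n_bins):
        members = values[assign == b]
        if members.size:
            bins[b] = np.median(members)
    interpolated = bool(np.isnan(bins).any())
    if interpolated:
        idx = np.arange(params.n_bins)
        ok = ~np.isnan(bins)
        bins = np.interp(idx, idx[ok], bins[ok])
        logger.info("profile %s: %d empty bins filled by interpolation",
                    profile.filopodium_id, int((~ok).sum()))
    return BinnedProfile(profile.filopodium_id, bins, n_samples=n,
                         interpolated=interpolated)


def is_positive(binned: BinnedProfile, params: MappingParams | None = None) -> bool:
    """Positive-detection call: >= 3 bins at or above the 10000 floor."""
    params = params or MappingParams()
    return int(np.count_nonzero(binned.bins >= params.bin_floor)) >= params.min_positive_bins


def percent_positive(cohort: POICohort, params: MappingParams | None = None) -> float:
    """Percentage of a cohort's filopodia positive for the protein."""
    if not cohort.profiles:
        raise IntegrityError(f"cohort {cohort.poi_name!r} is empty")
    params = params or MappingParams()
    n_pos = sum(is_positive(b, params) for b in cohort.profiles)
    return 100.0 * n_pos / len(cohort.profiles)


def classify_poi(pct: float, params: MappingParams | None = None) -> str:
    """Detection-frequency category of a protein.

    >= 60% -> core; 10-40% (closed interval) -> accessory; < 10% -> absent;
    the undefined gap (40%, 60%) -> intermediate, reported explicitly.
    """
    params = params or MappingParams()
    if not (0 <= pct <= 100):
        raise ParameterError(f"percent positive outside [0, 100]: {pct}")
    if pct >= params.core_min_pct:
        return "core"
    if params.accessory_min_pct <= pct <= params.accessory_max_pct:
        return "accessory"
    if pct < params.accessory_min_pct:
        return "absent"
    return "intermediate"


def average_map_row(cohort: POICohort, positives_only: bool = False,
                    params: MappingParams | None = None) -> np.ndarray:
    """Arithmetic per-bin mean across the cohort's binned profiles.

    By default every analyzed filopodium contributes, positive or not; the
    ``positives_only`` switch restricts the average to positive detections.
    """
    profiles = cohort.profiles
    if positives_only:
        params = params or MappingParams()
        profiles = [b for b in profiles if is_positive(b, params)]
    if not profiles:
        raise IntegrityError(
            f"cohort {cohort.poi_name!r} has no profiles to average"
        )
    return np.mean([b.bins for b in profiles], axis=0)


def summarize_cohort(cohort: POICohort, params: MappingParams | None = None,
                     map_positives_only: bool = False) -> POISummary:
    """Detection frequency, category and averaged map row for one protein."""
    params = params or MappingParams()
    pct = percent_positive(cohort, params)
    return POISummary(
        poi_name=cohort.poi_name,
        n_filopodia=len(cohort.profiles),
        percent_positive=pct,
        category=classify_poi(pct, params),
        map_row=average_map_row(cohort, positives_only=map_positives_only,
                                params=params),
        lengths_um=list(cohort.lengths_um),
    )


def _row_enrichment(row: np.ndarray, eparams: EnrichmentParams) -> float:
    tip = row[: eparams.tip_last_bin]
    shaft = row[eparams.tip_last_bin:]
    return float(np.mean(tip) / np.mean(shaft)) if np.mean(shaft) > 0 else np.inf


def assemble_map(
    summaries: Sequence[POISummary],
    ordering: str = "median_enrichment",
    row_scaling: str = "rowmax",
    eparams: EnrichmentParams | None = None,
) -> FilopodiaMap:
    """Stack per-protein map rows into the filopodia-map matrix.

    ``ordering`` is either "given" (input order) or "median_enrichment"
    (rows sorted by decreasing tip/shaft enrichment of the averaged row).
    Raw per-bin means are always kept; ``row_scaling`` only records how the
    heatmap display normalizes each row.
    """
    names = [s.poi_name for s in summaries]
    if len(set(names)) != len(names):
        raise IntegrityError("duplicate poi_name among map rows")
    if row_scaling not in ("rowmax", "none"):
        raise ParameterError(f"unknown row_scaling {row_scaling!r}")
    n_bins = summaries[0].map_row.size
    matrix = pd.DataFrame(
        np.vstack([s.map_row for s in summaries]),
        index=pd.Index(names, name="poi_name"),
        columns=[f"bin_{i}" for i in range(1, n_bins + 1)],
    )
    if ordering == "median_enrichment":
        eparams = eparams or EnrichmentParams()
        scores = {s.poi_name: _row_enrichment(s.map_row, eparams) for s in summaries}
        order = sorted(names, key=lambda n: scores[n], reverse=True)
        matrix = matrix.loc[order]
    elif ordering == "given":
        order = names
    else:
        raise ParameterError(f"unknown ordering {ordering!r}")
    return FilopodiaMap(matrix=matrix, row_order=list(matrix.index),
                        row_scaling=row_scaling)


def plot_map(fmap: FilopodiaMap, eparams: EnrichmentParams | None = None,
             path=None):
    """Render the filopodia map as a heatmap with the tip region demarcated."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    eparams = eparams or EnrichmentParams()
    display = fmap.scaled()
    fig, ax = plt.subplots(
        figsize=(8, max(2.0, 0.3 * len(display) + 1.2)), constrained_layout=True
    )
    im = ax.imshow(display.to_numpy(), aspect="auto", cmap="magma",
                   interpolation="nearest")
    ax.axvline(eparams.tip_last_bin - 0.5, color="cyan", lw=1.2)
    ax.text(eparams.tip_last_bin / 2 - 0.5, -0.8, "tip", ha="center", color="black")
    ax.set_yticks(range(len(display)), display.index)
    ax.set_xlabel("bin (1 = tip, 40 = base)")
    fig.colorbar(im, ax=ax, label=f"mean intensity (row scaling: {fmap.row_scaling})")
    ax.set_title("filopodia map")
    if path is not None:
        fig.savefig(path, dpi=150, metadata=None)
        plt.close(fig)
    return fig
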