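"""Parameter objects for every pipeline stage.

All analysis constants live here as frozen-by-convention dataclasses with the
field defaults used throughout: the 40-bin representation with its
positive-detection rule (at least 3 bins at or above 10000 on the 0-65535
intensity scale), the detection-frequency category boundaries (core >= 60%,
accessory 10-40%), the tip/shaft split at bin 6 with the two-fold
plasma-membrane rule, percentile anchors for automatic brightness/contrast
adjustment, and the LoG/LAP tracking settings (blob diameter 0.8 um, linking
max distance 1 um, no gap closing).

Every dataclass validates on construction and round-trips through YAML via
:func:`params_to_yaml` / :func:`params_from_yaml`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ParameterError, PipelineConfigError

logger = logging.getLogger("filomap")

#: Full-scale intensity of the 16-bit representation all stages operate on.
INTENSITY_MAX = 65535


@dataclass
class MappingParams:
    """Constants of the binning, detection and categorization rules.

    ``n_bins`` contiguous segments per tip-to-base profile, reduced by the
    median; a filopodium is positive for a protein when at least
    ``min_positive_bins`` bins reach ``bin_floor``; cohort detection
    frequencies map to categories via the ``*_pct`` boundaries (the gap
    between ``accessory_max_pct`` and ``core_min_pct`` is reported as an
    explicit ``intermediate`` category, never merged).
    """

    n_bins: int = 40
    min_positive_bins: int = 3
    bin_floor: float = 10000.0
    core_min_pct: float = 60.0
    accessory_min_pct: float = 10.0
    accessory_max_pct: float = 40.0

    def __post_init__(self) -> None:
        if not (0 < self.min_positive_bins <= self.n_bins):
            raise ParameterError(
                f"min_positive_bins must be in (0, n_bins]; got "
                f"{self.min_positive_bins} with n_bins={self.n_bins}"
            )
        if not (0 <= self.bin_floor <= INTENSITY_MAX):
            raise ParameterError(f"bin_floor outside [0, {INTENSITY_MAX}]: {self.bin_floor}")
        if not (0 <= self.accessory_min_pct <= self.accessory_max_pct
                < self.core_min_pct <= 100):
            raise ParameterError(
                "category boundaries must satisfy 0 <= accessory_min <= "
                "accessory_max < core_min <= 100"
            )


@dataclass
class EnrichmentParams:
    """Tip/shaft geometry and the plasma-membrane fold rule.

    Bin indices are 1-based from the tip: ``tip_last_bin`` = 6 means bins 1-6
    form the tip and bins 7-40 the shaft.  A protein is called tip- (shaft-)
    localized when its median per-filopodium enrichment ratio is at least
    ``fold_threshold`` times above (below) the reference cohort's median and
    a two-sided test on log2 ratios is significant at ``alpha``.
    """

    tip_last_bin: int = 6
    n_bins: int = 40
    fold_threshold: float = 2.0
    reference_poi: str = "plasma_membrane (CAAX)"
    test: str = "welch"  # or "mannwhitney"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (1 <= self.tip_last_bin < self.n_bins):
            raise ParameterError("tip_last_bin must lie strictly inside 1..n_bins")
        if self.fold_threshold <= 1:
            raise ParameterError("fold_threshold must exceed 1")
        if self.test not in ("welch", "mannwhitney"):
            raise ParameterError(f"unknown test {self.test!r}")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must be in (0, 1)")

    @property
    def tip_bins(self) -> range:
        """1-based tip bin indices."""
        return range(1, self.tip_last_bin + 1)

    @property
    def shaft_bins(self) -> range:
        """1-based shaft bin indices."""
        return range(self.tip_last_bin + 1, self.n_bins + 1)


@dataclass
class NormalizationParams:
    """Percentile anchors of the automatic brightness/contrast adjustment.

    The upper anchor stands in for "the brightest cellular structure in the
    field of view": a robust maximum at the 99.95th percentile rather than
    the absolute max, to resist hot pixels. The lower anchor (1st percentile)
    approximates the background level.
    """

    upper_percentile: float = 99.95
    lower_percentile: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.lower_percentile < self.upper_percentile <= 100):
            raise ParameterError(
                "percentile anchors must satisfy 0 <= lower < upper <= 100"
            )


@dataclass
class TrackingParams:
    """LoG detection and nearest-assignment linking settings.

    ``quality_threshold`` is in the package's own quality unit (see
    :mod:`filomap.tracking`); gap closing is structurally disabled — a spot
    missing for one frame terminates its track.
    """

    blob_diameter_um: float = 0.8
    quality_threshold: float = 20.0
    max_link_distance_um: float = 1.0
    frame_interval_s: float = 5.0
    stable_cutoff_s: float = 60.0

    def __post_init__(self) -> None:
        if self.blob_diameter_um <= 0:
            raise ParameterError("blob_diameter_um must be positive")
        if self.max_link_distance_um <= 0:
            raise ParameterError("max_link_distance_um must be positive")
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be positive")


@dataclass
class PipelineConfig:
    """Paths, parameters and seeds for a full pipeline run.

    Exactly one input mode applies: ``simulate=True`` generates a synthetic
    dataset from ``seed``; otherwise ``image_path`` and ``traces_path`` must
    both be set.
    """

    output_dir: str = "filomap_run"
    simulate: bool = True
    image_path: Optional[str] = None
    traces_path: Optional[str] = None
    movie_path: Optional[str] = None
    poi_name: str = "POI"
    seed: int = 0
    n_filopodia_per_class: int = 50
    track: bool = True
    include_negatives_in_map: bool = True
    positives_only_ratios: bool = True
    mapping: MappingParams = field(default_factory=MappingParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)

    def validate(self) -> None:
        if not self.simulate:
            if self.image_path is None:
                raise PipelineConfigError("image mode requires 'image_path'")
            if self.traces_path is None:
                raise PipelineConfigError("image mode requires 'traces_path'")


def _asdict(obj) -> dict:
    return dataclasses.asdict(obj)


def params_to_yaml(config: PipelineConfig, path: str | Path) -> None:
    """Write a :class:`PipelineConfig` (with all nested params) to YAML."""
    Path(path).write_text(yaml.safe_dump(_asdict(config), sort_keys=False))


def params_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML, validating every block."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    nested = {
        "mapping": MappingParams,
        "enrichment": EnrichmentParams,
        "normalization": NormalizationParams,
        "tracking": TrackingParams,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in nested:
            kwargs[key] = nested[key](**(value or {}))
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)
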