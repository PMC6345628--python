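"""16-bit multi-channel image I/O and per-image contrast normalization.

Raw fluorescence fields vary in expression level and illumination, so before
any profile is sampled each channel of each field of view is linearly
rescaled so that a robust maximum — the brightest cellular structure,
operationalized as the 99.95th intensity percentile — maps to 65535 and the
1st percentile (background) maps to 0.  The rescaling is monotone and
invariant to multiplying the raw channel by a constant, which is what makes
downstream detection calls and enrichment ratios comparable across images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile

from .config import INTENSITY_MAX, NormalizationParams
from .errors import FormatError, NormalizationError

__all__ = ["MultiChannelImage", "read_image", "write_image", "auto_adjust"]


@dataclass
class MultiChannelImage:
    """Named 2-D channels sharing one pixel grid on the 0-65535 scale.

    ``data`` has shape (channels, height, width) and dtype uint16;
    ``normalized`` records whether :func:`auto_adjust` has been applied.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise FormatError(f"expected (C, H, W) pixel array, got shape {self.data.shape}")
        if len(self.channel_names) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the shared pixel grid."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's 2-D pixel array by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]


def write_image(image: MultiChannelImage, path: str | Path) -> None:
    """Write a 16-bit multi-channel TIFF with channel names and calibration.

    Metadata (channel names, pixel size, normalization flag) is stored in the
    TIFF's shaped-metadata JSON so that :func:`read_image` round-trips
    losslessly.
    """
    tifffile.imwrite(
        str(path),
        image.data.astype(np.uint16),
        metadata={
            "axes": "CYX",
            "channel_names": list(image.channel_names),
            "pixel_size_um": float(image.pixel_size_um),
            "normalized": bool(image.normalized),
        },
    )


def read_image(
    path: str | Path,
    channel_names: Optional[Sequence[str]] = None,
    pixel_size_um: Optional[float] = None,
    allow_float: bool = False,
) -> MultiChannelImage:
    """Read a grayscale 8- or 16-bit TIFF as a :class:`MultiChannelImage`.

    8-bit input is upscaled by 257 so that 255 maps to 65535.  The channel
    axis is taken from metadata when present, otherwise inferred as the
    smallest leading axis (at most 8).  RGB or floating-point files are
    rejected unless ``allow_float`` converts the latter by clipping to
    [0, 65535].
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
        page = tif.pages[0]
        if getattr(page.photometric, "name", "") == "RGB" or (
            arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.dtype == np.uint8
        ):
            raise FormatError(f"{path}: RGB TIFF; expected grayscale channels")

    if np.issubdtype(arr.dtype, np.floating):
        if not allow_float:
            raise FormatError(
                f"{path}: floating-point TIFF; pass allow_float=True to clip-convert"
            )
        arr = np.clip(np.round(arr), 0, INTENSITY_MAX).astype(np.uint16)
    elif arr.dtype == np.uint8:
        arr = arr.astype(np.uint16) * 257
    elif arr.dtype != np.uint16:
        arr = np.clip(arr, 0, INTENSITY_MAX).astype(np.uint16)

    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3 and meta.get("axes") != "CYX":
        # channel axis: smallest axis no larger than 8, moved first
        c_axis = int(np.argmin(arr.shape))
        if arr.shape[c_axis] > 8:
            raise FormatError(f"{path}: cannot identify a channel axis in shape {arr.shape}")
        arr = np.moveaxis(arr, c_axis, 0)
    elif arr.ndim > 3:
        raise FormatError(f"{path}: unsupported dimensionality {arr.ndim}")

    names = list(channel_names or meta.get("channel_names") or
                 [f"ch{i}" for i in range(arr.shape[0])])
    px = pixel_size_um if pixel_size_um is not None else float(meta.get("pixel_size_um", 1.0))
    return MultiChannelImage(
        data=arr,
        channel_names=names,
        pixel_size_um=px,
        normalized=bool(meta.get("normalized", False)),
    )


def auto_adjust(
    image: MultiChannelImage,
    params: NormalizationParams | None = None,
    upper_percentile: Optional[float] = None,
) -> MultiChannelImage:
    """Per-channel automatic brightness/contrast adjustment.

    Each channel is independently rescaled so its ``upper_percentile`` value
    (default 99.95, the robust stand-in for the brightest labeled structure)
    maps to 65535 and its 1st-percentile value maps to 0, then clipped.
    The map is monotone non-decreasing and idempotent within one grey level.

    Raises
    ------
    NormalizationError
        If a channel is constant between the two percentile anchors, naming
        the offending channel.
    """
    params = params or NormalizationParams()
    if upper_percentile is not None:
        params = replace(params, upper_percentile=upper_percentile)
    out = np.empty_like(image.data, dtype=np.uint16)
    for i, name in enumerate(image.channel_names):
        ch = image.data[i].astype(np.float64)
        lo = np.percentile(ch, params.lower_percentile)
        hi = np.percentile(ch, params.upper_percentile)
        if hi <= lo:
            raise NormalizationError(
                f"channel {name!r} is constant between the {params.lower_percentile} "
                f"and {params.upper_percentile} percentiles; cannot normalize"
            )
        scaled = (ch - lo) / (hi - lo) * INTENSITY_MAX
        out[i] = np.clip(np.round(scaled), 0, INTENSITY_MAX).astype(np.uint16)
    return MultiChannelImage(
        data=out,
        channel_names=list(image.channel_names),
        pixel_size_um=image.pixel_size_um,
        normalized=True,
    )
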