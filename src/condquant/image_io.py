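"""Image stacks, run configuration, and tabular I/O.

The universal in-memory container is :class:`ImageStack`, a calibrated
multi-channel, multi-z intensity array with canonical axis order
``(z, channel, y, x)``; ``y`` increases downward, ``x`` rightward, and
integer pixel indices address pixel centers. Intensities are stored as
floating point regardless of the on-disk integer type, since background
subtraction produces non-integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

CANONICAL_AXES = "ZCYX"


@dataclass(frozen=True)
class ImageStack:
    """Multi-channel, multi-z fluorescence image with physical calibration.

    Parameters
    ----------
    pixels
        Non-negative intensity array indexed ``(z, channel, y, x)``.
    pixel_size_um
        Lateral pixel size in micrometres (same for y and x).
    z_step_um
        Spacing between consecutive z planes in micrometres.
    channel_names
        Ordered channel labels, e.g. ``("gfp", "mcherry")``.
    """

    pixels: np.ndarray
    pixel_size_um: float = 0.1
    z_step_um: float = 0.4
    channel_names: tuple[str, ...] = ("gfp",)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 4:
            raise ValueError(f"pixels must be 4-D (z, channel, y, x); got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("pixel intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("pixel intensities must be non-negative")
        object.__setattr__(self, "pixels", arr)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if len(self.channel_names) != arr.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {arr.shape[1]} channels"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if arr.shape[0] > 1 and not self.z_step_um > 0:
            raise ValueError("z_step_um must be > 0 for multi-z stacks")

    @property
    def n_z(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in {self.channel_names}"
            ) from None

    def channel(self, channel: str) -> np.ndarray:
        """All z planes of one channel, shape (z, y, x)."""
        return self.pixels[:, self.channel_index(channel)]

    def plane(self, z: int, channel: str) -> np.ndarray:
        if not 0 <= z < self.n_z:
            raise IndexError(f"z index {z} out of range [0, {self.n_z})")
        return self.pixels[z, self.channel_index(channel)]

    def mean_projection(self, channel: str) -> np.ndarray:
        return self.channel(channel).mean(axis=0)


@dataclass
class RunConfig:
    """Parameters shared across pipeline stages.

    All sigmas and sizes are in pixels. ``threshold`` selects the
    thresholding mode for segmentation ("otsu" is relative and therefore
    intensity-scale invariant). ``z_plane`` of ``None`` segments on the
    channel's mean projection.
    """

    smoothing_sigma_px: float = 1.0
    threshold: str = "otsu"
    clip_percentile: float = 97.0
    min_area_px: int = 30
    z_plane: int | None = None
    interior_margin_px: int = 2
    dot_sigma_px: float = 1.0
    dot_min_prominence: float = 3.0
    window_radius_px: int = 10
    center_radius_px: int = 2
    equal_var_ttest: bool = True
    frap_restarts: int = 3
    droplet_min_area_px: int = 10
    droplet_guard_band_px: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smoothing_sigma_px <= 0 or self.dot_sigma_px <= 0:
            raise ValueError("smoothing sigmas must be > 0")
        for name in ("min_area_px", "window_radius_px", "droplet_min_area_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.interior_margin_px < 0 or self.droplet_guard_band_px < 0:
            raise ValueError("margins must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def with_options(self, **kwargs: Any) -> "RunConfig":
        return replace(self, **kwargs)


def _canonicalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder an array with labelled axes to canonical (Z, C, Y, X).

    ``axes`` is a string like "YX", "CYX", "ZYX" or "ZCYX"; "S"
    (samples, e.g. RGB) is treated as a channel axis. Missing Z/C axes
    become length-1 axes.
    """
    axes = axes.upper().replace("S", "C")
    if len(axes) != data.ndim:
        raise ValueError(f"axes {axes!r} does not match array of ndim {data.ndim}")
    unknown = set(axes) - set(CANONICAL_AXES)
    if unknown:
        raise ValueError(f"unresolvable axis order: unknown axes {sorted(unknown)}")
    if len(set(axes)) != len(axes):
        raise ValueError(f"repeated axis in {axes!r}")
    if "Y" not in axes or "X" not in axes:
        raise ValueError(f"axes {axes!r} lack Y/X image axes")
    for missing in set(CANONICAL_AXES) - set(axes):
        data = data[np.newaxis]
        axes = missing + axes
    order = [axes.index(ax) for ax in CANONICAL_AXES]
    return np.transpose(data, order)


def read_stack(
    path: str | Path,
    axes: str | None = None,
    pixel_size_um: float = 0.1,
    z_step_um: float = 0.4,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a single- or multi-page TIFF / OME-TIFF into an :class:`ImageStack`.

    The axis order is taken from TIFF series metadata unless overridden
    by ``axes``. Single-plane images become z-length 1. Raises
    ``ValueError`` on unreadable files, unresolvable axis orders, or
    negative intensities.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            file_axes = series.axes
    except (tifffile.TiffFileError, IndexError, ValueError) as exc:
        raise ValueError(f"unreadable file: {path} ({exc})") from exc
    arr = _canonicalize_axes(np.asarray(data), axes or file_axes)
    if np.any(arr < 0):
        raise ValueError(f"negative intensities in {path} after offset handling")
    if channel_names is None:
        channel_names = _default_channel_names(arr.shape[1])
    return ImageStack(
        pixels=arr.astype(np.float64),
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        channel_names=tuple(channel_names),
    )


def _default_channel_names(n: int) -> tuple[str, ...]:
    if n == 1:
        return ("gfp",)
    if n == 2:
        return ("gfp", "mcherry")
    return tuple(f"ch{i}" for i in range(n))


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an ImageStack as a 32-bit float TIFF with ZCYX axis metadata."""
    tifffile.imwrite(
        str(path),
        stack.pixels.astype(np.float32),
        metadata={"axes": CANONICAL_AXES},
    )


def write_results(rows: Iterable[Mapping[str, Any]] | pd.DataFrame, path: str | Path) -> None:
    """Write tabular records to CSV (default) or TSV, chosen by extension.

    All rows must share one schema; ragged rows raise ``ValueError``.
    An empty row list yields a header-only file when a DataFrame with
    columns is given, or an empty file for a bare empty list.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        if rows:
            schema = list(rows[0].keys())
            for i, row in enumerate(rows):
                if list(row.keys()) != schema:
                    raise ValueError(f"ragged rows: row {i} keys differ from row 0")
        frame = pd.DataFrame(rows)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame.to_csv(path, sep=sep, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)
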