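"""Reading and writing multi-channel fluorescence microscopy images.

Supports single-plane TIFF (8/16-bit, 1-3 channels, ImageJ-style calibration
metadata) and 8-bit PNG. CZI files are dispatched to an optional third-party
reader when one is importable. The nucleus stain (DAPI, blue) is the
segmentation reference; green/red channels carry the foci marker signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import tifffile

from .errors import (
    ImageReadError,
    MissingCalibrationError,
    RoleAssignmentError,
    RoleConflictError,
    ShapeMismatchError,
    UnsupportedDimensionalityError,
)

logger = logging.getLogger(__name__)

ROLE_NUCLEUS = "nucleus"
ROLE_GREEN = "marker_green"
ROLE_RED = "marker_red"
VALID_ROLES = {ROLE_NUCLEUS, ROLE_GREEN, ROLE_RED}

_COLOR_TO_ROLE = {"blue": ROLE_NUCLEUS, "green": ROLE_GREEN, "red": ROLE_RED}
_ROLE_TO_COLOR = {v: k for k, v in _COLOR_TO_ROLE.items()}


@dataclass
class MultiChannelImage:
    """A calibrated, single-plane, multi-channel intensity image.

    Parameters
    ----------
    channels : dict mapping channel index to a 2-D integer intensity grid.
    bit_depth : 8 or 16; every intensity lies in ``[0, 2**bit_depth - 1]``.
    pixel_size_um : physical edge length of one pixel in micrometres.
    source_path : identifier of the originating file.
    channel_roles : map channel index -> role; exactly one channel holds the
        ``nucleus`` role once roles are assigned.
    channel_colors : optional per-channel color hints ("red"/"green"/"blue")
        recovered from LUT metadata, used for role inference.
    """

    channels: dict[int, np.ndarray]
    bit_depth: int
    pixel_size_um: float
    source_path: str = ""
    channel_roles: dict[int, str] = field(default_factory=dict)
    channel_colors: dict[int, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.channels:
            raise ValueError("image must have at least one channel")
        shapes = {grid.shape for grid in self.channels.values()}
        if len(shapes) != 1:
            raise ShapeMismatchError(f"channel grids differ in shape: {shapes}")
        limit = 2**self.bit_depth - 1
        for cid, grid in self.channels.items():
            if grid.ndim != 2:
                raise ValueError(f"channel {cid} is not 2-D")
            if grid.min() < 0 or grid.max() > limit:
                raise ValueError(
                    f"channel {cid} intensities outside [0, {limit}]"
                )
        roles = list(self.channel_roles.values())
        if len(roles) != len(set(roles)):
            raise RoleConflictError("two channels claim the same role")
        if roles and roles.count(ROLE_NUCLEUS) != 1:
            raise RoleAssignmentError("exactly one channel must be the nucleus")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    def channel_by_role(self, role: str) -> np.ndarray | None:
        for cid, r in self.channel_roles.items():
            if r == role:
                return self.channels[cid]
        return None

    @property
    def nucleus_channel(self) -> np.ndarray:
        grid = self.channel_by_role(ROLE_NUCLEUS)
        if grid is None:
            raise RoleAssignmentError("no channel holds the nucleus role")
        return grid


def pixel_area_um2(image: MultiChannelImage) -> float:
    """Physical area of one pixel in square micrometres."""
    return image.pixel_size_um**2


def _lut_color(lut: np.ndarray) -> str | None:
    """Classify an ImageJ (3, 256) LUT as red/green/blue by its brightest end."""
    lut = np.asarray(lut)
    if lut.shape[0] != 3:
        lut = lut.T
    tops = lut[:, -1].astype(int)
    if len(set(tops.tolist())) == 1:
        return None  # grayscale LUT carries no color information
    return ("red", "green", "blue")[int(np.argmax(tops))]


def _tiff_pixel_size(tif: tifffile.TiffFile) -> float | None:
    """Extract a µm/pixel calibration from ImageJ metadata + resolution tags."""
    meta = tif.imagej_metadata or {}
    unit = meta.get("unit", "")
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0:
        return None
    size = float(Fraction(int(den), int(num)))
    if unit in ("um", "µm", "micron", "microns"):
        return size
    res_unit = page.tags.get("ResolutionUnit")
    if res_unit is not None and getattr(res_unit.value, "name", "") == "CENTIMETER":
        return size * 1e4
    return None


def _split_planes(data: np.ndarray, axes: str) -> list[np.ndarray]:
    """Split a tifffile series into channel planes, rejecting z/t stacks."""
    # drop singleton axes first so a (1, C, Y, X) hyperstack still loads
    keep = [i for i, n in enumerate(data.shape) if n > 1 or axes[i] in "YX"]
    data = data.reshape([data.shape[i] for i in keep])
    axes = "".join(axes[i] for i in keep)
    for ax, n in zip(axes, data.shape):
        if ax in "ZT" and n > 1:
            raise UnsupportedDimensionalityError(
                f"{n} planes along axis {ax}: only 2-D single-plane images are supported"
            )
    if data.ndim == 2:
        return [data]
    if data.ndim == 3:
        ch_axis = 0 if axes[0] not in "YX" else 2
        n = data.shape[ch_axis]
        if n > 3:
            raise UnsupportedDimensionalityError(
                f"{n} planes along axis {axes[ch_axis]}: at most 3 channels supported"
            )
        return [np.take(data, i, axis=ch_axis) for i in range(n)]
    raise UnsupportedDimensionalityError(
        f"cannot interpret image with axes {axes} and shape {data.shape}"
    )


def _read_tiff(path: Path) -> tuple[list[np.ndarray], list[str | None], float | None]:
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        planes = _split_planes(series.asarray(), series.axes)
        pixel_size = _tiff_pixel_size(tif)
        meta = tif.imagej_metadata or {}
        luts = meta.get("LUTs")
        colors: list[str | None]
        if luts is not None and len(luts) == len(planes):
            colors = [_lut_color(lut) for lut in luts]
        else:
            colors = [None] * len(planes)
    return planes, colors, pixel_size


def _read_png(path: Path) -> tuple[list[np.ndarray], list[str | None]]:
    from PIL import Image

    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA"):
            arr = np.asarray(im.convert("RGB"))
            return (
                [arr[..., 0], arr[..., 1], arr[..., 2]],
                ["red", "green", "blue"],
            )
        if im.mode == "L":
            return [np.asarray(im)], [None]
        raise ImageReadError(f"unsupported PNG mode {im.mode!r}")


def _read_czi(path: Path) -> tuple[list[np.ndarray], list[str | None], float | None]:
    try:
        from aicsimageio import AICSImage  # optional dependency
    except ImportError as exc:
        raise ImageReadError(
            "CZI support requires the optional 'aicsimageio' package; "
            "convert the image to single-plane TIFF or install a CZI reader"
        ) from exc
    img = AICSImage(path)
    if img.dims.Z > 1 or img.dims.T > 1:
        raise UnsupportedDimensionalityError(
            "z-stacks and time series are not supported"
        )
    planes = [img.get_image_data("YX", C=c) for c in range(img.dims.C)]
    px = img.physical_pixel_sizes.X
    return planes, [None] * len(planes), float(px) if px else None


def read_image(
    path: str | Path, pixel_size_override: float | None = None
) -> MultiChannelImage:
    """Read a microscopy image file into a :class:`MultiChannelImage`.

    Bit depth is detected from the pixel dtype. Pixel size comes from file
    metadata, unless ``pixel_size_override`` is given, which always wins.
    Channel roles are left unassigned; see :func:`assign_channel_roles`.

    Raises
    ------
    ImageReadError
        Unreadable or unsupported file.
    UnsupportedDimensionalityError
        More than one z-plane or time point.
    MissingCalibrationError
        No pixel-size metadata and no override.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such file: {path}")
    suffix = path.suffix.lower()
    pixel_size: float | None = None
    try:
        if suffix in (".tif", ".tiff"):
            planes, colors, pixel_size = _read_tiff(path)
        elif suffix == ".png":
            planes, colors = _read_png(path)
        elif suffix == ".czi":
            planes, colors, pixel_size = _read_czi(path)
        else:
            raise ImageReadError(f"unsupported file extension {suffix!r}")
    except (ImageReadError, MissingCalibrationError):
        raise
    except Exception as exc:  # codec-level failure
        raise ImageReadError(f"could not read {path}: {exc}") from exc

    if len(planes) > 3:
        raise UnsupportedDimensionalityError(
            f"{len(planes)} channels: at most 3 supported"
        )
    if pixel_size_override is not None:
        pixel_size = float(pixel_size_override)
    if pixel_size is None:
        raise MissingCalibrationError(
            f"{path.name}: no pixel-size metadata; pass a µm/pixel override"
        )
    dtype = planes[0].dtype
    bit_depth = 16 if dtype.itemsize > 1 else 8
    channels = {i: np.ascontiguousarray(p) for i, p in enumerate(planes)}
    return MultiChannelImage(
        channels=channels,
        bit_depth=bit_depth,
        pixel_size_um=pixel_size,
        source_path=str(path),
        channel_colors={i: c for i, c in enumerate(colors)},
    )


def assign_channel_roles(
    image: MultiChannelImage, explicit_roles: dict[int, str] | None = None
) -> MultiChannelImage:
    """Populate ``channel_roles`` on a copy of *image*.

    Precedence: ``explicit_roles`` > embedded LUT/color metadata > channel-order
    convention. The order convention (logged when used) is: channel 0 =
    marker_green, channel 1 = marker_red (3-channel files only), last channel =
    nucleus. Single-channel images need an explicit nucleus role.
    """
    n = len(image.channels)
    if explicit_roles is not None:
        bad = set(explicit_roles.values()) - VALID_ROLES
        if bad:
            raise RoleAssignmentError(f"unknown roles: {sorted(bad)}")
        roles = dict(explicit_roles)
    elif any(c is not None for c in image.channel_colors.values()):
        roles = {
            cid: _COLOR_TO_ROLE[color]
            for cid, color in image.channel_colors.items()
            if color in _COLOR_TO_ROLE
        }
    elif n >= 2:
        roles = {0: ROLE_GREEN, n - 1: ROLE_NUCLEUS}
        if n == 3:
            roles[1] = ROLE_RED
        logger.info(
            "%s: no channel color metadata; using order convention "
            "(ch0=marker_green%s, ch%d=nucleus)",
            image.source_path,
            ", ch1=marker_red" if n == 3 else "",
            n - 1,
        )
    else:
        roles = {}
    values = list(roles.values())
    if len(values) != len(set(values)):
        raise RoleConflictError(f"two channels claim the same role: {roles}")
    if values.count(ROLE_NUCLEUS) != 1:
        raise RoleAssignmentError(
            f"{image.source_path}: no channel assignable as nucleus "
            f"(inferred roles: {roles})"
        )
    return MultiChannelImage(
        channels=image.channels,
        bit_depth=image.bit_depth,
        pixel_size_um=image.pixel_size_um,
        source_path=image.source_path,
        channel_roles=roles,
        channel_colors=image.channel_colors,
    )


def write_image(image: MultiChannelImage, path: str | Path) -> None:
    """Write the image as an ImageJ-style TIFF with calibration and LUTs."""
    path = Path(path)
    dtype = np.uint16 if image.bit_depth == 16 else np.uint8
    stack = np.stack(
        [image.channels[cid].astype(dtype) for cid in sorted(image.channels)]
    )
    luts = []
    ramp = np.arange(256, dtype=np.uint8)
    for cid in sorted(image.channels):
        color = image.channel_colors.get(cid)
        role = image.channel_roles.get(cid)
        if color is None and role is not None:
            color = _ROLE_TO_COLOR.get(role)
        lut = np.zeros((3, 256), dtype=np.uint8)
        if color is None:
            lut[:] = ramp
        else:
            lut[("red", "green", "blue").index(color)] = ramp
        luts.append(lut)
    res = 1.0 / image.pixel_size_um
    tifffile.imwrite(
        path,
        stack,
        imagej=True,
        resolution=(res, res),
        metadata={"unit": "um", "axes": "CYX", "mode": "composite", "LUTs": luts},
    )
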