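"""Batch processing of an image folder with one shared parameter set."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import FociCountError, ValidationError
from .foci import FociParams
from .image_io import assign_channel_roles, read_image
from .pipeline import process_image
from .segmentation import SegmentationParams
from .summary import CHANNEL_TAGS, write_outputs

logger = logging.getLogger(__name__)

_EXTENSIONS = (".czi", ".tif", ".tiff")


@dataclass
class RunConfig:
    """Parameters of one batch run; serialized to the output folder."""

    input_dir: str
    output_dir: str
    nucleus_size: float = 100.0  # µm², minimum nucleus area
    mark_brightness: float = 10_000.0
    mark_count: int = 10
    channel_overrides: dict[str, dict] = field(default_factory=dict)
    pixel_size: float | None = None  # µm/pixel override
    qc_images: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def discover_images(input_dir: str | Path) -> list[Path]:
    """Non-recursive, case-insensitive listing of CZI/TIFF files, sorted
    lexicographically so CSV row order is deterministic."""
    folder = Path(input_dir)
    return sorted(
        (
            p
            for p in folder.iterdir()
            if p.is_file() and p.suffix.lower() in _EXTENSIONS
        ),
        key=lambda p: p.name,
    )


def _validate(config: RunConfig) -> None:
    if not (0 <= config.mark_brightness <= 65535):
        raise ValidationError(
            f"mark_brightness {config.mark_brightness} outside the 16-bit "
            "intensity range 0-65535"
        )
    if config.mark_count < 0:
        raise ValidationError("mark_count must be >= 0")
    if config.nucleus_size <= 0:
        raise ValidationError("nucleus_size must be positive")
    if config.pixel_size is not None and config.pixel_size <= 0:
        raise ValidationError("pixel_size must be positive")


def _foci_params(config: RunConfig) -> tuple[FociParams, dict[str, FociParams]]:
    base = FociParams(
        mark_brightness=config.mark_brightness, mark_count=config.mark_count
    )
    overrides = {}
    for tag, fields_ in config.channel_overrides.items():
        if tag not in CHANNEL_TAGS:
            raise ValidationError(f"unknown channel tag {tag!r} in overrides")
        overrides[tag] = FociParams(
            mark_brightness=fields_.get("mark_brightness", config.mark_brightness),
            mark_count=fields_.get("mark_count", config.mark_count),
        )
    return base, overrides


def _setup_logging(output_dir: Path, level: str) -> logging.FileHandler:
    handler = logging.FileHandler(output_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("focicount")
    root.setLevel(level.upper())
    root.addHandler(handler)
    return handler


def run_batch(config: RunConfig) -> int:
    """Process every image in ``config.input_dir`` with identical parameters.

    Files are processed independently; a failure on one file is logged and
    skipped. Summary CSVs cover the files that succeeded. Returns 0 when at
    least one file was analysed, 1 otherwise.

    Raises
    ------
    ValidationError
        Invalid parameters, or an input folder without readable images —
        both detected before any processing.
    """
    _validate(config)
    files = discover_images(config.input_dir)
    if not files:
        raise ValidationError(f"no CZI/TIFF images found in {config.input_dir}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out, config.log_level)
    try:
        config.to_yaml(out / "config.yaml")
        seg = SegmentationParams(min_nucleus_area_um2=config.nucleus_size)
        base, overrides = _foci_params(config)
        summaries: dict[str, list] = {}
        records_by_image: dict[str, list] = {}
        qc: list = []
        n_ok = 0
        for path in files:
            try:
                image = read_image(path, pixel_size_override=config.pixel_size)
                if config.mark_brightness > image.max_intensity:
                    raise ValidationError(
                        f"mark_brightness {config.mark_brightness} exceeds the "
                        f"{image.bit_depth}-bit range of {path.name}"
                    )
                image = assign_channel_roles(image)
                result = process_image(
                    image, seg_params=seg, foci_params=base, channel_overrides=overrides
                )
            except FociCountError as exc:
                logger.error("skipping %s: %s", path.name, exc)
                continue
            n_ok += 1
            for tag, summary in result.summaries.items():
                summaries.setdefault(tag, []).append(summary)
            records_by_image[result.filename] = result.records
            if config.qc_images:
                qc.append((path, image, result))
        write_outputs(summaries, records_by_image, out)
        for path, image, result in qc:
            _write_qc(out / path.stem, image, result)
        logger.info("analysed %d/%d images", n_ok, len(files))
        return 0 if n_ok else 1
    finally:
        logging.getLogger("focicount").removeHandler(handler)
        handler.close()


def _write_qc(folder: Path, image, result) -> None:
    """Label-map TIFF plus an RGB outline overlay for visual checking."""
    import tifffile
    from skimage.segmentation import find_boundaries

    folder.mkdir(parents=True, exist_ok=True)
    labels = np.zeros(image.shape, dtype=np.uint16)
    for roi in result.rois:
        labels[roi.mask] = roi.label
    tifffile.imwrite(folder / "qc_labels.tif", labels)
    nuc = image.nucleus_channel.astype(np.float64)
    scale = nuc.max() or 1.0
    base = (255 * nuc / scale).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    rgb[find_boundaries(labels, mode="outer")] = (255, 255, 0)
    tifffile.imwrite(folder / "qc_overlay.tif", rgb)
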