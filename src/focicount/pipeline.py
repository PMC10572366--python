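"""End-to-end analysis of one image: segment, detect foci, classify, summarize."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .colocalization import channel_max, channel_min
from .foci import FociParams, detect_foci, nucleus_average_intensity
from .image_io import ROLE_GREEN, ROLE_RED, MultiChannelImage, assign_channel_roles
from .segmentation import NucleusROI, SegmentationParams, detect_nuclei
from .summary import ImageSummary, NucleusRecord, classify_nucleus, summarize_image


@dataclass
class ImageResult:
    """Everything the pipeline derives from one input image."""

    filename: str
    rois: list[NucleusROI]
    records: list[NucleusRecord]
    summaries: dict[str, ImageSummary] = field(default_factory=dict)


def marker_grids(image: MultiChannelImage) -> dict[str, np.ndarray]:
    """Collect the evaluated marker grids, keyed by channel tag.

    With both green and red markers present, the pixelwise Min (colocalized
    signal) and Max (union signal) grids join the set and are analysed by
    the same detection path.
    """
    grids: dict[str, np.ndarray] = {}
    green = image.channel_by_role(ROLE_GREEN)
    red = image.channel_by_role(ROLE_RED)
    if green is not None:
        grids["green"] = green
    if red is not None:
        grids["red"] = red
    if green is not None and red is not None:
        grids["Min"] = channel_min(green, red)
        grids["Max"] = channel_max(green, red)
    return grids


def process_image(
    image: MultiChannelImage,
    seg_params: SegmentationParams | None = None,
    foci_params: FociParams | None = None,
    channel_overrides: dict[str, FociParams] | None = None,
) -> ImageResult:
    """Run the full per-image analysis.

    ``foci_params`` applies to every channel unless ``channel_overrides``
    supplies a channel-specific replacement (e.g. a mark_count of 3 on the
    Min channel for telomere-dysfunction-foci positivity, versus 10 for
    plain damage calling).
    """
    if not image.channel_roles:
        image = assign_channel_roles(image)
    seg_params = seg_params or SegmentationParams()
    foci_params = foci_params or FociParams()
    overrides = channel_overrides or {}
    rois = detect_nuclei(image, seg_params)
    grids = marker_grids(image)
    records = [NucleusRecord(nucleus_label=roi.label) for roi in rois]
    filename = Path(image.source_path).name if image.source_path else "image"
    result = ImageResult(filename=filename, rois=rois, records=records)
    for tag, grid in grids.items():
        params = overrides.get(tag, foci_params)
        for roi, record in zip(rois, records):
            foci = detect_foci(grid, roi, params, bit_depth=image.bit_depth)
            qualifying, selected = classify_nucleus(foci, params)
            record.foci[tag] = foci
            record.qualifying[tag] = qualifying
            record.selected[tag] = selected
        result.summaries[tag] = summarize_image(
            filename, rois, records, nucleus_average_intensity(grid, rois), tag
        )
    return result
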