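import numpy as np
import pytest

from focicount import (
    FocusSpec,
    NucleusSpec,
    SceneSpec,
    render_scene,
)

DISK_PX_AREA = 0.312**2  # µm² per pixel at the default fixture calibration


def disk_scene(n_disks=5, radius=26, foci_counts=None, seed=0, noise_sd=0.0):
    """Evenly spaced circular nuclei on a 512x512 field, optional planted foci.

    radius 26 px -> ~207 µm², comfortably above the 100 µm² filter.
    """
    centers = [(96 + 160 * (i // 3), 96 + 160 * (i % 3)) for i in range(n_disks)]
    nuclei = [
        NucleusSpec(center=c, radii=(radius, radius)) for c in centers
    ]
    spec = SceneSpec(nuclei=nuclei, seed=seed, noise_sd=noise_sd)
    if foci_counts is not None:
        per_nucleus = []
        for k in foci_counts:
            # two-ring placement keeps spots >= 6 px apart for k <= 15
            n_outer = min(k, 10)
            spots = [
                FocusSpec(
                    offset=(
                        12 * np.cos(2 * np.pi * j / max(n_outer, 1)),
                        12 * np.sin(2 * np.pi * j / max(n_outer, 1)),
                    )
                )
                for j in range(n_outer)
            ]
            spots += [
                FocusSpec(
                    offset=(
                        6 * np.cos(2 * np.pi * j / (k - 10) + 0.5),
                        6 * np.sin(2 * np.pi * j / (k - 10) + 0.5),
                    )
                )
                for j in range(k - 10)
            ]
            per_nucleus.append(spots)
        spec.foci["green"] = per_nucleus
    return spec


@pytest.fixture
def five_disk_image():
    """Noise-free 5-nucleus field with 12 foci each, plus its ground truth."""
    spec = disk_scene(foci_counts=[12] * 5)
    image, gt = render_scene(spec)
    return spec, image, gt
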