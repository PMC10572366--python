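"""Pixelwise min/max combination of two marker channels.

The minimum image is bright only where BOTH markers are bright, so foci
detected on it are colocalized foci (the telomere-dysfunction-induced-foci
readout); the maximum image carries the union signal. Both grids run through
the same detection pipeline as real channels.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeMismatchError


def _check(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"marker grids differ in shape: {a.shape} vs {b.shape}")
    return a, b


def channel_min(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise minimum of two equally-shaped marker grids."""
    a, b = _check(a, b)
    return np.minimum(a, b)


def channel_max(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise maximum of two equally-shaped marker grids."""
    a, b = _check(a, b)
    return np.maximum(a, b)
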