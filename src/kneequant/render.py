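"""Colour rendering of projected thickness maps.

Colour rule: thickness above ``white_mm`` (2.0 mm) renders pure white,
thickness between 0 and ``white_mm`` ramps linearly from pure red to white,
and pixels without cartilage render gray (also the colour of bare bone).
ROI outlines are overlaid in black.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy import ndimage

from .geometry import ProjectedThicknessMap, RegionOfInterest

__all__ = ["render_thickness_map", "save_png"]

WHITE = (1.0, 1.0, 1.0)
RED = (1.0, 0.0, 0.0)
GRAY = (0.5, 0.5, 0.5)


def render_thickness_map(
    pmap: ProjectedThicknessMap,
    rois: Iterable[RegionOfInterest] = (),
    white_mm: float = 2.0,
    gray: tuple[float, float, float] = GRAY,
) -> np.ndarray:
    """Return an (H, W, 3) float RGB image of a projected thickness map."""
    t = pmap.thickness_mm
    img = np.empty(t.shape + (3,), float)
    img[:] = gray
    has = np.isfinite(t)
    frac = np.clip(np.where(has, t, 0.0) / white_mm, 0.0, 1.0)
    # red (1,0,0) -> white (1,1,1) ramp on the green/blue channels
    img[has, 0] = 1.0
    img[has, 1] = frac[has]
    img[has, 2] = frac[has]
    for roi in rois:
        outline = roi.mask & ~ndimage.binary_erosion(roi.mask)
        img[outline] = (0.0, 0.0, 0.0)
    return img


def save_png(img: np.ndarray, path) -> None:
    import matplotlib.image

    matplotlib.image.imsave(str(path), np.clip(img, 0.0, 1.0))
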