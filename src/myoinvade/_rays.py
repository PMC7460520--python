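"""Sub-pixel radial extent of star-shaped binary regions.

Shared by the phantom's realized-truth measurement and the staging
estimator so both sides of parameter recovery use one geometric definition:
along each ray the mask is sampled bilinearly (which smooths the jagged
pixel boundary) and the region's radial extent is the inside-sample count
times the radial step — for a star-shaped region this equals the radius of
the outermost crossing up to half a step.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ray_extents"]


def ray_extents(mask: np.ndarray, center: tuple[float, float],
                thetas: np.ndarray, r_max: float,
                step: float = 0.25) -> np.ndarray:
    """Radial extent of ``mask`` along rays from ``center``, in pixels."""
    m = np.asarray(mask, dtype=np.float64)
    h, w = m.shape
    radii = np.arange(step, r_max + step, step)
    rows = center[0] + radii[None, :] * np.sin(thetas)[:, None]
    cols = center[1] + radii[None, :] * np.cos(thetas)[:, None]
    inb = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    rows = np.clip(rows, 0, h - 1)
    cols = np.clip(cols, 0, w - 1)
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = rows - r0
    fc = cols - c0
    val = (m[r0, c0] * (1 - fr) * (1 - fc) + m[r1, c0] * fr * (1 - fc)
           + m[r0, c1] * (1 - fr) * fc + m[r1, c1] * fr * fc)
    inside = (val >= 0.5) & inb
    return inside.sum(axis=1) * step
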