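"""Myometrial-invasion depth from uterus and lesion masks; FIGO IA/IB call.

The depth statistic is defined by ray geometry: from a stable interior
point of the endometrial compartment, cast rays and record where each ray
leaves the lesion (``r_lesion``) and the uterus (``r_serosa``). The
pre-invasion endomyometrial junction ``r_junction`` is not observable in a
post-invasion mask, so it is reconstructed by a robust low-order
trigonometric fit to ``r_lesion`` that down-weights outward residuals (the
protruding invasion front), leaving the non-invaded baseline. The invasion
fraction is then

    f = max over rays of  (r_lesion - r_junction) / (r_serosa - r_junction)

i.e. deepest penetration over local myometrial thickness, clamped to
[0, 1]; a case is staged IB when f >= 0.5 and IA otherwise. The same ray
definition underlies the phantom generator's ground truth, so parameter
recovery is well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._rays import ray_extents

__all__ = [
    "RayProfile",
    "InvasionEstimate",
    "StageCall",
    "ray_profile",
    "estimate_junction",
    "invasion_fraction",
    "stage_case",
    "estimate_case",
]

STAGE_CUTOFF = 0.5  # FIGO stage-I substage rule: >= 50% invasion is IB
DEGENERATE_THICKNESS = 2.0  # px; rays thinner than this are excluded
_EPS = 1e-6


@dataclass
class RayProfile:
    angles: np.ndarray  # radians, uniform grid
    r_serosa: np.ndarray  # outermost uterus crossing per ray, px
    r_lesion: np.ndarray  # outermost lesion crossing per ray, px
    valid: np.ndarray  # bool; rays that crossed the uterus boundary
    origin: tuple[float, float]  # (row, col) ray origin


@dataclass
class InvasionEstimate:
    fraction: float
    per_slice_fractions: list[float]
    n_valid_rays: int
    fit_order: int
    flags: list[str]


@dataclass(frozen=True)
class StageCall:
    stage: str  # "IA" or "IB"
    fraction: float
    cutoff: float = STAGE_CUTOFF
    rule: str = "fraction >= 0.5 => IB"


def _stable_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Centroid of the erosion-stable interior (robust to boundary spikes)."""
    core = mask
    for _ in range(10):
        eroded = ndimage.binary_erosion(core)
        if eroded.sum() < 25:
            break
        core = eroded
    cy, cx = ndimage.center_of_mass(core)
    return float(cy), float(cx)


def ray_profile(uterus_mask: np.ndarray, lesion_mask: np.ndarray,
                n_rays: int = 720) -> RayProfile:
    """Radial extent of lesion and uterus along rays from the lesion core.

    The origin is the centroid of the lesion's erosion-stable interior; per
    ray, the radius is the outermost mask crossing (0.25 px radial steps
    with bilinear sub-pixel sampling). Rays whose origin falls outside a
    mask or that never cross the uterus are marked invalid.
    """
    ut = np.asarray(uterus_mask).astype(bool)
    le = np.asarray(lesion_mask).astype(bool)
    if ut.shape != le.shape:
        raise ValueError(f"mask shapes differ: {ut.shape} vs {le.shape}")
    if not ut.any() or not le.any():
        raise ValueError("empty mask")
    if np.any(le & ~ut):
        raise ValueError("lesion mask extends outside the uterus mask")
    # The uterus interior is the stable anchor: a deeply protruding lesion
    # drags its own centroid into the invasion front, which would distort
    # the whole polar frame.
    origin = _stable_centroid(ut)
    oy, ox = int(round(origin[0])), int(round(origin[1]))
    if not (0 <= oy < ut.shape[0] and 0 <= ox < ut.shape[1] and ut[oy, ox]):
        raise ValueError("ray origin lies outside the uterus mask")

    angles = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    r_max = float(np.hypot(*ut.shape))
    r_ser = ray_extents(ut, origin, angles, r_max)
    r_les = ray_extents(le, origin, angles, r_max)
    valid = r_ser > 0
    return RayProfile(angles=angles, r_serosa=r_ser, r_lesion=r_les,
                      valid=valid, origin=origin)


def _trig_design(theta: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones_like(theta)]
    for k in range(1, order + 1):
        cols.append(np.cos(k * theta))
        cols.append(np.sin(k * theta))
    return np.stack(cols, axis=1)


def estimate_junction(profile: RayProfile, fit_order: int = 2,
                      n_iter: int = 25, trim: float = 0.40) -> np.ndarray:
    """Reconstruct the baseline endomyometrial junction radius per ray.

    Fits ``r_lesion(theta)`` with a trigonometric polynomial of order
    ``fit_order`` (<= 3) by iterative asymmetric trimming: on each pass the
    most outward-lying residuals (up to the ``trim`` fraction — the invasion
    front protruding beyond the baseline) are dropped and the curve refit,
    so it settles onto the non-invaded lower envelope. The default order is
    2, one below the maximum baseline harmonic: an order-3 fit can bend into
    a wide invasion front and absorb it into the "baseline". The result is
    clipped to ``[0, r_serosa]``.
    """
    if not 0 <= fit_order <= 3:
        raise ValueError("fit_order must be in 0..3")
    theta = profile.angles[profile.valid]
    r = profile.r_lesion[profile.valid]
    n_basis = 2 * fit_order + 1
    if len(theta) < 2 * n_basis:
        raise ValueError(
            f"too few valid rays ({len(theta)}) for fit order {fit_order}"
        )
    design = _trig_design(theta, fit_order)
    keep = np.ones(len(r), dtype=bool)
    for _ in range(n_iter):
        coef, *_ = np.linalg.lstsq(design[keep], r[keep], rcond=None)
        resid = r - design @ coef
        floor = np.quantile(resid, 1.0 - trim)
        keep = resid <= max(floor, np.quantile(resid, 0.6))
    r_hat = _trig_design(profile.angles, fit_order) @ coef
    return np.clip(r_hat, 0.0, profile.r_serosa)


def invasion_fraction(profile: RayProfile,
                      r_junction_hat: np.ndarray) -> InvasionEstimate:
    """Deepest penetration over local thickness, maximized over valid rays."""
    thick = profile.r_serosa - r_junction_hat
    usable = profile.valid & (thick >= DEGENERATE_THICKNESS)
    flags = []
    if not np.any(usable):
        raise ValueError("all rays degenerate: no measurable myometrium")
    if usable.sum() < 0.5 * profile.valid.sum():
        flags.append("many_degenerate_rays")
    depth = np.maximum(0.0, profile.r_lesion[usable] - r_junction_hat[usable])
    f = depth / np.maximum(thick[usable], _EPS)
    fraction = float(np.clip(f.max(), 0.0, 1.0))
    return InvasionEstimate(
        fraction=fraction,
        per_slice_fractions=[fraction],
        n_valid_rays=int(usable.sum()),
        fit_order=-1,
        flags=flags,
    )


def stage_case(per_slice_fractions: list[float],
               cutoff: float = STAGE_CUTOFF) -> StageCall:
    """Stage a case from its per-slice fractions: deepest invasion governs.

    The cutoff is inclusive: a fraction of exactly 0.5 is stage IB.
    """
    if len(per_slice_fractions) == 0:
        raise ValueError("need at least one slice fraction")
    fraction = float(max(per_slice_fractions))
    stage = "IB" if fraction >= cutoff else "IA"
    return StageCall(stage=stage, fraction=fraction, cutoff=cutoff)


def estimate_case(uterus_mask: np.ndarray, lesion_mask: np.ndarray,
                  n_rays: int = 720, fit_order: int = 2) -> InvasionEstimate:
    """Full per-slice pipeline: rays -> junction fit -> fraction."""
    profile = ray_profile(uterus_mask, lesion_mask, n_rays=n_rays)
    r_hat = estimate_junction(profile, fit_order=fit_order)
    est = invasion_fraction(profile, r_hat)
    est.fit_order = fit_order
    return est
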