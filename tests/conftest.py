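import math

import numpy as np
import pytest

from myoinvade import phantom as ph


@pytest.fixture(scope="session")
def deep_invasion_case():
    """One phantom with a deep (75%) invasion front and a fixed seed."""
    params = ph.PhantomParams(
        target_fraction=0.75, seed=3, lesion_angle=1.1,
        cavity_coeffs=((1.2, 0.3), (0.2, 0.8), (0.3, 0.1)),
    )
    return ph.generate_phantom(params)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-case cohort reused by read-only tests."""
    return ph.generate_cohort(ph.CohortSpec(n_cases=12, seed=5))


def brute_force_fraction(case: ph.PhantomCase, n_angles: int = 720) -> float:
    """Independent oracle: exhaustive per-angle scan of the emitted masks.

    Re-rasterizes the baseline cavity from the case's stored junction
    samples and scans every angle with an explicit loop, bilinear
    sub-pixel boundary localization, measuring max depth over thickness —
    the same geometric definition as the generator, implemented
    independently.
    """
    lesion = case.lesion_mask
    uterus = case.uterus_mask
    h, w = uterus.shape
    cy, cx = h / 2.0, w / 2.0
    theta_t, r_t = case.junction_truth

    # independent baseline rasterization (point-in-region test per pixel)
    base = np.zeros_like(lesion)
    for y in range(h):
        for x in range(w):
            ang = math.atan2(y - cy, x - cx) % (2 * math.pi)
            rj = np.interp(ang, theta_t, r_t, period=2 * math.pi)
            if math.hypot(y - cy, x - cx) <= rj:
                base[y, x] = True

    def bilinear(mask, yy, xx):
        y0, x0 = int(math.floor(yy)), int(math.floor(xx))
        y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
        fy, fx = yy - y0, xx - x0
        return (mask[y0, x0] * (1 - fy) * (1 - fx) + mask[y1, x0] * fy * (1 - fx)
                + mask[y0, x1] * (1 - fy) * fx + mask[y1, x1] * fy * fx)

    step = 0.25
    best = 0.0
    for k in range(n_angles):
        ang = 2 * math.pi * k / n_angles
        s, c = math.sin(ang), math.cos(ang)
        r_les = r_base = r_ser = 0.0
        r = step
        while r < max(h, w):
            yy, xx = cy + r * s, cx + r * c
            if 0 <= yy <= h - 1 and 0 <= xx <= w - 1:
                if bilinear(lesion.astype(float), yy, xx) >= 0.5:
                    r_les += step
                if bilinear(base.astype(float), yy, xx) >= 0.5:
                    r_base += step
                if bilinear(uterus.astype(float), yy, xx) >= 0.5:
                    r_ser += step
            r += step
        thick = r_ser - r_base
        if thick >= 2.0:
            best = max(best, max(0.0, r_les - r_base) / thick)
    return min(best, 1.0)
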