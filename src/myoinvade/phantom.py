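"""Synthetic sagittal uterine phantoms with known myometrial-invasion depth.

Each phantom is a 2D grayscale slice pair (contrast-enhanced-T1w-like and
T2w-like) with ground-truth binary masks for the whole uterus and for the
endometrial compartment (baseline endometrium plus invading lesion), built
from smooth radial profiles around a common center:

* ``r_serosa(theta)`` — outer uterine boundary (an ellipse, optionally bulged
  by a leiomyoma),
* ``r_junction(theta)`` — baseline endomyometrial junction, a low-order
  trigonometric curve (optionally dented where a leiomyoma compresses the
  wall),
* ``r_lesion(theta)`` — junction plus a tapered radial protrusion whose peak
  penetrates a controllable fraction of the local myometrial thickness.

The realized invasion fraction is measured back from the rasterized masks
(maximum over rays of penetration depth divided by myometrial thickness), so
the recorded truth reflects exactly what a mask-based estimator can see.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._rays import ray_extents as _ray_extent

__all__ = [
    "PhantomParams",
    "LeiomyomaSpec",
    "TruthRecord",
    "PhantomCase",
    "CohortSpec",
    "PhantomGeometryError",
    "generate_phantom",
    "generate_cohort",
    "measure_fraction_from_masks",
    "DEFAULT_INTENSITIES",
]

MODALITIES = ("t1c", "t2")

#: Mean tissue intensity per modality, on a nominal [0, 1] display scale.
#: On contrast-enhanced T1w the myometrium enhances brightly while the
#: endometrial lesion stays hypointense; on T2w the endometrium/lesion is
#: bright against darker myometrium. Leiomyomas sit between (T1c) or below
#: (T2, classically dark fibroids).
DEFAULT_INTENSITIES: dict[str, dict[str, float]] = {
    "t1c": {"background": 0.10, "myometrium": 0.70, "lesion": 0.35, "leiomyoma": 0.50},
    "t2": {"background": 0.15, "myometrium": 0.30, "lesion": 0.80, "leiomyoma": 0.20},
}


class PhantomGeometryError(ValueError):
    """Raised when a parameter combination yields impossible anatomy."""


@dataclass(frozen=True)
class LeiomyomaSpec:
    """A benign fibroid: a disc in the myometrium that deforms the wall.

    ``compression`` scales how strongly the disc displaces the serosa
    outward and dents the endomyometrial junction inward around its angular
    position — the geometric confounder that degrades junction-based depth
    estimation.
    """

    angle: float  # radians, angular position of the disc center
    radius: float  # pixels
    compression: float = 0.6  # dimensionless, >= 0


@dataclass(frozen=True)
class PhantomParams:
    canvas_size: int = 128
    uterus_axes: tuple[float, float] = (52.0, 40.0)
    rotation: float = 0.0  # radians, ellipse orientation
    cavity_radius: float = 16.0  # baseline junction mean radius r0
    cavity_coeffs: tuple[tuple[float, float], ...] = ((1.5, 0.0), (0.0, 1.0), (0.5, 0.0))
    target_fraction: float = 0.0
    lesion_angle: float = 0.0  # radians, protrusion center
    lesion_angular_extent: float = math.pi / 2
    leiomyoma: LeiomyomaSpec | None = None
    intensity_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: DEFAULT_INTENSITIES
    )
    noise_sd: float = 0.03
    seed: int = 0
    case_id: str = "phantom-000"

    def validate(self) -> None:
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in [0, 1]")
        if not 0.0 < self.lesion_angular_extent < 2 * math.pi:
            raise ValueError("lesion_angular_extent must lie in (0, 2*pi)")
        if self.canvas_size < 16:
            raise ValueError("canvas_size too small")
        if min(self.uterus_axes) <= self.cavity_radius:
            raise PhantomGeometryError(
                "cavity must lie strictly inside the uterus ellipse"
            )
        if len(self.cavity_coeffs) > 3:
            raise ValueError("junction harmonics limited to order 3")


@dataclass(frozen=True)
class TruthRecord:
    true_fraction: float
    true_stage: str  # "IA" or "IB"
    leiomyoma_present: bool
    histology_type: str = "I"  # covariate label only: "I" or "II"

    def __post_init__(self) -> None:
        expected = "IB" if self.true_fraction >= 0.5 else "IA"
        if self.true_stage != expected:
            raise ValueError(
                f"stage {self.true_stage!r} inconsistent with fraction "
                f"{self.true_fraction:.4f} under the >=50% rule"
            )


@dataclass
class PhantomCase:
    case_id: str
    images: dict[str, np.ndarray]  # modality -> float 2D image
    uterus_mask: np.ndarray  # bool 2D
    lesion_mask: np.ndarray  # bool 2D, endometrium + lesion
    junction_truth: tuple[np.ndarray, np.ndarray]  # (theta, r_junction(theta))
    truth: TruthRecord
    params: PhantomParams | None = None


@dataclass(frozen=True)
class CohortSpec:
    """Sampling law for a phantom cohort shaped like the study population.

    Defaults reproduce the reported cohort composition: 26.4% stage IB,
    40.3% leiomyoma prevalence, ~18% type-II histology, with per-stage
    invasion fractions drawn uniformly over the observed pathological
    ranges (IA in [0, 0.48], IB in [0.5, 0.87]).
    """

    n_cases: int = 72
    stage_mix: float = 19 / 72  # proportion IB
    leiomyoma_prevalence: float = 29 / 72
    type_ii_prevalence: float = 13 / 72
    ia_fraction_range: tuple[float, float] = (0.0, 0.48)
    ib_fraction_range: tuple[float, float] = (0.5, 0.87)
    canvas_size: int = 128
    noise_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for name in ("stage_mix", "leiomyoma_prevalence", "type_ii_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# radial profiles
# ---------------------------------------------------------------------------

_N_THETA = 1440  # dense profile grid used for rasterization and truth


def _theta_grid() -> np.ndarray:
    return np.linspace(0.0, 2 * math.pi, _N_THETA, endpoint=False)


def _ellipse_radius(theta: np.ndarray, a: float, b: float, rot: float) -> np.ndarray:
    t = theta - rot
    return a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)


def _wrapped_gaussian(theta: np.ndarray, center: float, width: float) -> np.ndarray:
    d = np.angle(np.exp(1j * (theta - center)))
    return np.exp(-0.5 * (d / width) ** 2)


def _profiles(params: PhantomParams) -> dict[str, np.ndarray]:
    """Analytic radial profiles sampled on the dense theta grid."""
    theta = _theta_grid()
    a, b = params.uterus_axes
    r_serosa = _ellipse_radius(theta, a, b, params.rotation)

    r_junction = np.full_like(theta, params.cavity_radius)
    for k, (ck, sk) in enumerate(params.cavity_coeffs, start=1):
        r_junction = r_junction + ck * np.cos(k * theta) + sk * np.sin(k * theta)

    if params.leiomyoma is not None:
        lm = params.leiomyoma
        # Angular footprint of the disc at mid-myometrial depth.
        mid_r = float(np.interp(lm.angle, theta, (r_junction + r_serosa) / 2.0,
                                period=2 * math.pi))
        width = max(0.15, lm.radius / max(mid_r, 1e-6))
        bump = _wrapped_gaussian(theta, lm.angle, width)
        r_serosa = r_serosa + lm.compression * lm.radius * bump
        r_junction = np.maximum(r_junction - lm.compression * lm.radius * bump, 3.0)

    if np.any(r_junction >= r_serosa - 3.0):
        raise PhantomGeometryError(
            "myometrium too thin: lesion would exit the uterus "
            "(r_junction approaches r_serosa)"
        )

    # Tapered protrusion: cosine window peaking at exactly target_fraction.
    d = np.angle(np.exp(1j * (theta - params.lesion_angle)))
    half = params.lesion_angular_extent / 2.0
    taper = np.where(np.abs(d) <= half, 0.5 * (1 + np.cos(math.pi * d / half)), 0.0)
    r_lesion = r_junction + params.target_fraction * taper * (r_serosa - r_junction)

    return {"theta": theta, "serosa": r_serosa, "junction": r_junction,
            "lesion": r_lesion}


def _rasterize(radius_profile: np.ndarray, theta: np.ndarray,
               canvas: int, center: tuple[float, float]) -> np.ndarray:
    """Binary mask of the star-shaped region r <= profile(theta)."""
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    dy = yy - center[0]
    dx = xx - center[1]
    r = np.hypot(dy, dx)
    ang = np.mod(np.arctan2(dy, dx), 2 * math.pi)
    bound = np.interp(ang, theta, radius_profile, period=2 * math.pi)
    return r <= bound


# ---------------------------------------------------------------------------
# mask-based truth measurement
# ---------------------------------------------------------------------------



def measure_fraction_from_masks(
    lesion_mask: np.ndarray,
    baseline_mask: np.ndarray,
    uterus_mask: np.ndarray,
    center: tuple[float, float],
    n_rays: int = _N_THETA,
    min_thickness: float = 2.0,
) -> float:
    """Realized invasion fraction: max over rays of depth / local thickness.

    Depth is the lesion's radial excess over the baseline cavity; thickness
    is serosa minus baseline junction, both measured from the rasterized
    masks with the same ray estimator.
    """
    thetas = np.linspace(0.0, 2 * math.pi, n_rays, endpoint=False)
    r_max = float(max(lesion_mask.shape))
    r_les = _ray_extent(lesion_mask, center, thetas, r_max)
    r_base = _ray_extent(baseline_mask, center, thetas, r_max)
    r_ser = _ray_extent(uterus_mask, center, thetas, r_max)
    thick = r_ser - r_base
    valid = thick >= min_thickness
    if not np.any(valid):
        raise PhantomGeometryError("no ray with measurable myometrial thickness")
    f = np.maximum(0.0, r_les[valid] - r_base[valid]) / thick[valid]
    return float(np.clip(f.max(), 0.0, 1.0))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_phantom(params: PhantomParams) -> PhantomCase:
    """Build one phantom slice pair; deterministic given ``params.seed``."""
    params.validate()
    prof = _profiles(params)
    canvas = params.canvas_size
    scale = canvas / 128.0  # geometry defaults are stated at 128 px
    center = (canvas / 2.0, canvas / 2.0)

    theta = prof["theta"]
    serosa = prof["serosa"] * scale
    junction = prof["junction"] * scale
    lesion = prof["lesion"] * scale

    uterus_mask = _rasterize(serosa, theta, canvas, center)
    lesion_mask = _rasterize(lesion, theta, canvas, center)
    baseline_mask = _rasterize(junction, theta, canvas, center)
    lesion_mask &= uterus_mask
    baseline_mask &= lesion_mask

    if params.target_fraction == 0.0:
        true_fraction = 0.0
    else:
        true_fraction = measure_fraction_from_masks(
            lesion_mask, baseline_mask, uterus_mask, center
        )

    rng = np.random.default_rng(params.seed)
    myometrium = uterus_mask & ~lesion_mask
    images: dict[str, np.ndarray] = {}
    for modality in MODALITIES:
        table = params.intensity_table[modality]
        img = np.full((canvas, canvas), table["background"], dtype=np.float64)
        img[myometrium] = table["myometrium"]
        img[lesion_mask] = table["lesion"]
        if params.leiomyoma is not None:
            lm = params.leiomyoma
            mid_r = float(
                np.interp(lm.angle, theta, (junction + serosa) / 2.0,
                          period=2 * math.pi)
            )
            cy = center[0] + mid_r * math.sin(lm.angle)
            cx = center[1] + mid_r * math.cos(lm.angle)
            yy, xx = np.mgrid[0:canvas, 0:canvas]
            disc = (np.hypot(yy - cy, xx - cx) <= lm.radius * scale) & myometrium
            img[disc] = table["leiomyoma"]
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, img.shape)
        images[modality] = img

    truth = TruthRecord(
        true_fraction=true_fraction,
        true_stage="IB" if true_fraction >= 0.5 else "IA",
        leiomyoma_present=params.leiomyoma is not None,
    )
    return PhantomCase(
        case_id=params.case_id,
        images=images,
        uterus_mask=uterus_mask,
        lesion_mask=lesion_mask,
        junction_truth=(theta.copy(), junction.copy()),
        truth=truth,
        params=params,
    )


def _sample_params(rng: np.random.Generator, spec: CohortSpec, *,
                   stage_ib: bool, leiomyoma: bool, case_id: str) -> PhantomParams:
    lo, hi = spec.ib_fraction_range if stage_ib else spec.ia_fraction_range
    frac = float(rng.uniform(lo, hi))
    coeffs = tuple(
        (float(rng.uniform(-amp, amp)), float(rng.uniform(-amp, amp)))
        for amp in (1.8, 1.2, 0.7)
    )
    lesion_angle = float(rng.uniform(0, 2 * math.pi))
    lm = None
    if leiomyoma:
        # Fibroids adjacent to the tumor bed are the ones that distort
        # invasion-depth assessment; place the disc near the lesion sector.
        lm = LeiomyomaSpec(
            angle=float(lesion_angle + rng.normal(0.0, 0.4)),
            radius=float(rng.uniform(6.0, 11.0)),
            compression=float(rng.uniform(0.4, 0.8)),
        )
    return PhantomParams(
        canvas_size=spec.canvas_size,
        uterus_axes=(float(rng.uniform(46, 56)), float(rng.uniform(34, 42))),
        rotation=float(rng.uniform(-0.3, 0.3)),
        cavity_radius=float(rng.uniform(13.0, 18.0)),
        cavity_coeffs=coeffs,
        target_fraction=frac,
        lesion_angle=lesion_angle,
        lesion_angular_extent=float(rng.uniform(math.pi / 3, 2 * math.pi / 3)),
        leiomyoma=lm,
        noise_sd=spec.noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
        case_id=case_id,
    )


def generate_cohort(spec: CohortSpec) -> list[PhantomCase]:
    """Generate a phantom cohort with exact stage/leiomyoma allocation.

    Counts of IB cases and leiomyoma carriers are the rounded expected
    counts (e.g. the default spec at n=72 yields exactly 53 IA / 19 IB and
    29 leiomyomas), assigned to cases in a seed-determined shuffle so the
    two covariates are independent. A case whose sampled geometry is
    rejected (implausibly thin myometrium) is resampled with a fresh
    child seed; the final fraction may drift slightly during rasterization
    but the sampled target keeps the case on its allocated side of 50%.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases
    n_ib = int(round(spec.stage_mix * n))
    n_lm = int(round(spec.leiomyoma_prevalence * n))
    n_t2 = int(round(spec.type_ii_prevalence * n))

    stage_flags = np.zeros(n, dtype=bool)
    stage_flags[:n_ib] = True
    rng.shuffle(stage_flags)
    lm_flags = np.zeros(n, dtype=bool)
    lm_flags[:n_lm] = True
    rng.shuffle(lm_flags)
    t2_flags = np.zeros(n, dtype=bool)
    t2_flags[:n_t2] = True
    rng.shuffle(t2_flags)

    cases: list[PhantomCase] = []
    for i in range(n):
        case_id = f"phantom-{i:03d}"
        for _attempt in range(20):
            params = _sample_params(
                rng, spec, stage_ib=bool(stage_flags[i]),
                leiomyoma=bool(lm_flags[i]), case_id=case_id,
            )
            try:
                case = generate_phantom(params)
            except PhantomGeometryError:
                continue
            # keep the realized fraction on the allocated side of the cutoff
            if bool(stage_flags[i]) != (case.truth.true_fraction >= 0.5):
                continue
            break
        else:  # pragma: no cover - would need pathological spec bounds
            raise PhantomGeometryError(f"could not sample a valid case for {case_id}")
        case.truth = replace(case.truth, histology_type="II" if t2_flags[i] else "I")
        cases.append(case)
    return cases
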