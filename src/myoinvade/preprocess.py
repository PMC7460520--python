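"""Image standardization, cropping, augmentation, and cohort splitting.

Mirrors the study's preparation of sagittal MR slices: per-image intensity
standardization ``P' = (P - mean) / std``, center-cropping to a square
working resolution, train-only geometric/intensity augmentation, and the
24 / 6 / 42 train / validation / test split (with the evaluation pool being
validation + test in study-faithful mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, resize, warp

__all__ = [
    "StandardizedImage",
    "AugmentPlan",
    "SplitAssignment",
    "standardize",
    "crop_resize",
    "augment",
    "split_cohort",
]


@dataclass(frozen=True)
class StandardizedImage:
    pixels: np.ndarray  # zero-mean, unit-variance
    source_mean: float
    source_std: float


def standardize(img: np.ndarray) -> StandardizedImage:
    """Whole-image standardization ``P' = (P - Pmean) / Pstd``.

    ``Pstd`` is the population standard deviation over all pixels
    (denominator ``n``). A constant image has no well-defined
    standardization and raises ``ValueError``.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 8:
        raise ValueError("expected a 2D image with sides >= 8")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    mean = float(arr.mean())
    std = float(arr.std())  # population (ddof=0)
    if std == 0.0:
        raise ValueError("constant image: standard deviation is zero")
    return StandardizedImage((arr - mean) / std, mean, std)


def crop_resize(img: np.ndarray, target: int, *, is_mask: bool = False) -> np.ndarray:
    """Center-crop to the largest centered square, then resample to target².

    Images are resampled bilinearly; masks with nearest-neighbor so they
    stay binary.
    """
    if target < 8:
        raise ValueError("target size must be >= 8")
    arr = np.asarray(img)
    h, w = arr.shape
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    sq = arr[r0:r0 + side, c0:c0 + side]
    if side == target:
        return sq.copy()
    order = 0 if is_mask else 1
    out = resize(sq.astype(np.float64), (target, target), order=order,
                 preserve_range=True, anti_aliasing=not is_mask)
    if is_mask:
        return out > 0.5 if arr.dtype == bool else out.astype(arr.dtype)
    return out


@dataclass(frozen=True)
class AugmentPlan:
    """Which augmentation ops to apply, with their ranges.

    ``multiply`` is read as intensity scaling; set ``replicate`` > 1 for the
    alternate dataset-replication reading (emits extra jittered affines).
    """

    hflip: bool = True
    vflip: bool = True
    affine: bool = True
    multiply: bool = True
    max_rotation_deg: float = 15.0
    max_translation: float = 0.05  # fraction of side
    scale_range: tuple[float, float] = (0.9, 1.1)
    multiply_range: tuple[float, float] = (0.8, 1.2)
    replicate: int = 1


def _random_affine(rng: np.random.Generator, shape: tuple[int, int],
                   plan: AugmentPlan) -> AffineTransform:
    rot = math.radians(rng.uniform(-plan.max_rotation_deg, plan.max_rotation_deg))
    scale = rng.uniform(*plan.scale_range)
    ty = rng.uniform(-plan.max_translation, plan.max_translation) * shape[0]
    tx = rng.uniform(-plan.max_translation, plan.max_translation) * shape[1]
    # rotate/scale about the image center
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    center = AffineTransform(translation=(-cx, -cy))
    core = AffineTransform(rotation=rot, scale=(scale, scale))
    back = AffineTransform(translation=(cx + tx, cy + ty))
    return center + core + back


def augment(
    img: np.ndarray,
    mask: np.ndarray,
    plan: AugmentPlan | None = None,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Emit the original plus augmented (image, mask) pairs.

    Geometric ops (flips, random small affine) are applied identically to
    image and mask (mask warped nearest-neighbor); intensity multiplication
    touches the image only. Deterministic given ``seed``.
    """
    img = np.asarray(img, dtype=np.float64)
    mask_arr = np.asarray(mask)  # (H, W) or (C, H, W) for multi-structure
    if mask_arr.shape[-2:] != img.shape:
        raise ValueError(
            f"image shape {img.shape} and mask shape {mask_arr.shape} differ"
        )
    plan = plan or AugmentPlan()
    rng = np.random.default_rng(seed)

    def warp_pair(tform: AffineTransform) -> tuple[np.ndarray, np.ndarray]:
        wi = warp(img, tform.inverse, order=1, preserve_range=True)
        if mask_arr.ndim == 2:
            wm = warp(mask_arr.astype(np.float64), tform.inverse, order=0,
                      preserve_range=True) > 0.5
        else:
            wm = np.stack([
                warp(m.astype(np.float64), tform.inverse, order=0,
                     preserve_range=True) > 0.5
                for m in mask_arr
            ])
        return wi, wm

    out: list[tuple[np.ndarray, np.ndarray]] = [(img.copy(), mask_arr.copy())]
    if plan.hflip:
        out.append((img[:, ::-1].copy(), mask_arr[..., :, ::-1].copy()))
    if plan.vflip:
        if mask_arr.ndim == 2:
            out.append((img[::-1, :].copy(), mask_arr[::-1, :].copy()))
        else:
            out.append((img[::-1, :].copy(), mask_arr[:, ::-1, :].copy()))
    if plan.affine:
        for _ in range(max(1, plan.replicate)):
            out.append(warp_pair(_random_affine(rng, img.shape, plan)))
    if plan.multiply:
        factor = rng.uniform(*plan.multiply_range)
        out.append((img * factor, mask_arr.copy()))
    return out


@dataclass(frozen=True)
class SplitAssignment:
    labels: dict[str, str] = field(default_factory=dict)  # case_id -> split
    strict: bool = False

    def cases(self, split: str) -> list[str]:
        return [cid for cid, s in self.labels.items() if s == split]

    @property
    def evaluation_group(self) -> list[str]:
        """Cases used to appraise accuracy.

        Study-faithful mode pools validation and test cases (the study
        evaluated 42 test + 6 validation patients = 48); strict mode uses
        the test cases only.
        """
        if self.strict:
            return self.cases("test")
        return self.cases("validation") + self.cases("test")


def split_cohort(
    case_ids: list[str],
    *,
    train_fraction: float = 1 / 3,
    val_count: int = 6,
    seed: int = 0,
    stratify_by_stage: dict[str, str] | None = None,
    strict: bool = False,
) -> SplitAssignment:
    """Partition a cohort into train / validation / test.

    With the defaults and 72 cases this reproduces the study's 24 / 6 / 42
    split (evaluation group of 48). With ``stratify_by_stage`` (a
    case_id -> stage mapping) the train and validation draws are stratified
    so stage proportions are preserved within one case per split.
    """
    n = len(case_ids)
    n_train = int(round(train_fraction * n))
    if n_train < 1 or val_count < 0 or n_train + val_count >= n + 1:
        raise ValueError(
            f"cannot split {n} cases into {n_train} train + {val_count} validation"
        )
    rng = np.random.default_rng(seed)

    def draw(pool: list[str], k: int) -> list[str]:
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in sorted(idx)]

    if stratify_by_stage is None:
        train = draw(case_ids, n_train)
        rest = [c for c in case_ids if c not in train]
        val = draw(rest, val_count)
    else:
        strata: dict[str, list[str]] = {}
        for cid in case_ids:
            strata.setdefault(stratify_by_stage[cid], []).append(cid)
        train, val = [], []
        # largest-remainder apportionment per stratum
        for part, total, chosen in (("train", n_train, train),
                                    ("val", val_count, val)):
            pools = {
                s: [c for c in members if c not in train and c not in val]
                for s, members in strata.items()
            }
            avail = sum(len(p) for p in pools.values())
            quotas = {s: total * len(p) / avail for s, p in pools.items()} \
                if avail else {}
            base = {s: int(math.floor(q)) for s, q in quotas.items()}
            rem = total - sum(base.values())
            order = sorted(quotas, key=lambda s: quotas[s] - base[s], reverse=True)
            for s in order[:rem]:
                base[s] += 1
            for s, k in base.items():
                chosen.extend(draw(pools[s], min(k, len(pools[s]))))
    labels = {}
    taken = set(train) | set(val)
    for cid in case_ids:
        if cid in train:
            labels[cid] = "train"
        elif cid in val:
            labels[cid] = "validation"
        else:
            labels[cid] = "test"
    assert len(taken) == len(train) + len(val)
    return SplitAssignment(labels=labels, strict=strict)
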