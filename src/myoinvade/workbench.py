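"""Orchestration: configuration, case I/O, and the end-to-end experiment.

``run_experiment`` ties the pipeline together: phantom cohort generation ->
train/validation/test split -> preprocessing (augmentation on the training
fold only) -> segmentation training -> prediction on the evaluation pool ->
invasion-depth staging -> concordance report. All randomness is derived
from one global seed via spawned child seeds, so a rerun with the same
configuration reproduces the staging table exactly (single-threaded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from . import preprocess as pp
from . import segmentation as seg
from . import staging
from . import stats as st

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "ExperimentResult",
    "run_experiment",
    "write_case",
    "read_case",
    "write_truth_table",
    "load_config",
    "save_config",
    "parameter_recovery_experiment",
    "leiomyoma_contrast_experiment",
    "desk_training_experiment",
]


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: ph.CohortSpec = field(default_factory=ph.CohortSpec)
    target_size: int = 128
    modality: str = "t1c"
    augment: pp.AugmentPlan = field(default_factory=pp.AugmentPlan)
    model: seg.ModelSpec = field(default_factory=seg.ModelSpec)
    train: seg.TrainConfig = field(default_factory=seg.TrainConfig)
    n_rays: int = 720
    fit_order: int = 2
    train_fraction: float = 1 / 3
    val_count: int = 6
    strict_evaluation: bool = False  # False: evaluation pool = validation + test
    seed: int = 0

    def child_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31 - 1)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))


def _tupled(d: dict) -> dict:
    """YAML round-trip turns tuples into lists; restore tuple fields."""
    return {k: (tuple(tuple(x) if isinstance(x, list) else x for x in v)
                if isinstance(v, list) else v)
            for k, v in d.items()} if d else d


def load_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    cohort = ph.CohortSpec(**_tupled(raw.pop("cohort", {})))
    augment = pp.AugmentPlan(**_tupled(raw.pop("augment", {})))
    model = seg.ModelSpec(**_tupled(raw.pop("model", {})))
    train = seg.TrainConfig(**raw.pop("train", {}))
    return ExperimentConfig(cohort=cohort, augment=augment, model=model,
                            train=train, **raw)


def config_hash(cfg: ExperimentConfig) -> str:
    return hashlib.sha256(
        yaml.safe_dump(_to_plain(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    software_version: str
    started: float
    finished: float | None = None
    stages: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def log(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, "time": time.time(), **info})


@dataclass
class ExperimentResult:
    manifest: RunManifest
    report: st.CohortReport
    staging_table: pd.DataFrame
    curves: pd.DataFrame
    metrics: seg.MetricRecord
    split: pp.SplitAssignment


def _prepare_case(case: ph.PhantomCase, modality: str,
                  target: int) -> tuple[np.ndarray, np.ndarray]:
    img = pp.crop_resize(case.images[modality], target)
    img = pp.standardize(img).pixels
    masks = np.stack([
        pp.crop_resize(case.uterus_mask, target, is_mask=True),
        pp.crop_resize(case.lesion_mask, target, is_mask=True),
    ])
    return img.astype(np.float32), masks.astype(np.float32)


def run_experiment(cfg: ExperimentConfig,
                   out_dir: str | Path | None = None) -> ExperimentResult:
    """Execute the full phantom-to-report pipeline."""
    from . import __version__

    manifest = RunManifest(config_hash=config_hash(cfg),
                           software_version=__version__, started=time.time())

    cohort_spec = dataclasses.replace(cfg.cohort, seed=cfg.child_seed("cohort"))
    cases = ph.generate_cohort(cohort_spec)
    by_id = {c.case_id: c for c in cases}
    manifest.log("phantom", n_cases=len(cases))

    split = pp.split_cohort(
        [c.case_id for c in cases],
        train_fraction=cfg.train_fraction, val_count=cfg.val_count,
        seed=cfg.child_seed("split"),
        stratify_by_stage={c.case_id: c.truth.true_stage for c in cases},
        strict=cfg.strict_evaluation,
    )
    manifest.log("split", train=len(split.cases("train")),
                 validation=len(split.cases("validation")),
                 test=len(split.cases("test")))

    prepared = {cid: _prepare_case(by_id[cid], cfg.modality, cfg.target_size)
                for cid in by_id}
    aug_seed = cfg.child_seed("augment")
    x_tr, y_tr = [], []
    for i, cid in enumerate(split.cases("train")):
        img, masks = prepared[cid]
        for a_img, a_mask in pp.augment(img, masks, cfg.augment,
                                        seed=aug_seed + i):
            x_tr.append(a_img[None])
            y_tr.append(a_mask)
    x_va = np.stack([prepared[cid][0][None]
                     for cid in split.cases("validation")])
    y_va = np.stack([prepared[cid][1] for cid in split.cases("validation")])
    manifest.log("preprocess", n_train_images=len(x_tr),
                 augmented_only_in_train=True)

    model = seg.build_model(cfg.model, seed=cfg.child_seed("init"))
    train_cfg = dataclasses.replace(cfg.train, seed=cfg.child_seed("train"))
    metrics = seg.train(model, np.stack(x_tr), np.stack(y_tr),
                        x_va, y_va, train_cfg)
    manifest.log("train", best_epoch=metrics.best_epoch,
                 val_iou=metrics.iou)

    rows = []
    for cid in split.evaluation_group:
        case = by_id[cid]
        img, _ = prepared[cid]
        out = seg.predict_masks(model, img, case_id=cid)
        flags = list(out.flags)
        if out.masks["uterus"].any() and out.masks["lesion"].any():
            try:
                est = staging.estimate_case(out.masks["uterus"],
                                            out.masks["lesion"],
                                            n_rays=cfg.n_rays,
                                            fit_order=cfg.fit_order)
                fraction = est.fraction
                n_valid = est.n_valid_rays
                flags.extend(est.flags)
            except ValueError as exc:
                fraction, n_valid = 0.0, 0
                flags.append(f"staging_failed:{exc}")
        else:
            fraction, n_valid = 0.0, 0
            flags.append("unstageable_empty_mask")
        call = staging.stage_case([fraction])
        rows.append({
            "case_id": cid,
            "fraction": fraction,
            "stage": call.stage,
            "true_fraction": case.truth.true_fraction,
            "true_stage": case.truth.true_stage,
            "leiomyoma": case.truth.leiomyoma_present,
            "n_valid_rays": n_valid,
            "flags": ";".join(flags),
        })
    staging_table = pd.DataFrame(rows).sort_values("case_id").reset_index(drop=True)
    manifest.log("stage", n_evaluated=len(staging_table))

    report = st.cohort_report(
        staging_table["stage"], staging_table["true_stage"],
        pred_fractions=staging_table["fraction"],
        true_fractions=staging_table["true_fraction"],
        leiomyoma_flags=staging_table["leiomyoma"],
        evaluation_mode="strict" if cfg.strict_evaluation else "study-faithful",
    )
    manifest.log("stats", accuracy=report.summary.accuracy)
    manifest.finished = time.time()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        staging_table.to_csv(out / "staging.csv", index=False)
        metrics.curves.to_csv(out / "curves.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(_to_plain(report), indent=2, default=str))
        split_df = pd.DataFrame(
            sorted(split.labels.items()), columns=["case_id", "split"])
        split_df.to_csv(out / "split.csv", index=False)
        save_config(cfg, out / "config.yaml")
        manifest.outputs = ["staging.csv", "curves.csv", "report.json",
                            "split.csv", "config.yaml"]
        (out / "manifest.json").write_text(
            json.dumps(_to_plain(manifest), indent=2, default=str))
        missing = [f for f in manifest.outputs if not (out / f).exists()]
        assert not missing, f"manifest lists missing outputs: {missing}"

    return ExperimentResult(manifest=manifest, report=report,
                            staging_table=staging_table,
                            curves=metrics.curves, metrics=metrics, split=split)


# ---------------------------------------------------------------------------
# benchmark experiments (shared by the acceptance suite and scripts)
# ---------------------------------------------------------------------------

def _random_geometry(rng: np.random.Generator) -> dict:
    return dict(
        lesion_angular_extent=float(rng.uniform(np.pi / 3, 2 * np.pi / 3)),
        cavity_radius=float(rng.uniform(13.0, 18.0)),
        uterus_axes=(float(rng.uniform(46, 56)), float(rng.uniform(34, 42))),
        rotation=float(rng.uniform(-0.3, 0.3)),
        cavity_coeffs=tuple(
            (float(rng.uniform(-a, a)), float(rng.uniform(-a, a)))
            for a in (1.8, 1.2, 0.7)),
    )


def parameter_recovery_experiment(n: int = 200, seed: int = 20200818,
                                  n_rays: int = 720) -> pd.DataFrame:
    """Estimate invasion fractions from ground-truth masks of random phantoms.

    Leiomyoma-free phantoms with target fractions uniform on [0, 1]; returns
    per-case true and estimated fraction plus stage agreement — the
    mask-to-fraction estimator's parameter-recovery benchmark.
    """
    rng = np.random.default_rng(seed)
    rows = []
    while len(rows) < n:
        params = ph.PhantomParams(
            target_fraction=float(rng.uniform(0, 1)),
            lesion_angle=float(rng.uniform(0, 2 * np.pi)),
            seed=int(rng.integers(2**31)),
            **_random_geometry(rng),
        )
        try:
            case = ph.generate_phantom(params)
        except ph.PhantomGeometryError:
            continue
        est = staging.estimate_case(case.uterus_mask, case.lesion_mask,
                                    n_rays=n_rays)
        rows.append({
            "true_fraction": case.truth.true_fraction,
            "est_fraction": est.fraction,
            "true_stage": case.truth.true_stage,
            "est_stage": staging.stage_case([est.fraction]).stage,
        })
    df = pd.DataFrame(rows)
    df.attrs["rmse"] = float(np.sqrt(
        ((df.est_fraction - df.true_fraction) ** 2).mean()))
    df.attrs["stage_agreement"] = float(
        (df.true_stage == df.est_stage).mean())
    return df


def leiomyoma_contrast_experiment(n_pairs: int = 100, seed: int = 1,
                                  band: tuple[float, float] = (0.4, 0.6),
                                  n_rays: int = 360) -> dict[str, float]:
    """Matched-pair staging accuracy with vs without a juxta-lesional fibroid.

    Each pair shares geometry, seed, and target fraction (drawn from
    ``band``, the near-cutoff region where staging errors concentrate); one
    twin carries a leiomyoma adjacent to the lesion sector. Returns staging
    accuracy per arm, computed from ground-truth masks.
    """
    rng = np.random.default_rng(seed)
    correct = {"leiomyoma": [], "leiomyoma_free": []}
    for _ in range(n_pairs):
        tf = float(rng.uniform(*band))
        lesion_angle = float(rng.uniform(0, 2 * np.pi))
        geo = _random_geometry(rng)
        case_seed = int(rng.integers(2**31))
        lm = ph.LeiomyomaSpec(
            angle=float(lesion_angle + rng.normal(0, 0.4)),
            radius=float(rng.uniform(6, 11)),
            compression=float(rng.uniform(0.4, 0.8)),
        )
        for arm, fibroid in (("leiomyoma_free", None), ("leiomyoma", lm)):
            params = ph.PhantomParams(target_fraction=tf, seed=case_seed,
                                      lesion_angle=lesion_angle,
                                      leiomyoma=fibroid, **geo)
            try:
                case = ph.generate_phantom(params)
            except ph.PhantomGeometryError:
                continue
            est = staging.estimate_case(case.uterus_mask, case.lesion_mask,
                                        n_rays=n_rays)
            correct[arm].append(
                (est.fraction >= 0.5) == (case.truth.true_fraction >= 0.5))
    return {arm: float(np.mean(v)) for arm, v in correct.items()}


def desk_training_experiment(n_train: int = 60, n_val: int = 12,
                             epochs: int = 15, seed: int = 0,
                             canvas_size: int = 128,
                             modality: str = "t1c") -> seg.MetricRecord:
    """Train the tiny encoder-decoder on a phantom cohort and report val IoU.

    Desk-scale counterpart of the study's training runs: no augmentation,
    SGD on soft-Dice with gradient clipping and best-validation
    checkpointing, at a batch size and learning rate suited to the small
    randomly-initialized network (the published 0.001/150-epoch schedule
    belongs to pretrained encoders at full resolution).
    """
    spec = ph.CohortSpec(n_cases=n_train + n_val, canvas_size=canvas_size,
                         seed=seed)
    cases = ph.generate_cohort(spec)
    xs = np.stack([
        pp.standardize(c.images[modality]).pixels[None] for c in cases
    ]).astype(np.float32)
    ys = np.stack([
        np.stack([c.uterus_mask, c.lesion_mask]) for c in cases
    ]).astype(np.float32)
    model = seg.build_model(seg.ModelSpec("tiny"), seed=seed)
    cfg = seg.TrainConfig(batch_size=8, learning_rate=0.02, epochs=epochs,
                          seed=seed)
    return seg.train(model, xs[:n_train], ys[:n_train],
                     xs[n_train:], ys[n_train:], cfg)


# ---------------------------------------------------------------------------
# case I/O
# ---------------------------------------------------------------------------

def write_case(case: ph.PhantomCase, directory: str | Path,
               fmt: str = "png") -> list[Path]:
    """Write a phantom case to disk (PNG 16-bit or NIfTI) plus metadata.

    PNG images are quantized to 16 bits with the affine scale recorded in a
    sidecar, so masks and truth round-trip bit-identically and images to
    1/65535 of their range.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta = {"case_id": case.case_id, "format": fmt, "scales": {}}
    for modality, img in case.images.items():
        if fmt == "png":
            lo, hi = float(img.min()), float(img.max())
            scale = (hi - lo) or 1.0
            q = np.round((img - lo) / scale * 65535).astype(np.uint16)
            path = directory / f"{case.case_id}_{modality}.png"
            iio.imwrite(path, q)
            meta["scales"][modality] = {"lo": lo, "hi": hi}
        elif fmt == "nifti":
            path = directory / f"{case.case_id}_{modality}.nii.gz"
            nib.save(nib.Nifti1Image(img.astype(np.float64), np.eye(4)), path)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        written.append(path)
    for name, mask in (("uterus", case.uterus_mask), ("lesion", case.lesion_mask)):
        if fmt == "png":
            path = directory / f"{case.case_id}_mask_{name}.png"
            iio.imwrite(path, (mask.astype(np.uint8) * 255))
        else:
            path = directory / f"{case.case_id}_mask_{name}.nii.gz"
            nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), path)
        written.append(path)
    theta, r = case.junction_truth
    meta["junction_truth"] = {"theta": theta.tolist(), "r": r.tolist()}
    meta["truth"] = _to_plain(case.truth)
    meta_path = directory / f"{case.case_id}_meta.json"
    meta_path.write_text(json.dumps(meta))
    written.append(meta_path)
    return written


def _read_mask(path: Path) -> np.ndarray:
    """Read a binary mask tolerant of 0/1 and 0/255 encodings."""
    if path.suffix == ".png":
        arr = np.asarray(iio.imread(path))
    else:
        arr = np.asarray(nib.load(path).dataobj)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1, 255))):
        raise ValueError(f"mask {path} is not binary (values {uniq[:10]})")
    return arr > 0


def read_case(directory: str | Path, case_id: str) -> ph.PhantomCase:
    """Read back a case written by :func:`write_case`."""
    directory = Path(directory)
    meta = json.loads((directory / f"{case_id}_meta.json").read_text())
    fmt = meta["format"]
    images = {}
    for modality in ph.MODALITIES:
        if fmt == "png":
            q = np.asarray(iio.imread(directory / f"{case_id}_{modality}.png"),
                           dtype=np.float64)
            s = meta["scales"][modality]
            images[modality] = q / 65535 * (s["hi"] - s["lo"]) + s["lo"]
        else:
            images[modality] = np.asarray(
                nib.load(directory / f"{case_id}_{modality}.nii.gz").dataobj,
                dtype=np.float64)
    ext = "png" if fmt == "png" else "nii.gz"
    uterus = _read_mask(directory / f"{case_id}_mask_uterus.{ext}")
    lesion = _read_mask(directory / f"{case_id}_mask_lesion.{ext}")
    if uterus.shape != images["t1c"].shape:
        raise ValueError(
            f"image shape {images['t1c'].shape} != mask shape {uterus.shape}"
        )
    truth = ph.TruthRecord(**meta["truth"])
    jt = meta["junction_truth"]
    return ph.PhantomCase(
        case_id=case_id, images=images, uterus_mask=uterus, lesion_mask=lesion,
        junction_truth=(np.array(jt["theta"]), np.array(jt["r"])),
        truth=truth,
    )


def write_truth_table(cases: list[ph.PhantomCase], path: str | Path,
                      split: pp.SplitAssignment | None = None) -> pd.DataFrame:
    rows = [{
        "case_id": c.case_id,
        "true_fraction": c.truth.true_fraction,
        "true_stage": c.truth.true_stage,
        "leiomyoma": c.truth.leiomyoma_present,
        "histology_type": c.truth.histology_type,
        "split": split.labels.get(c.case_id, "") if split else "",
    } for c in cases]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
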