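"""File formats, configuration, and the end-to-end experiment driver.

Volumes and masks are stored as NIfTI (one file per case per role:
``<case>_image.nii.gz``, ``<case>_mask_<tissue>.nii.gz``), optionally as
per-slice 16-bit PNGs (``<case>_slice####.png``).  Boxes live in one JSON
file per directory: ``{case_id: {slice_index: {tissue: [rmin, cmin, rmax,
cmax]}}}``.  Metrics are CSV; configuration is YAML with sections
``phantom`` / ``train`` / ``iasal``; every run directory gets a JSON
manifest (config snapshot, seed, package version, artifact paths)
sufficient to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

import swsal
from swsal.annotations import SparseConfig
from swsal.iasal import AnnotationState, IasalSchedule, equivalent_workload, run_iasal
from swsal.network import BackboneConfig
from swsal.phantom import Box, PhantomConfig, Volume, generate_phantom
from swsal.trainer import (
    TrainConfig,
    evaluate_dice,
    pretrain_swssl,
    train_stage_sparse,
    volume_samples,
)

MASK_SUFFIX = "_mask_"


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def _nifti_write(path: Path, stack: np.ndarray) -> None:
    # store as (H, W, S) so slice i is [..., i]
    img = nib.Nifti1Image(np.transpose(stack, (1, 2, 0)), affine=np.eye(4))
    nib.save(img, str(path))


def _nifti_read(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(str(path))
    data = np.asarray(nib.load(str(path)).dataobj)
    return np.transpose(data, (2, 0, 1))


def _normalize_mask(arr: np.ndarray, path: Path) -> np.ndarray:
    vals = np.unique(arr)
    if np.all(np.isin(vals, (0, 1))):
        return arr.astype(np.uint8)
    if np.all(np.isin(vals, (0, 255))):
        warnings.warn(f"{path.name}: mask uses {{0,255}}; normalizing to {{0,1}}", stacklevel=3)
        return (arr > 0).astype(np.uint8)
    raise ValueError(f"{path.name}: mask values {vals[:10]} are not binary")


def write_volume(volume: Volume, out_dir: str | Path, png: bool = False) -> None:
    """Write a volume (image + per-tissue masks + boxes) into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _nifti_write(out / f"{volume.case_id}_image.nii.gz", volume.slices.astype(np.float64))
    for t in volume.tissue_names:
        _nifti_write(out / f"{volume.case_id}{MASK_SUFFIX}{t}.nii.gz", volume.gt_masks[t].astype(np.uint8))
    if png:
        for i, sl in enumerate(volume.slices):
            iio.imwrite(
                out / f"{volume.case_id}_slice{i:04d}.png",
                np.round(np.clip(sl, 0, 1) * 65535).astype(np.uint16),
            )
    boxes_path = out / "boxes.json"
    all_boxes = json.loads(boxes_path.read_text()) if boxes_path.exists() else {}
    all_boxes[volume.case_id] = {
        str(i): {
            t: list(map(int, b))
            for t in volume.tissue_names
            if (b := volume.gt_boxes[t][i]) is not None
        }
        for i in range(volume.n_slices)
    }
    boxes_path.write_text(json.dumps(all_boxes, indent=1, sort_keys=True))


def read_volume(data_dir: str | Path, case_id: str, tissue_names: list[str] | None = None) -> Volume:
    """Read one case back from a directory written by :func:`write_volume`."""
    d = Path(data_dir)
    slices = _nifti_read(d / f"{case_id}_image.nii.gz").astype(np.float64)
    if tissue_names is None:
        tissue_names = sorted(
            p.name.split(MASK_SUFFIX)[1].split(".nii")[0]
            for p in d.glob(f"{case_id}{MASK_SUFFIX}*.nii.gz")
        )
    masks = {}
    for t in tissue_names:
        mpath = d / f"{case_id}{MASK_SUFFIX}{t}.nii.gz"
        arr = _nifti_read(mpath)
        if arr.shape != slices.shape:
            raise ValueError(f"{mpath.name}: mask shape {arr.shape} != image shape {slices.shape}")
        masks[t] = _normalize_mask(arr, mpath)
    boxes = read_boxes(d).get(case_id, {})
    gt_boxes: dict[str, list[Box | None]] = {
        t: [None] * slices.shape[0] for t in tissue_names
    }
    for i_str, per_tissue in boxes.items():
        for t, b in per_tissue.items():
            if t in gt_boxes:
                gt_boxes[t][int(i_str)] = tuple(b)  # type: ignore[assignment]
    return Volume(case_id=case_id, slices=slices, gt_masks=masks, gt_boxes=gt_boxes, tissue_names=tissue_names)


def write_pseudo_labels(volume, pseudo, out_dir: str | Path) -> None:
    """Write region-grown pseudo-masks as NIfTI plus a JSON confidence report.

    Files: ``<case>_pseudo_<tissue>.nii.gz`` and ``<case>_pseudo_confidence.json``
    mapping ``"<tissue>/<slice>"`` to a boolean (False = growth stalled).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t, stack in pseudo.masks.items():
        _nifti_write(out / f"{volume.case_id}_pseudo_{t}.nii.gz", stack.astype(np.uint8))
    report = {f"{t}/{i}": bool(ok) for (t, i), ok in sorted(pseudo.confidence.items())}
    (out / f"{volume.case_id}_pseudo_confidence.json").write_text(json.dumps(report, indent=1))


def read_boxes(data_dir: str | Path) -> dict:
    path = Path(data_dir) / "boxes.json"
    if not path.exists():
        return {}
    return json.loads(path.read_text())


def list_cases(data_dir: str | Path) -> list[str]:
    return sorted(p.name[: -len("_image.nii.gz")] for p in Path(data_dir).glob("*_image.nii.gz"))


# ---------------------------------------------------------------------------
# configuration and manifest
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level of the config must be a mapping")
    return cfg


def parse_config(cfg: dict) -> tuple[PhantomConfig, SparseConfig, TrainConfig, BackboneConfig, IasalSchedule]:
    return (
        PhantomConfig(**cfg.get("phantom", {})),
        SparseConfig(**cfg.get("sparse", {})),
        TrainConfig(**cfg.get("train", {})),
        BackboneConfig(**cfg.get("network", {})),
        IasalSchedule(**cfg.get("iasal", {})),
    )


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-run a run directory bit-identically."""

    config: dict
    seed: int
    version: str
    checkpoints: dict[str, str]
    metrics: dict[str, str]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------


def run_experiment(config: dict | str | Path, out_dir: str | Path) -> RunManifest:
    """Generate phantoms, pretrain per tissue, run the annotation loop, evaluate.

    Emits per-stage metric CSVs and a manifest into ``out_dir``.  The split
    into train/val/test cases follows ``config["split"]`` (a 3-list,
    default proportional to 70/15/422 scaled to the case count, with at
    least one case each).
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phantom_cfg, sparse_cfg, train_cfg, backbone_cfg, sched = parse_config(cfg)
    volumes = generate_phantom(phantom_cfg)
    n = len(volumes)
    split = cfg.get("split")
    if split is None:
        n_train = max(1, int(round(n * 0.6)))
        n_val = max(1, int(round(n * 0.2)))
        n_train = min(n_train, n - 2) if n >= 3 else 1
        split = [n_train, n_val, n - n_train - n_val]
    if sum(split) != n or min(split) < 0 or split[0] == 0:
        raise ValueError(f"invalid split {split} for {n} cases")
    train_v = volumes[: split[0]]
    val_v = volumes[split[0] : split[0] + split[1]]
    test_v = volumes[split[0] + split[1] :]

    checkpoints: dict[str, str] = {}
    metrics: dict[str, str] = {}
    eval_rows = []
    for tissue in volumes[0].tissue_names:
        res = pretrain_swssl(train_v, val_v, tissue, train_cfg, sparse_cfg, backbone_cfg)
        for stage, hist in res.history.items():
            p = out / f"pretrain_{tissue}_{stage}.csv"
            hist.to_csv(p, index=False)
            metrics[f"pretrain_{tissue}_{stage}"] = p.name
        state = AnnotationState.from_sparse(train_v, res.sparse_indices)
        net, state, iasal_df = run_iasal(
            res.net, train_v, tissue, state, sched, train_cfg, test_volumes=test_v or val_v
        )
        p = out / f"iasal_{tissue}.csv"
        iasal_df.to_csv(p, index=False)
        metrics[f"iasal_{tissue}"] = p.name
        ckpt = out / f"model_{tissue}.npz"
        net.save(str(ckpt))
        checkpoints[tissue] = ckpt.name
        test_samples = volume_samples(test_v or val_v, tissue)
        eval_rows.append(
            {
                "tissue": tissue,
                "test_dice": evaluate_dice(net, test_samples),
                "ss": state.ss,
                "sbb": state.sbb,
                "seq": equivalent_workload(state.ss, state.sbb),
            }
        )
    p = out / "evaluation.csv"
    pd.DataFrame(eval_rows).to_csv(p, index=False)
    metrics["evaluation"] = p.name
    manifest = RunManifest(
        config=cfg,
        seed=train_cfg.seed,
        version=swsal.__version__,
        checkpoints=checkpoints,
        metrics=metrics,
    )
    manifest.write(out / "manifest.json")
    return manifest


def sparse_interval_sweep(
    intervals: list[int],
    phantom_cfg: PhantomConfig,
    train_cfg: TrainConfig,
    backbone_cfg: BackboneConfig,
    tissue: str = "bone",
    slice_budget: int | None = None,
) -> pd.DataFrame:
    """Dice as a function of the sparse annotation interval, at a fixed label budget.

    For each interval the same number of annotated slices is used (the
    budget defaults to what the largest interval yields), mirroring the
    fixed-total-slices design of interval ablations.
    """
    from swsal.annotations import select_sparse_slices
    from swsal.network import DualHeadNet

    volumes = generate_phantom(phantom_cfg)
    n_val = max(1, len(volumes) // 4)
    train_v, val_v = volumes[:-n_val], volumes[-n_val:]
    if slice_budget is None:
        slice_budget = min(
            sum(len(select_sparse_slices(v.n_slices, SparseConfig(s_int=i))) for v in train_v)
            for i in intervals
        )
    rows = []
    for s_int in intervals:
        indices = {}
        remaining = slice_budget
        for v in train_v:
            idx = select_sparse_slices(v.n_slices, SparseConfig(s_int=s_int))[:remaining]
            indices[v.case_id] = idx
            remaining -= len(idx)
        samples = volume_samples(train_v, tissue, indices)
        val_samples = volume_samples(val_v, tissue)
        net = DualHeadNet(backbone_cfg, seed=train_cfg.seed)
        net, _ = train_stage_sparse(net, samples, train_cfg, val_samples)
        rows.append(
            {"s_int": s_int, "n_slices": slice_budget - remaining, "val_dice": evaluate_dice(net, val_samples)}
        )
    return pd.DataFrame(rows)
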