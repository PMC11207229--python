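"""Three-stage semi-weakly supervised training.

Stage A  — sparse-label training: minimize area + edge loss on the few
           fully annotated slices (edge labels derived from the masks).
Stage B  — bounding-box training: minimize the pseudo-label area loss on
           region-grown pseudo-masks with the edge head frozen (derived
           pseudo-edges are too noisy to supervise), then repeatedly
           replace each pseudo-mask with the net's own binarized
           prediction and retrain (pseudo-label self-refinement).
Joint    — per round ``e_cur``, take a gradient pass over the pseudo set
           weighted by ``alpha`` (area + pseudo-edge loss) and a pass over
           the sparse set weighted by ``beta``; the schedule moves
           supervision linearly from pseudo to true labels over the first
           ``e_thres`` rounds.

All stages share one Adam configuration, optional validation-Dice early
stopping with best-checkpoint restore, and full determinism under a fixed
seed.  "Rounds" are epochs over the training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from swsal.annotations import SparseConfig, dice, edge_from_mask, select_sparse_slices
from swsal.losses import (
    JointSchedule,
    area_loss,
    area_loss_grad,
    schedule_weights,
    weighted_edge_loss,
    weighted_edge_loss_grad,
)
from swsal.network import Adam, BackboneConfig, DualHeadNet
from swsal.phantom import Volume, tight_bbox
from swsal.pseudolabel import BBoxLabel, GrowParams, pseudo_labels_for_volume


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam defaults follow the common recipe:
    lr 5e-4, weight decay 1e-4, beta1 0.9, early stop patience 20)."""

    learning_rate: float = 5e-4
    weight_decay: float = 1e-4
    beta1: float = 0.9
    batch_size: int = 8
    max_rounds: int = 50
    early_stop_patience: int = 20
    refine_cycles: int = 3
    e_thres: int = 10
    seed: int = 0
    edge_weight_swap: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_rounds < 1:
            raise ValueError("batch_size and max_rounds must be positive")
        if self.refine_cycles < 0:
            raise ValueError("refine_cycles must be >= 0")


Sample = tuple[np.ndarray, np.ndarray]  # (image, binary mask)


def _make_optimizer(net: DualHeadNet, cfg: TrainConfig) -> Adam:
    return Adam(
        net,
        lr=cfg.learning_rate,
        beta1=cfg.beta1,
        weight_decay=cfg.weight_decay,
    )


def _sample_pass(
    net: DualHeadNet,
    image: np.ndarray,
    seg: np.ndarray,
    edge: np.ndarray | None,
    scale: float,
    swap: bool,
) -> float:
    """Forward + loss + scaled backward for one slice; returns the unscaled loss."""
    pred = net.forward(image)
    loss = area_loss(seg, pred.seg_prob)
    d_seg = area_loss_grad(seg, pred.seg_prob)
    d_edge = None
    if edge is not None:
        loss += weighted_edge_loss(edge, pred.edge_prob, swap)
        d_edge = weighted_edge_loss_grad(edge, pred.edge_prob, swap) * scale
    net.backward(d_seg * scale, d_edge)
    return loss


def _train_epoch(
    net: DualHeadNet,
    opt: Adam,
    samples: list[Sample],
    edges: list[np.ndarray] | None,
    cfg: TrainConfig,
    rng: np.random.Generator,
    weight: float = 1.0,
) -> float:
    """One shuffled epoch; gradients averaged per minibatch and scaled by ``weight``."""
    order = rng.permutation(len(samples))
    losses = []
    for start in range(0, len(order), cfg.batch_size):
        batch = order[start : start + cfg.batch_size]
        net.zero_grad()
        scale = weight / len(batch)
        for i in batch:
            img, seg = samples[i]
            edge = edges[i] if edges is not None else None
            losses.append(_sample_pass(net, img, seg, edge, scale, cfg.edge_weight_swap))
        opt.step()
    return float(np.mean(losses))


def evaluate_dice(net: DualHeadNet, samples: list[Sample], threshold: float = 0.5) -> float:
    """Mean Dice of binarized predictions against the samples' masks."""
    scores = [
        dice((net.forward(img).seg_prob >= threshold).astype(np.uint8), seg)
        for img, seg in samples
    ]
    return float(np.mean(scores))


class _BestTracker:
    """Early stopping on validation Dice with best-parameter restore.

    The incoming parameters count as round -1, so a stage that only hurts
    validation Dice restores the model it started from.
    """

    def __init__(self, net: DualHeadNet, patience: int, val_samples: list[Sample] | None = None) -> None:
        self.net = net
        self.patience = patience
        self.best_dice = evaluate_dice(net, val_samples) if val_samples else -np.inf
        self.best_params = net.get_params()
        self.stale = 0

    def update(self, val_dice: float) -> bool:
        """Record a round; returns True when training should stop."""
        if val_dice > self.best_dice:
            self.best_dice = val_dice
            self.best_params = self.net.get_params()
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience

    def restore(self) -> None:
        self.net.set_params(self.best_params)


def train_stage_sparse(
    net: DualHeadNet,
    samples: list[Sample],
    cfg: TrainConfig,
    val_samples: list[Sample] | None = None,
) -> tuple[DualHeadNet, pd.DataFrame]:
    """Stage A: train on fully annotated slices with area + edge loss."""
    if not samples:
        raise ValueError("sparse training set is empty")
    edges = [edge_from_mask(seg) for _, seg in samples]
    opt = _make_optimizer(net, cfg)
    rng = np.random.default_rng(cfg.seed)
    tracker = _BestTracker(net, cfg.early_stop_patience, val_samples)
    rows = []
    for rnd in range(cfg.max_rounds):
        loss = _train_epoch(net, opt, samples, edges, cfg, rng)
        val = evaluate_dice(net, val_samples) if val_samples else np.nan
        rows.append({"round": rnd, "loss": loss, "val_dice": val})
        if val_samples and tracker.update(val):
            break
    if val_samples:
        tracker.restore()
    return net, pd.DataFrame(rows)


def train_stage_bbox(
    net: DualHeadNet,
    samples: list[Sample],
    cfg: TrainConfig,
    val_samples: list[Sample] | None = None,
) -> tuple[DualHeadNet, list[np.ndarray], pd.DataFrame]:
    """Stage B: pseudo-label training with self-refinement, edge head frozen.

    ``samples`` pair each image with its region-grown pseudo-mask.  The net
    is first trained on the given pseudo-masks; then, ``refine_cycles``
    times, each pseudo-mask is replaced by the net's binarized prediction
    (threshold 0.5; a slice whose original pseudo-mask was empty stays
    empty) and the net is retrained.  Returns the net, the final
    pseudo-masks, and the per-round log.
    """
    if not samples or all(seg.sum() == 0 for _, seg in samples):
        raise ValueError("all pseudo-labels are empty; nothing to train on")
    originally_empty = [seg.sum() == 0 for _, seg in samples]
    labels = [seg.copy() for _, seg in samples]
    images = [img for img, _ in samples]
    net.edge_frozen = True
    try:
        opt = _make_optimizer(net, cfg)
        rng = np.random.default_rng(cfg.seed)
        rows = []

        def _fit(cycle: int) -> None:
            tracker = _BestTracker(net, cfg.early_stop_patience, val_samples)
            for rnd in range(cfg.max_rounds):
                cur = list(zip(images, labels))
                loss = _train_epoch(net, opt, cur, None, cfg, rng)
                val = evaluate_dice(net, val_samples) if val_samples else np.nan
                rows.append({"cycle": cycle, "round": rnd, "loss": loss, "val_dice": val})
                if val_samples and tracker.update(val):
                    break
            if val_samples:
                tracker.restore()

        def _replace_labels() -> None:
            for i, img in enumerate(images):
                if originally_empty[i]:
                    continue
                labels[i] = (net.forward(img).seg_prob >= 0.5).astype(np.uint8)

        _fit(0)
        for cycle in range(1, cfg.refine_cycles + 1):
            _replace_labels()
            _fit(cycle)
        if cfg.refine_cycles > 0:
            _replace_labels()  # the refined set is the final net's own prediction
    finally:
        net.edge_frozen = False
    return net, labels, pd.DataFrame(rows)


def refine_pseudo_labels(
    net: DualHeadNet, samples: list[Sample], threshold: float = 0.5
) -> list[np.ndarray]:
    """Replace each nonempty pseudo-mask with the net's binarized prediction."""
    out = []
    for img, seg in samples:
        if seg.sum() == 0:
            out.append(seg.copy())
        else:
            out.append((net.forward(img).seg_prob >= threshold).astype(np.uint8))
    return out


def train_joint(
    net: DualHeadNet,
    sparse_samples: list[Sample],
    pseudo_samples: list[Sample],
    cfg: TrainConfig,
    val_samples: list[Sample] | None = None,
) -> tuple[DualHeadNet, pd.DataFrame]:
    """Joint training: alpha-weighted pseudo pass + beta-weighted sparse pass per round.

    Pseudo-edge labels are derived from the (refined) pseudo-masks and do
    participate here, mirroring the full pseudo loss; after ``e_thres``
    rounds supervision is purely sparse-label.
    """
    if not sparse_samples or not pseudo_samples:
        raise ValueError("joint training needs both a sparse and a pseudo label set")
    if cfg.e_thres > cfg.max_rounds:
        import warnings

        warnings.warn(
            f"e_thres={cfg.e_thres} exceeds max_rounds={cfg.max_rounds}; "
            "the schedule never reaches pure sparse supervision",
            stacklevel=2,
        )
    sparse_edges = [edge_from_mask(seg) for _, seg in sparse_samples]
    pseudo_edges = [edge_from_mask(seg) for _, seg in pseudo_samples]
    opt = _make_optimizer(net, cfg)
    rng = np.random.default_rng(cfg.seed)
    tracker = _BestTracker(net, cfg.early_stop_patience, val_samples)
    rows = []
    for e_cur in range(cfg.max_rounds):
        sched = JointSchedule(e_thres=cfg.e_thres, e_total=cfg.max_rounds, e_cur=e_cur)
        alpha, beta = schedule_weights(sched)
        loss_sl = loss_gl = np.nan
        if alpha > 0:
            loss_sl = _train_epoch(net, opt, pseudo_samples, pseudo_edges, cfg, rng, weight=alpha)
        if beta > 0:
            loss_gl = _train_epoch(net, opt, sparse_samples, sparse_edges, cfg, rng, weight=beta)
        val = evaluate_dice(net, val_samples) if val_samples else np.nan
        rows.append(
            {"round": e_cur, "alpha": alpha, "beta": beta, "loss_sl": loss_sl, "loss_gl": loss_gl, "val_dice": val}
        )
        if val_samples and tracker.update(val):
            break
    if val_samples:
        tracker.restore()
    return net, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end pipeline helpers
# ---------------------------------------------------------------------------


def volume_samples(volumes: list[Volume], tissue: str, indices: dict[str, list[int]] | None = None) -> list[Sample]:
    """(image, gt mask) pairs for a tissue, optionally restricted per case."""
    out = []
    for v in volumes:
        idx = indices[v.case_id] if indices is not None else range(v.n_slices)
        for i in idx:
            out.append((v.slices[i], v.gt_masks[tissue][i]))
    return out


def boxes_from_gt(volume: Volume, tissue: str, indices: list[int]) -> list[BBoxLabel]:
    """Tight ground-truth boxes for the given slices (simulating box annotation)."""
    out = []
    for i in indices:
        box = tight_bbox(volume.gt_masks[tissue][i])
        if box is not None:
            out.append(BBoxLabel(tissue=tissue, box=box, slice_index=i, case_id=volume.case_id))
    return out


@dataclass
class PretrainResult:
    net: DualHeadNet
    sparse_indices: dict[str, list[int]]
    raw_pseudo: list[Sample]
    refined_pseudo: list[Sample]
    history: dict[str, pd.DataFrame]
    n_sparse_slices: int
    n_bbox_slices: int


def pretrain_swssl(
    train_volumes: list[Volume],
    val_volumes: list[Volume],
    tissue: str,
    cfg: TrainConfig,
    sparse_cfg: SparseConfig = SparseConfig(),
    backbone: BackboneConfig = BackboneConfig(),
    grow_params: GrowParams | None = None,
    cfg_bbox: TrainConfig | None = None,
    cfg_joint: TrainConfig | None = None,
) -> PretrainResult:
    """Full semi-weakly supervised pretraining for one tissue.

    Sparse slices carry true masks; every other slice carries only a
    (ground-truth-derived) bounding box, converted to a pseudo-mask by
    region growing.  Stages run in order: sparse -> bbox + self-refinement
    -> joint.
    """
    sparse_indices = {
        v.case_id: select_sparse_slices(v.n_slices, sparse_cfg) for v in train_volumes
    }
    sparse_samples = volume_samples(train_volumes, tissue, sparse_indices)
    val_samples = volume_samples(val_volumes, tissue) if val_volumes else None

    gp = grow_params or GrowParams.for_tissue(tissue)
    raw_pseudo: list[Sample] = []
    n_bbox = 0
    for v in train_volumes:
        bbox_idx = [i for i in range(v.n_slices) if i not in set(sparse_indices[v.case_id])]
        boxes = boxes_from_gt(v, tissue, bbox_idx)
        n_bbox += len(boxes)
        labels = pseudo_labels_for_volume(v, boxes, {tissue: gp})
        for i in bbox_idx:
            raw_pseudo.append((v.slices[i], labels.masks[tissue][i]))

    net = DualHeadNet(backbone, seed=cfg.seed)
    net, hist_a = train_stage_sparse(net, sparse_samples, cfg, val_samples)
    net, refined, hist_b = train_stage_bbox(net, raw_pseudo, cfg_bbox or cfg, val_samples)
    refined_pseudo = [(img, lab) for (img, _), lab in zip(raw_pseudo, refined)]
    net, hist_j = train_joint(net, sparse_samples, refined_pseudo, cfg_joint or cfg, val_samples)
    return PretrainResult(
        net=net,
        sparse_indices=sparse_indices,
        raw_pseudo=raw_pseudo,
        refined_pseudo=refined_pseudo,
        history={"sparse": hist_a, "bbox": hist_b, "joint": hist_j},
        n_sparse_slices=len(sparse_samples),
        n_bbox_slices=n_bbox,
    )
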