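"""Iterative annotation strategy based on active learning.

After pretraining, the model predicts every unannotated slice.  Because
adjacent slices of a volume are anatomically similar, a slice whose
prediction disagrees with its neighbours' is likely wrong; the per-slice
score is the mean Dice of the slice's mask against its neighbours' masks
(single neighbour at the stack ends).  Slices scoring below a threshold
``dice_ts`` are offered to a (here: simulated) doctor who corrects a
sparse subset of them — every (interval+1)-th — by replacing the
prediction with the true mask.  The model is retrained on all annotated
slices and the loop repeats with ``dice_ts`` rising linearly to 1 and the
correction interval falling to 0, so the final round sweeps up every
remaining slice.

Workload accounting converts box annotations into equivalent segmentation
effort: one full slice mask costs about 15 box annotations, so
``S_eq = S_s + floor(S_bb / 15)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from swsal.annotations import dice
from swsal.network import DualHeadNet
from swsal.phantom import Volume
from swsal.trainer import Sample, TrainConfig, evaluate_dice, train_stage_sparse, volume_samples

SEG_LABELED = "seg_labeled"
BBOX_ONLY = "bbox_only"
PENDING = "pending_correction"
CORRECTED = "corrected"

_RANK = {BBOX_ONLY: 0, PENDING: 1, CORRECTED: 2, SEG_LABELED: 2}


@dataclass
class AnnotationState:
    """Per-case, per-slice annotation status plus workload counters.

    ``ss`` counts slices with full segmentation labels (initial sparse plus
    corrected); ``sbb`` counts slices annotated only with a bounding box.
    Statuses only ever move toward corrected/seg_labeled.
    """

    statuses: dict[str, list[str]]
    ss: int = 0
    sbb: int = 0
    round_index: int = 0

    @classmethod
    def from_sparse(cls, volumes: list[Volume], sparse_indices: dict[str, list[int]]) -> "AnnotationState":
        statuses = {}
        ss = sbb = 0
        for v in volumes:
            labeled = set(sparse_indices.get(v.case_id, []))
            statuses[v.case_id] = [
                SEG_LABELED if i in labeled else BBOX_ONLY for i in range(v.n_slices)
            ]
            ss += len(labeled)
            sbb += v.n_slices - len(labeled)
        return cls(statuses=statuses, ss=ss, sbb=sbb)

    def set_status(self, case_id: str, slice_index: int, status: str) -> None:
        cur = self.statuses[case_id][slice_index]
        if _RANK[status] < _RANK[cur]:
            raise ValueError(f"status may not regress: {cur} -> {status}")
        if status == CORRECTED and cur in (BBOX_ONLY, PENDING):
            self.ss += 1
        self.statuses[case_id][slice_index] = status

    def labeled_indices(self, case_id: str) -> list[int]:
        return [i for i, s in enumerate(self.statuses[case_id]) if s in (SEG_LABELED, CORRECTED)]

    def unlabeled_indices(self, case_id: str) -> list[int]:
        return [i for i, s in enumerate(self.statuses[case_id]) if s not in (SEG_LABELED, CORRECTED)]

    @property
    def all_labeled(self) -> bool:
        return all(not self.unlabeled_indices(c) for c in self.statuses)


@dataclass(frozen=True)
class IasalSchedule:
    """Round schedules for the selection threshold and the correction interval.

    ``dice_ts`` rises linearly from ``dice_ts_start`` to exactly 1 at the
    final round; the correction interval steps down by 1 per round from
    ``correction_interval_start`` and must reach 0 by the final round
    (otherwise the loop could never annotate everything).
    """

    dice_ts_start: float = 0.7
    n_rounds: int = 5
    correction_interval_start: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.dice_ts_start <= 1:
            raise ValueError("dice_ts_start must be in [0, 1]")
        if self.n_rounds < 1 or self.correction_interval_start < 0:
            raise ValueError("n_rounds must be >= 1 and interval start >= 0")
        if self.correction_interval_start > self.n_rounds - 1:
            raise ValueError(
                "non-terminating schedule: the correction interval "
                f"(start {self.correction_interval_start}) cannot reach 0 within "
                f"{self.n_rounds} rounds"
            )

    def dice_ts(self, round_index: int) -> float:
        if self.n_rounds == 1:
            return 1.0
        frac = min(round_index / (self.n_rounds - 1), 1.0)
        return self.dice_ts_start + (1.0 - self.dice_ts_start) * frac

    def interval(self, round_index: int) -> int:
        return max(self.correction_interval_start - round_index, 0)


def adjacent_dice_scores(preds: list[np.ndarray]) -> list[float]:
    """Per-slice adjacent-consistency scores for one case.

    Interior slices score the mean of the Dice with both neighbours; the
    first and last slice use their single neighbour.  A single-slice case
    scores 0 (no neighbour to agree with — always selected).
    """
    n = len(preds)
    if n == 0:
        raise ValueError("empty prediction stack")
    if n == 1:
        return [0.0]
    pair = [dice(preds[i], preds[i + 1]) for i in range(n - 1)]
    scores = [pair[0]]
    for i in range(1, n - 1):
        scores.append((pair[i - 1] + pair[i]) / 2.0)
    scores.append(pair[-1])
    return scores


def select_slices(scores: list[float], dice_ts: float) -> list[int]:
    """Indices whose score falls strictly below the threshold."""
    return [i for i, s in enumerate(scores) if s < dice_ts]


def oracle_correct(
    selected: list[int],
    gt_masks: np.ndarray,
    interval: int,
    state: AnnotationState,
    case_id: str,
    masks: np.ndarray,
) -> list[int]:
    """Simulated doctor: sparsely correct the selected slices.

    From the sorted selection, every (interval+1)-th slice is kept; kept
    slices get their prediction replaced by the ground-truth mask and are
    marked corrected (updating the Ss counter).  Returns the kept indices.
    """
    if interval < 0:
        raise ValueError("interval must be >= 0")
    kept = sorted(selected)[:: interval + 1]
    for i in kept:
        masks[i] = gt_masks[i]
        state.set_status(case_id, i, CORRECTED)
    return kept


def equivalent_workload(ss: int, sbb: int) -> int:
    """Equivalent segmentation annotation workload ``S_s + floor(S_bb / 15)``."""
    if ss < 0 or sbb < 0:
        raise ValueError("annotation counts must be nonnegative")
    return ss + sbb // 15


def equivalent_workload_exact(ss: int, sbb: int) -> float:
    """Exact (unrounded) equivalent workload ``S_s + S_bb / 15``."""
    if ss < 0 or sbb < 0:
        raise ValueError("annotation counts must be nonnegative")
    return ss + sbb / 15.0


def run_iasal(
    net: DualHeadNet,
    volumes: list[Volume],
    tissue: str,
    state: AnnotationState,
    schedule: IasalSchedule,
    cfg: TrainConfig,
    test_volumes: list[Volume] | None = None,
    strategy: str = "al",
    budget_per_round: list[int] | None = None,
    retrain_rounds: int | None = None,
    warm_start: bool = True,
) -> tuple[DualHeadNet, AnnotationState, pd.DataFrame]:
    """The iterative annotation loop for one tissue.

    Per round: predict unannotated slices, score adjacent consistency,
    select, sparsely oracle-correct, retrain on all annotated slices
    (warm-start), and log metrics.  ``strategy`` is ``"al"`` (score-based
    selection) or ``"sequential"`` (the dense baseline: slices in stack
    order).  ``budget_per_round`` optionally caps the number of corrected
    slices per round (used for equal-budget comparisons); with a budget the
    AL strategy corrects the lowest-scoring slices first and the interval
    rule is bypassed.  At the final round the threshold reaches 1 and every
    remaining slice is selected, so the loop always terminates with all
    slices annotated.
    """
    if strategy not in ("al", "sequential"):
        raise ValueError(f"unknown strategy {strategy!r}")
    # working copy of per-case masks: ground truth where labeled, predictions elsewhere
    masks: dict[str, np.ndarray] = {
        v.case_id: v.gt_masks[tissue].copy() for v in volumes
    }
    test_samples = volume_samples(test_volumes, tissue) if test_volumes else None
    rows = []
    r = 0
    while r < schedule.n_rounds and not state.all_labeled:
        dice_ts = schedule.dice_ts(r)
        interval = schedule.interval(r)
        n_selected = n_corrected = 0
        for v in volumes:
            unlabeled = state.unlabeled_indices(v.case_id)
            if not unlabeled:
                continue
            for i in unlabeled:
                masks[v.case_id][i] = (net.forward(v.slices[i]).seg_prob >= 0.5).astype(np.uint8)
            scores = adjacent_dice_scores(list(masks[v.case_id]))
            if strategy == "sequential":
                selected = list(unlabeled)
            elif dice_ts >= 1.0:
                selected = list(unlabeled)  # final sweep: annotate everything left
            else:
                chosen = set(select_slices(scores, dice_ts))
                selected = [i for i in unlabeled if i in chosen]
            n_selected += len(selected)
            if budget_per_round is not None:
                # equal-budget mode: both strategies correct exactly `budget`
                # slices per case per round (AL the lowest-scoring, the
                # baseline the first in stack order); the interval rule and,
                # for AL, the threshold are bypassed
                budget = budget_per_round[min(r, len(budget_per_round) - 1)]
                if strategy == "al":
                    selected = sorted(unlabeled, key=lambda i: scores[i])[:budget]
                else:
                    selected = list(unlabeled)[:budget]
                kept = oracle_correct(
                    selected, v.gt_masks[tissue], 0, state, v.case_id, masks[v.case_id]
                )
            else:
                kept = oracle_correct(
                    selected, v.gt_masks[tissue], interval, state, v.case_id, masks[v.case_id]
                )
            n_corrected += len(kept)
        # retrain on all annotated slices (true labels only), warm start
        labeled = {v.case_id: state.labeled_indices(v.case_id) for v in volumes}
        train_samples: list[Sample] = volume_samples(volumes, tissue, labeled)
        retrain_cfg = cfg if retrain_rounds is None else _with_rounds(cfg, retrain_rounds)
        if not warm_start:
            net = DualHeadNet(net.config, seed=cfg.seed, dtype=net.dtype)
        net, _ = train_stage_sparse(net, train_samples, retrain_cfg, None)
        test_dice = evaluate_dice(net, test_samples) if test_samples else np.nan
        seq = equivalent_workload(state.ss, state.sbb)
        rows.append(
            {
                "round": r,
                "dice_ts": dice_ts,
                "interval": interval,
                "n_selected": n_selected,
                "n_corrected": n_corrected,
                "ss": state.ss,
                "sbb": state.sbb,
                "seq": seq,
                "test_dice": test_dice,
            }
        )
        state.round_index = r + 1
        r += 1
    return net, state, pd.DataFrame(rows)


def _with_rounds(cfg: TrainConfig, rounds: int) -> TrainConfig:
    return replace(cfg, max_rounds=rounds)
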