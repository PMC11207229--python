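"""Training losses and the joint-training weight schedule.

The segmentation ("area") loss is mean binary cross-entropy plus a smoothed
Dice loss; the edge loss is a weighted binary cross-entropy whose weights
are derived from the edge-pixel fraction of the label.  During joint
training the pseudo-label and true-label losses are mixed with weights
``alpha = max((e_thres - e_cur)/e_thres, 0)`` and
``beta = min(e_cur/e_thres, 1)``, so supervision shifts linearly from the
abundant pseudo-labels to the few true sparse labels over the first
``e_thres`` rounds and stays purely true-label supervised afterwards.

Numerical conventions
---------------------
Summed losses are normalized by the pixel count so the alpha/beta balance
is independent of image size.  Cross-entropies use the standard negated
(minimizable) form.  Probabilities are clipped to [1e-7, 1 - 1e-7] before
any logarithm; the Dice loss is smoothed with eps = 1e-6 in numerator and
denominator, which makes the empty-label/empty-prediction case evaluate to
exactly 0.

The edge-loss weights assign ``w0 = |E| / (W H)`` to the edge-positive term
and ``w1 = 1 - w0`` to the background term.  Because edges are rare, this
down-weights the positive class — the opposite of usual class balancing —
but it is implemented this way deliberately; ``edge_weight_swap=True``
exchanges the two weights for conventional balancing.

Each loss has a companion ``*_grad`` returning the exact derivative with
respect to the predicted probability map, used by the trainer's
backpropagation and verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LOG_EPS = 1e-7
DICE_EPS = 1e-6


def _check_pair(label: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (label, raw prediction, log-clipped prediction)."""
    lab = np.asarray(label, dtype=np.float64)
    prd = np.asarray(pred, dtype=np.float64)
    if lab.shape != prd.shape:
        raise ValueError(f"shape mismatch: label {lab.shape} vs prediction {prd.shape}")
    return lab, prd, np.clip(prd, LOG_EPS, 1 - LOG_EPS)


def area_loss(label: np.ndarray, pred_seg: np.ndarray) -> float:
    """Mean BCE + smoothed Dice loss between a binary label and a probability map.

    The logarithms see the clipped prediction; the Dice term uses the raw
    prediction so an all-empty label with an all-zero prediction scores 0.
    """
    g, q, qc = _check_pair(label, pred_seg)
    bce = -np.mean(g * np.log(qc) + (1 - g) * np.log(1 - qc))
    inter = np.sum(g * q)
    denom = np.sum(g) + np.sum(q)
    dice_loss = 1.0 - (2.0 * inter + DICE_EPS) / (denom + DICE_EPS)
    return float(bce + dice_loss)


def area_loss_grad(label: np.ndarray, pred_seg: np.ndarray) -> np.ndarray:
    """d(area_loss)/d(pred_seg), elementwise."""
    g, q, qc = _check_pair(label, pred_seg)
    n = q.size
    d_bce = -(g / qc - (1 - g) / (1 - qc)) / n
    inter = np.sum(g * q)
    denom = np.sum(g) + np.sum(q)
    num = 2.0 * inter + DICE_EPS
    den = denom + DICE_EPS
    d_dice = -(2.0 * g * den - num) / den**2
    return d_bce + d_dice


def _edge_weights(e: np.ndarray, swap: bool) -> tuple[float, float]:
    w0 = float(np.sum(e)) / e.size
    w1 = 1.0 - w0
    return (w1, w0) if swap else (w0, w1)


def weighted_edge_loss(edge_label: np.ndarray, pred_edge: np.ndarray, edge_weight_swap: bool = False) -> float:
    """Weighted BCE between a binary edge label and an edge probability map.

    The positive (edge) term carries weight ``w0 = |E|/(W H)`` and the
    background term ``w1 = 1 - w0``; ``edge_weight_swap`` exchanges them.
    The sum is normalized by the pixel count.
    """
    e, _, s = _check_pair(edge_label, pred_edge)
    w0, w1 = _edge_weights(e, edge_weight_swap)
    loss = -np.sum(w0 * e * np.log(s) + w1 * (1 - e) * np.log(1 - s)) / e.size
    return float(loss)


def weighted_edge_loss_grad(edge_label: np.ndarray, pred_edge: np.ndarray, edge_weight_swap: bool = False) -> np.ndarray:
    """d(weighted_edge_loss)/d(pred_edge), elementwise (weights held fixed)."""
    e, _, s = _check_pair(edge_label, pred_edge)
    w0, w1 = _edge_weights(e, edge_weight_swap)
    return -(w0 * e / s - w1 * (1 - e) / (1 - s)) / e.size


@dataclass
class JointSchedule:
    """State of the pseudo-to-true supervision schedule.

    ``e_thres`` is the round at which supervision becomes purely
    true-label; ``e_cur`` the current round; ``e_total`` the round budget.
    """

    e_thres: int
    e_total: int
    e_cur: int = 0

    def __post_init__(self) -> None:
        if self.e_thres < 1:
            raise ValueError(f"e_thres must be >= 1, got {self.e_thres}")
        if self.e_total < 1:
            raise ValueError(f"e_total must be >= 1, got {self.e_total}")
        if self.e_cur < 0:
            raise ValueError(f"e_cur must be >= 0, got {self.e_cur}")


def schedule_weights(s: JointSchedule) -> tuple[float, float]:
    """(alpha, beta): weights of the pseudo-label and true-label losses."""
    alpha = max((s.e_thres - s.e_cur) / s.e_thres, 0.0)
    beta = min(s.e_cur / s.e_thres, 1.0)
    return alpha, beta


def joint_loss(
    loss_pl: float,
    loss_p_edge: float,
    loss_area: float,
    loss_edge: float,
    s: JointSchedule,
) -> float:
    """alpha * (pseudo area + pseudo edge) + beta * (true area + true edge)."""
    alpha, beta = schedule_weights(s)
    return alpha * (loss_pl + loss_p_edge) + beta * (loss_area + loss_edge)
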