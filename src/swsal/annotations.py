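"""Sparse-slice selection, edge labels derived from masks, and the Dice metric.

A "sparse" annotation scheme provides a full per-pixel mask only on every
(s_int + 1)-th slice of a volume; the slices in between carry no mask.
Edge labels are derived from masks by an 8-neighbourhood rule: a foreground
pixel is an edge pixel iff at least one of its 8 neighbours is background
(pixels outside the image count as background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


def _as_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2D, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (values in {{0,1}}), found {vals[:10]}")
    return arr.astype(bool)


@dataclass(frozen=True)
class SparseConfig:
    """Sparse annotation layout.

    Parameters
    ----------
    s_int
        Number of unannotated slices between consecutive annotated slices.
        ``s_int = 0`` means every slice is annotated (dense annotation).
    """

    s_int: int = 3

    def __post_init__(self) -> None:
        if self.s_int < 0:
            raise ValueError(f"s_int must be >= 0, got {self.s_int}")


def select_sparse_slices(n_slices: int, cfg: SparseConfig) -> list[int]:
    """Indices of the annotated slices: 0, s_int+1, 2(s_int+1), ... < n_slices."""
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    return list(range(0, n_slices, cfg.s_int + 1))


def edge_from_mask(mask: np.ndarray) -> np.ndarray:
    """Edge label of a binary mask under the 8-neighbour rule.

    A pixel is an edge pixel iff it is foreground and at least one of its 8
    neighbours (out-of-image neighbours count as background) is background.
    The edge set is always a subset of the mask foreground.
    """
    m = _as_binary(mask)
    # erosion with border_value=0 removes exactly the pixels with a background
    # 8-neighbour (including the virtual background outside the image)
    interior = ndimage.binary_erosion(m, structure=np.ones((3, 3), bool), border_value=0)
    return (m & ~interior).astype(np.uint8)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) between two binary masks.

    Two empty masks score 1.0 (they agree that nothing is present), which
    keeps the metric defined on slices without tissue.
    """
    ma = _as_binary(a, "a")
    mb = _as_binary(b, "b")
    if ma.shape != mb.shape:
        raise ValueError(f"shape mismatch: {ma.shape} vs {mb.shape}")
    sa = int(ma.sum())
    sb = int(mb.sum())
    if sa + sb == 0:
        return 1.0
    inter = int((ma & mb).sum())
    return 2.0 * inter / (sa + sb)
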