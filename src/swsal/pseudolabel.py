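"""Pseudo-segmentation labels from bounding boxes by seeded region growing.

A bounding box localizes a tissue on a slice but gives no per-pixel mask.
Region growing converts it into a pseudo-mask: a seed pixel is chosen by a
tissue-specific rule, then an 8-connected region is grown around the seed,
restricted to the box, admitting pixels whose intensity stays close to the
running region mean.  The intensity tolerance is escalated until the grown
area reaches a tissue-specific fraction of the box area (0.8 for the
compact bone tissue, 0.6 for the thin cartilage tissue), which guarantees
termination on any image.

Seed rules
----------
bone
    The integer centre of the box — compact convex-ish tissue, so the
    centre is reliably interior.
cartilage
    Canny edges are detected inside the box; for each column the
    longitudinal (vertical) extent between the topmost and bottommost edge
    response is measured, and the seed is the vertical midpoint of the
    column with maximal extent — the thickest part of the band, which for a
    thin elongated tissue is the safest interior point.  If Canny finds no
    edges the box centre is used and a warning emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import feature

from swsal.phantom import BONE, CARTILAGE, Box, Volume


@dataclass(frozen=True)
class BBoxLabel:
    """An axis-aligned box label for one tissue on one slice.

    ``box`` is (row_min, col_min, row_max, col_max), inclusive, 0-based.
    """

    tissue: str
    box: Box
    slice_index: int = 0
    case_id: str = ""

    def __post_init__(self) -> None:
        rmin, cmin, rmax, cmax = self.box
        if rmin > rmax or cmin > cmax or rmin < 0 or cmin < 0:
            raise ValueError(f"invalid box {self.box}")

    def validate_within(self, shape: tuple[int, int]) -> None:
        rmin, cmin, rmax, cmax = self.box
        if rmax >= shape[0] or cmax >= shape[1]:
            raise ValueError(f"box {self.box} outside image of shape {shape}")

    @property
    def area(self) -> int:
        rmin, cmin, rmax, cmax = self.box
        return (rmax - rmin + 1) * (cmax - cmin + 1)


@dataclass(frozen=True)
class GrowParams:
    """Region-growing parameters for one tissue kind.

    ``area_ratio_stop`` is the stop rule: growth ends once the region area
    reaches ``area_ratio_stop`` times the box area (0.8 for bone, 0.6 for
    cartilage).  ``intensity_tolerance_init`` is the initial admissible
    deviation from the running region mean; it is raised by
    ``tolerance_step`` each time growth stalls below the area target.
    """

    tissue_kind: str = BONE
    area_ratio_stop: float = 0.8
    intensity_tolerance_init: float = 0.05
    tolerance_step: float = 0.05
    max_iterations: int = 50
    canny_sigma: float = 1.0
    canny_low_pct: float = 50.0
    canny_high_pct: float = 90.0

    def __post_init__(self) -> None:
        if not 0 < self.area_ratio_stop <= 1:
            raise ValueError(f"area_ratio_stop must be in (0, 1], got {self.area_ratio_stop}")

    @classmethod
    def for_tissue(cls, tissue: str) -> "GrowParams":
        if tissue == CARTILAGE:
            return cls(tissue_kind=CARTILAGE, area_ratio_stop=0.6)
        return cls(tissue_kind=BONE, area_ratio_stop=0.8)


def select_seed(image: np.ndarray, bbox: BBoxLabel, kind: str, params: GrowParams | None = None) -> tuple[int, int]:
    """Seed pixel for region growing, by the tissue-specific rule."""
    img = np.asarray(image, dtype=np.float64)
    bbox.validate_within(img.shape)
    rmin, cmin, rmax, cmax = bbox.box
    center = ((rmin + rmax) // 2, (cmin + cmax) // 2)
    if kind == BONE:
        return center
    if kind != CARTILAGE:
        raise ValueError(f"unknown tissue kind {kind!r}")
    params = params or GrowParams.for_tissue(CARTILAGE)
    patch = img[rmin : rmax + 1, cmin : cmax + 1]
    lo = np.percentile(patch, params.canny_low_pct)
    hi = np.percentile(patch, params.canny_high_pct)
    edges = feature.canny(patch, sigma=params.canny_sigma, low_threshold=lo, high_threshold=hi)
    if not edges.any():
        warnings.warn("no Canny edges inside cartilage box; falling back to box centre", stacklevel=2)
        return center
    best_col, best_extent, best_mid = None, -1, None
    for c in range(edges.shape[1]):
        rows = np.flatnonzero(edges[:, c])
        if rows.size < 2:
            continue
        extent = int(rows[-1] - rows[0])
        if extent > best_extent:
            best_col, best_extent = c, extent
            best_mid = int((rows[0] + rows[-1]) // 2)
    if best_col is None:
        warnings.warn("no column with two edge responses; falling back to box centre", stacklevel=2)
        return center
    return rmin + best_mid, cmin + best_col


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _grow_once(patch: np.ndarray, seed: tuple[int, int], tol: float) -> np.ndarray:
    """One 8-connected growth pass at a fixed tolerance (running-mean criterion)."""
    h, w = patch.shape
    region = np.zeros((h, w), dtype=bool)
    region[seed] = True
    total = float(patch[seed])
    count = 1
    frontier = [seed]
    while frontier:
        nxt = []
        mean = total / count
        for r, c in frontier:
            for dr, dc in _NEIGHBORS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not region[rr, cc]:
                    if abs(patch[rr, cc] - mean) <= tol:
                        region[rr, cc] = True
                        total += float(patch[rr, cc])
                        count += 1
                        nxt.append((rr, cc))
        frontier = nxt
    return region


def region_grow(image: np.ndarray, seed: tuple[int, int], bbox: BBoxLabel, params: GrowParams) -> tuple[np.ndarray, bool]:
    """Grow a pseudo-mask around ``seed`` inside ``bbox``.

    Returns ``(mask, confident)`` where ``mask`` is a full-size binary mask
    whose foreground is a single 8-connected region containing the seed and
    never leaves the box, and ``confident`` is False when the area target
    could not be reached within ``max_iterations`` tolerance escalations.
    """
    img = np.asarray(image, dtype=np.float64)
    bbox.validate_within(img.shape)
    rmin, cmin, rmax, cmax = bbox.box
    if not (rmin <= seed[0] <= rmax and cmin <= seed[1] <= cmax):
        raise ValueError(f"seed {seed} outside box {bbox.box}")
    patch = img[rmin : rmax + 1, cmin : cmax + 1]
    local_seed = (seed[0] - rmin, seed[1] - cmin)
    target = params.area_ratio_stop * bbox.area
    tol = params.intensity_tolerance_init
    best = None
    confident = False
    for _ in range(params.max_iterations):
        region = _grow_once(patch, local_seed, tol)
        if best is None or region.sum() > best.sum():
            best = region
        if region.sum() >= target:
            confident = True
            break
        tol += params.tolerance_step
    mask = np.zeros(img.shape, dtype=np.uint8)
    mask[rmin : rmax + 1, cmin : cmax + 1] = best.astype(np.uint8)
    return mask, confident


@dataclass
class PseudoLabels:
    """Per-slice, per-tissue pseudo-masks plus a confidence report.

    ``masks[tissue]`` is (n_slices, H, W) uint8; ``confidence[(tissue, i)]``
    is False when growth on that slice stalled below its area target or
    failed outright.
    """

    masks: dict[str, np.ndarray]
    confidence: dict[tuple[str, int], bool]


def pseudo_labels_for_volume(
    volume: Volume,
    boxes: list[BBoxLabel],
    params: dict[str, GrowParams] | None = None,
) -> PseudoLabels:
    """Pseudo-masks for every slice and tissue of a volume.

    Slices without a box for a tissue get an empty mask.  Per-slice growth
    failures are flagged in the confidence report but never abort the volume.
    """
    params = params or {t: GrowParams.for_tissue(t) for t in volume.tissue_names}
    h, w = volume.shape
    masks: dict[str, np.ndarray] = {
        t: np.zeros((volume.n_slices, h, w), dtype=np.uint8) for t in volume.tissue_names
    }
    confidence: dict[tuple[str, int], bool] = {}
    for b in boxes:
        if b.case_id and b.case_id != volume.case_id:
            raise ValueError(f"box for case {b.case_id!r} applied to {volume.case_id!r}")
        img = volume.slices[b.slice_index]
        p = params[b.tissue]
        try:
            seed = select_seed(img, b, b.tissue, p)
            mask, ok = region_grow(img, seed, b, p)
        except ValueError:
            confidence[(b.tissue, b.slice_index)] = False
            continue
        masks[b.tissue][b.slice_index] = mask
        confidence[(b.tissue, b.slice_index)] = ok
    return PseudoLabels(masks=masks, confidence=confidence)
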