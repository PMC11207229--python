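"""Synthetic multi-slice phantom volumes with ground-truth masks and boxes.

Each case is an ordered stack of 2D grayscale slices that emulates the
statistical structure of a sagittal knee MRI stack: adjacent slices are
anatomically similar, each slice contains one compact bright "bone"-like
tissue and one thin elongated "cartilage"-like tissue hugging the bone
boundary, and intensities are 0-1 standardized per case.

Geometry
--------
The bone is a smoothly perturbed filled ellipse: in polar coordinates about
a per-slice centre, its radius is ``r_e(theta) * (1 + sum_k a_k cos(k theta
+ phi_k))`` with a small number of low-order harmonics.  The cartilage is a
crescent band of spatially varying thickness (about 2-6 px) lying just
outside the bone boundary over an angular arc near the top of the bone, so
that image columns cross it once and its thickest part has a well-defined
column.  Between adjacent slices all shape parameters follow a smooth
random walk whose step size is ``inter_slice_drift``; drift 0 freezes the
anatomy so every slice of a case has identical ground truth.

Coordinates are row-major and 0-based; boxes are (row_min, col_min,
row_max, col_max), inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from swsal.annotations import _as_binary

Box = tuple[int, int, int, int]

BONE = "bone"
CARTILAGE = "cartilage"


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for a batch of phantom cases.

    Parameters
    ----------
    n_cases
        Number of independent cases (volumes) to generate.
    slices_per_case
        Slices in each stack.
    height, width
        Slice size in pixels.
    inter_slice_drift
        Standard-deviation scale of the per-slice random walk of the shape
        parameters, in pixels for positions/radii.  0 means identical
        ground truth on every slice of a case.
    noise_sigma
        Standard deviation of additive Gaussian intensity noise (on the
        pre-standardization intensity scale, where tissue contrasts are
        about 0.3-0.6).
    bias_amplitude
        Peak amplitude of a smooth multiplicative-style intensity
        inhomogeneity (a slowly varying ramp plus a broad blob), emulating
        the coil bias fields of real MRI; drifts slowly across slices.
    rng_seed
        Seed; the same seed yields bit-identical volumes and masks.
    """

    n_cases: int = 5
    slices_per_case: int = 32
    height: int = 96
    width: int = 96
    inter_slice_drift: float = 0.5
    noise_sigma: float = 0.03
    bias_amplitude: float = 0.12
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.slices_per_case < 1:
            raise ValueError("n_cases and slices_per_case must be positive")
        if self.height < 16 or self.width < 16:
            raise ValueError(f"height/width must be >= 16, got {self.height}x{self.width}")
        if self.inter_slice_drift < 0 or self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise ValueError("inter_slice_drift, noise_sigma and bias_amplitude must be nonnegative")


@dataclass
class Volume:
    """One case: an ordered slice stack with per-slice, per-tissue ground truth.

    ``gt_masks[tissue]`` is a (n_slices, H, W) uint8 array aligned one-to-one
    with ``slices``; ``gt_boxes[tissue][i]`` is the tight box of the mask on
    slice ``i`` or ``None`` when that mask is empty.
    """

    case_id: str
    slices: np.ndarray  # (S, H, W) float in [0, 1]
    gt_masks: dict[str, np.ndarray]
    gt_boxes: dict[str, list[Box | None]]
    tissue_names: list[str] = field(default_factory=lambda: [BONE, CARTILAGE])

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices.shape[1], self.slices.shape[2]


def tight_bbox(mask: np.ndarray) -> Box | None:
    """Minimal axis-aligned box containing all foreground pixels, or None."""
    m = _as_binary(mask)
    rows = np.any(m, axis=1)
    if not rows.any():
        return None
    cols = np.any(m, axis=0)
    rmin, rmax = np.flatnonzero(rows)[[0, -1]]
    cmin, cmax = np.flatnonzero(cols)[[0, -1]]
    return int(rmin), int(cmin), int(rmax), int(cmax)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


class _CaseShape:
    """Shape parameters of one case, advanced slice-to-slice by a random walk."""

    N_HARMONICS = 3

    def __init__(self, cfg: PhantomConfig, rng: np.random.Generator) -> None:
        h, w = cfg.height, cfg.width
        scale = min(h, w)
        self.cy = h / 2 + rng.uniform(-0.04, 0.04) * h
        self.cx = w / 2 + rng.uniform(-0.04, 0.04) * w
        self.ry = scale * rng.uniform(0.20, 0.26)
        self.rx = scale * rng.uniform(0.20, 0.26)
        self.amp = rng.uniform(0.0, 0.06, self.N_HARMONICS)
        self.phase = rng.uniform(0, 2 * np.pi, self.N_HARMONICS)
        # cartilage arc near the top of the bone (rows decrease upward)
        self.theta_c = -np.pi / 2 + rng.uniform(-0.25, 0.25)
        self.arc_half = rng.uniform(0.55, 0.80)
        self.t_max = rng.uniform(4.5, 6.0)
        self.t_min = 2.0
        # smooth intensity inhomogeneity: linear ramp direction + broad blob
        ang = rng.uniform(0, 2 * np.pi)
        self.bias_dir = np.array([np.sin(ang), np.cos(ang)])
        self.blob_cy = rng.uniform(0.2, 0.8) * h
        self.blob_cx = rng.uniform(0.2, 0.8) * w
        self.blob_sigma = rng.uniform(0.4, 0.7) * scale

    def drift(self, d: float, rng: np.random.Generator) -> None:
        self.cy += d * rng.normal(0, 1.0)
        self.cx += d * rng.normal(0, 1.0)
        self.ry *= 1 + d * rng.normal(0, 0.01)
        self.rx *= 1 + d * rng.normal(0, 0.01)
        self.amp = np.clip(self.amp + d * rng.normal(0, 0.01, self.N_HARMONICS), 0, 0.12)
        self.phase += d * rng.normal(0, 0.02, self.N_HARMONICS)
        self.theta_c += d * rng.normal(0, 0.02)
        self.t_max = float(np.clip(self.t_max + d * rng.normal(0, 0.15), 3.0, 6.0))
        self.blob_cy += d * rng.normal(0, 1.0)
        self.blob_cx += d * rng.normal(0, 1.0)

    def masks(self, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.mgrid[0:h, 0:w]
        dy = rows - self.cy
        dx = cols - self.cx
        theta = np.arctan2(dy, dx)
        dist = np.hypot(dy, dx)
        # elliptical base radius as a function of angle
        r_e = (self.rx * self.ry) / np.sqrt(
            (self.ry * np.cos(theta)) ** 2 + (self.rx * np.sin(theta)) ** 2
        )
        mod = np.ones_like(theta)
        for k in range(self.N_HARMONICS):
            mod += self.amp[k] * np.cos((k + 1) * theta + self.phase[k])
        r_b = r_e * mod
        bone = dist <= r_b
        rel = _wrap_angle(theta - self.theta_c)
        in_arc = np.abs(rel) <= self.arc_half
        thick = self.t_min + (self.t_max - self.t_min) * np.cos(
            np.pi / 2 * rel / self.arc_half
        ) ** 2
        cart = in_arc & (dist > r_b) & (dist <= r_b + thick)
        return bone.astype(np.uint8), cart.astype(np.uint8)

    def bias_field(self, h: int, w: int, amplitude: float) -> np.ndarray:
        rows, cols = np.mgrid[0:h, 0:w]
        ramp = (
            self.bias_dir[0] * (rows / h - 0.5) + self.bias_dir[1] * (cols / w - 0.5)
        )
        blob = np.exp(
            -((rows - self.blob_cy) ** 2 + (cols - self.blob_cx) ** 2)
            / (2 * self.blob_sigma**2)
        )
        return amplitude * (ramp + blob - 0.5)


def _standardize_case(stack: np.ndarray) -> np.ndarray:
    lo = stack.min()
    hi = stack.max()
    if hi <= lo:
        return np.zeros_like(stack)
    return (stack - lo) / (hi - lo)


def generate_phantom(config: PhantomConfig) -> list[Volume]:
    """Generate ``config.n_cases`` phantom volumes with ground truth.

    The bone interior is brighter than the background; the cartilage takes an
    intermediate intensity.  Tissue boundaries are softened by a small
    Gaussian blur before noise so edges are not artificially crisp.
    Intensities are standardized to exactly [0, 1] per case.
    """
    volumes: list[Volume] = []
    for c in range(config.n_cases):
        rng = np.random.default_rng([config.rng_seed, c])
        shape = _CaseShape(config, rng)
        h, w = config.height, config.width
        imgs = np.empty((config.slices_per_case, h, w), dtype=np.float64)
        bone_masks = np.empty((config.slices_per_case, h, w), dtype=np.uint8)
        cart_masks = np.empty_like(bone_masks)
        for s in range(config.slices_per_case):
            if s > 0:
                shape.drift(config.inter_slice_drift, rng)
            bone, cart = shape.masks(h, w)
            img = 0.25 + 0.60 * bone + 0.30 * cart.astype(np.float64)
            img += shape.bias_field(h, w, config.bias_amplitude)
            img = ndimage.gaussian_filter(img, sigma=1.0)
            img += rng.normal(0, config.noise_sigma, (h, w))
            imgs[s] = img
            bone_masks[s] = bone
            cart_masks[s] = cart
        imgs = _standardize_case(imgs)
        masks = {BONE: bone_masks, CARTILAGE: cart_masks}
        boxes = {
            t: [tight_bbox(masks[t][s]) for s in range(config.slices_per_case)]
            for t in (BONE, CARTILAGE)
        }
        volumes.append(
            Volume(
                case_id=f"case{c:03d}",
                slices=imgs,
                gt_masks=masks,
                gt_boxes=boxes,
            )
        )
    return volumes
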