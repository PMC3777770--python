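"""Brain extraction, edge-preserving denoising, and intensity standardization.

The standardization follows the decile-based piecewise-linear scheme of
Nyul & Udupa: learn a standard scale from training volumes by mapping each
volume's foreground deciles onto a common range and averaging, then map any
volume onto that scale by a monotone piecewise-linear transform through its
own deciles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import BinaryMask, connected_components, morphology

__all__ = [
    "IntensityScale", "extract_brain_mask", "anisotropic_diffusion",
    "learn_standard_scale", "standardize_intensities", "apply_standard_map",
]

DECILES = np.arange(10, 100, 10)  # p10 .. p90


@dataclass
class IntensityScale:
    """Learned decile landmarks of the standard intensity scale."""

    landmarks_standard: np.ndarray           # 9 standard-scale decile positions
    standard_range: Tuple[float, float] = (0.0, 4095.0)
    landmarks_input: List[np.ndarray] = field(default_factory=list)  # per training volume

    def __post_init__(self) -> None:
        lm = np.asarray(self.landmarks_standard, dtype=float)
        if lm.ndim != 1 or len(lm) != len(DECILES):
            raise ValueError("landmarks_standard must hold the 9 decile positions")
        if np.any(np.diff(lm) <= 0):
            raise ValueError("standard landmarks must be strictly increasing")
        lo, hi = self.standard_range
        if not (lo < hi) or lm.min() < lo or lm.max() > hi:
            raise ValueError("standard landmarks must lie within standard_range")
        self.landmarks_standard = lm

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps({
            "standard_range": list(self.standard_range),
            "landmarks_standard": self.landmarks_standard.tolist(),
            "landmarks_input": [lm.tolist() for lm in self.landmarks_input],
        }, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "IntensityScale":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["landmarks_standard"]),
                   tuple(d["standard_range"]),
                   [np.asarray(x) for x in d["landmarks_input"]])


def extract_brain_mask(t2: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    """Histogram-threshold brain extraction from a fat-sat T2 volume.

    Otsu threshold separates head from background, then morphological opening,
    largest 26-connected component, closing and hole fill produce a single
    connected, hole-free brain mask.
    """
    t2 = np.asarray(t2, dtype=float)
    if np.ptp(t2) == 0:
        raise ValueError("constant volume: no histogram threshold exists")
    thr = threshold_otsu(t2)
    mask = BinaryMask(t2 > thr, spacing)
    st = ndimage.generate_binary_structure(3, 1)
    opened = ndimage.binary_erosion(mask.mask, st, border_value=0)
    opened = ndimage.binary_dilation(opened, st, border_value=0)
    if not opened.any():
        opened = mask.mask  # opening destroyed everything: fall back
    comp = connected_components(BinaryMask(opened, spacing), connectivity=26)
    largest = comp.component_mask(int(np.argmax(comp.sizes)) + 1)
    closed = morphology(BinaryMask(largest, spacing), "close", radius=2)
    filled = morphology(closed, "fill_holes")
    return filled


def anisotropic_diffusion(grid: np.ndarray, iterations: int = 5,
                          kappa: float | None = None, dt: float = 1.0 / 14.0,
                          ) -> np.ndarray:
    """Perona-Malik diffusion, 6-neighbour flux, reflecting boundaries.

    Conductance g(d) = exp(-(d/kappa)^2).  The stencil is flux-conservative:
    with zero boundary flux the grid's total intensity is preserved exactly.
    ``kappa`` defaults to the median absolute face gradient of the input.
    dt <= 1/14 keeps the 3D explicit scheme stable.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if dt <= 0 or dt > 1.0 / 6.0 + 1e-12:
        raise ValueError("dt must be in (0, 1/6] for stability (default 1/14)")
    out = np.asarray(grid, dtype=np.float64).copy()
    if kappa is None:
        diffs = np.concatenate([np.abs(np.diff(out, axis=a)).ravel() for a in range(3)])
        nz = diffs[diffs > 0]
        kappa = float(np.median(nz)) if nz.size else 1.0
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    for _ in range(iterations):
        div = np.zeros_like(out)
        for a in range(3):
            d = np.diff(out, axis=a)                      # face differences
            flux = np.exp(-(d / kappa) ** 2) * d          # conductance * gradient
            pad = [(0, 0)] * 3
            pad[a] = (1, 1)                               # zero flux at the borders
            f = np.pad(flux, pad)
            sl_hi = [slice(None)] * 3
            sl_lo = [slice(None)] * 3
            sl_hi[a] = slice(1, None)
            sl_lo[a] = slice(0, -1)
            div += f[tuple(sl_hi)] - f[tuple(sl_lo)]
        out += dt * div
    return out


def _foreground_deciles(grid: np.ndarray, mask: BinaryMask) -> np.ndarray:
    fg = np.asarray(grid)[mask.mask]
    if fg.size == 0:
        raise ValueError("empty brain mask")
    lm = np.percentile(fg, DECILES)
    if np.any(np.diff(lm) <= 0):
        raise ValueError("degenerate volume: foreground deciles are not increasing")
    return lm


def learn_standard_scale(volumes: Sequence[np.ndarray],
                         brain_masks: Sequence[BinaryMask],
                         standard_range: Tuple[float, float] = (0.0, 4095.0),
                         ) -> IntensityScale:
    """Learn standard decile landmarks from training volumes.

    Each volume's [p10, p90] is mapped linearly onto ``standard_range``; the
    mapped deciles are averaged across volumes.  Invariant to per-volume
    affine intensity changes.
    """
    if len(volumes) == 0 or len(volumes) != len(brain_masks):
        raise ValueError("need >= 1 training volume with a mask each")
    s_lo, s_hi = standard_range
    mapped, inputs = [], []
    for grid, mask in zip(volumes, brain_masks):
        lm = _foreground_deciles(grid, mask)
        inputs.append(lm)
        m = s_lo + (lm - lm[0]) * (s_hi - s_lo) / (lm[-1] - lm[0])
        mapped.append(np.clip(m, s_lo, s_hi))   # guard 1-ulp rounding overshoot
    return IntensityScale(np.mean(mapped, axis=0), standard_range, inputs)


def standardize_intensities(grid: np.ndarray, mask: BinaryMask,
                            scale: IntensityScale) -> np.ndarray:
    """Map a volume onto the standard scale (monotone piecewise-linear).

    Knots send the volume's own foreground deciles to the standard landmarks;
    beyond p10/p90 the end segments extend linearly, clamped to the standard
    range.  Applied to every voxel of the grid.
    """
    return apply_standard_map(np.asarray(grid, dtype=float),
                              _foreground_deciles(grid, mask), scale)


def apply_standard_map(x: np.ndarray, landmarks_input: np.ndarray,
                       scale: IntensityScale) -> np.ndarray:
    """The piecewise-linear landmark map itself (knots -> standard landmarks)."""
    lm_in = np.asarray(landmarks_input, dtype=float)
    if np.any(np.diff(lm_in) <= 0):
        raise ValueError("input landmarks must be strictly increasing")
    lm_std = scale.landmarks_standard
    x = np.asarray(x, dtype=float)
    out = np.interp(x, lm_in, lm_std)
    lo_slope = (lm_std[1] - lm_std[0]) / (lm_in[1] - lm_in[0])
    hi_slope = (lm_std[-1] - lm_std[-2]) / (lm_in[-1] - lm_in[-2])
    below = x < lm_in[0]
    above = x > lm_in[-1]
    out[below] = lm_std[0] + (x[below] - lm_in[0]) * lo_slope
    out[above] = lm_std[-1] + (x[above] - lm_in[-1]) * hi_slope
    return np.clip(out, scale.standard_range[0], scale.standard_range[1])
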