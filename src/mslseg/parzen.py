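"""Non-parametric first-pass tissue/lesion classification via Parzen windows.

A 2D Gaussian-kernel density is estimated per class from expert (or phantom)
training points in a channel-pair intensity plane, quantized onto a bin grid
("feature map"), and applied by lookup:

* (T2, FLAIR) map -> {parenchyma, CSF, lesion}; GM+WM training points are
  pooled into parenchyma.  Only its lesion class is kept as lesion and its
  CSF class seeds the CSF segmentation.
* (T1, T2) map -> {GM, WM, CSF} seeds for the parametric EM-HMRF stage.

Because classification happens on standardized intensities, one feature map
serves every case.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import BACKGROUND, CSF, GM, LESION, WM, BinaryMask, LabelMap, MultichannelVolume

__all__ = [
    "PARENCHYMA", "TrainingSet", "FeatureMap",
    "parzen_density", "silverman_bandwidth", "build_feature_map",
    "t2flair_feature_map", "t1t2_feature_map",
    "classify_with_feature_map", "split_initial_classes",
]

PARENCHYMA = 5  # extra label code used only by the (T2, FLAIR) map


@dataclass
class TrainingSet:
    """Training points: one row per voxel, class label + channel intensities."""

    rows: pd.DataFrame            # columns: class code column + channel columns
    channel_pair: Tuple[str, str]
    class_column: str = "code"

    def __post_init__(self) -> None:
        for c in (*self.channel_pair, self.class_column):
            if c not in self.rows.columns:
                raise ValueError(f"training table lacks column {c!r}")
        counts = self.rows[self.class_column].value_counts()
        if (counts < 1).any() or counts.empty:
            raise ValueError("every declared class needs >= 1 training row")

    def class_points(self, code: int) -> np.ndarray:
        sel = self.rows[self.rows[self.class_column] == code]
        return sel[list(self.channel_pair)].to_numpy(dtype=float)

    @property
    def classes(self) -> list[int]:
        return sorted(int(c) for c in self.rows[self.class_column].unique())


def parzen_density(points: np.ndarray, class_points: np.ndarray,
                   h: Tuple[float, float]) -> np.ndarray:
    """Product-Gaussian kernel density estimate at 2D query points.

    density(p) = (1/n) sum_i (2 pi hx hy)^-1
                 exp(-(dx_i^2/(2 hx^2) + dy_i^2/(2 hy^2)))
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cp = np.atleast_2d(np.asarray(class_points, dtype=float))
    if cp.shape[0] == 0:
        raise ValueError("empty training class")
    hx, hy = float(h[0]), float(h[1])
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidths must be positive")
    dx = (pts[:, None, 0] - cp[None, :, 0]) / hx
    dy = (pts[:, None, 1] - cp[None, :, 1]) / hy
    k = np.exp(-0.5 * (dx ** 2 + dy ** 2)) / (2.0 * np.pi * hx * hy)
    return k.mean(axis=1)


def silverman_bandwidth(training: TrainingSet,
                        floor_fraction: float = 1e-3,
                        value_range: Tuple[float, float] = (0.0, 4095.0),
                        ) -> Tuple[float, float]:
    """Per-axis bandwidth: within-class Silverman h = sigma * n^(-1/6) (d=2),
    averaged over classes, floored at a small fraction of the value range."""
    per_axis = []
    for axis in range(2):
        hs = []
        for code in training.classes:
            pts = training.class_points(code)[:, axis]
            n = len(pts)
            sd = pts.std(ddof=1) if n > 1 else 0.0
            hs.append(sd * n ** (-1.0 / 6.0))
        per_axis.append(float(np.mean(hs)))
    floor = floor_fraction * (value_range[1] - value_range[0])
    return (max(per_axis[0], floor), max(per_axis[1], floor))


@dataclass
class FeatureMap:
    """Quantized per-class Parzen densities over a 2D intensity plane."""

    channel_pair: Tuple[str, str]
    bin_edges: Tuple[np.ndarray, np.ndarray]
    classes: np.ndarray                  # class codes, ascending
    class_density: np.ndarray            # (n_classes, bins_x, bins_y)
    bandwidth: Tuple[float, float]

    @property
    def bins(self) -> Tuple[int, int]:
        return (len(self.bin_edges[0]) - 1, len(self.bin_edges[1]) - 1)

    @property
    def bin_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        ex, ey = self.bin_edges
        return (0.5 * (ex[:-1] + ex[1:]), 0.5 * (ey[:-1] + ey[1:]))

    @property
    def class_label(self) -> np.ndarray:
        """Per-bin argmax class; ties resolved to the lowest class code."""
        # classes are stored in ascending code order and argmax returns the
        # first maximum, which is exactly the documented tie-break
        return self.classes[np.argmax(self.class_density, axis=0)]

    def bin_index(self, values: np.ndarray, axis: int) -> np.ndarray:
        edges = self.bin_edges[axis]
        idx = np.searchsorted(edges, values, side="right") - 1
        return np.clip(idx, 0, len(edges) - 2)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path, density=self.class_density, classes=self.classes,
            edges_x=self.bin_edges[0], edges_y=self.bin_edges[1],
            meta=json.dumps({"channel_pair": list(self.channel_pair),
                             "bandwidth": list(self.bandwidth)}))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FeatureMap":
        z = np.load(path, allow_pickle=False)
        meta = json.loads(str(z["meta"]))
        return cls(tuple(meta["channel_pair"]), (z["edges_x"], z["edges_y"]),
                   z["classes"], z["density"], tuple(meta["bandwidth"]))


def build_feature_map(training: TrainingSet, bins: int = 256,
                      h: Tuple[float, float] | str = "auto",
                      value_range: Tuple[float, float] = (0.0, 4095.0),
                      ) -> FeatureMap:
    """Evaluate per-class Parzen densities at every bin center of the plane."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    classes = training.classes
    if len(classes) < 1:
        raise ValueError("need >= 1 training class")
    if h == "auto":
        h = silverman_bandwidth(training, value_range=value_range)
    hx, hy = float(h[0]), float(h[1])
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidths must be positive")
    lo, hi = value_range
    edges_x = np.linspace(lo, hi, bins + 1)
    edges_y = np.linspace(lo, hi, bins + 1)
    cx = 0.5 * (edges_x[:-1] + edges_x[1:])
    cy = 0.5 * (edges_y[:-1] + edges_y[1:])
    density = np.empty((len(classes), bins, bins))
    for i, code in enumerate(classes):
        pts = training.class_points(code)
        # separable kernel: outer product of per-axis Gaussians summed over points
        gx = np.exp(-0.5 * ((cx[:, None] - pts[None, :, 0]) / hx) ** 2)
        gy = np.exp(-0.5 * ((cy[:, None] - pts[None, :, 1]) / hy) ** 2)
        density[i] = gx @ gy.T / (len(pts) * 2.0 * np.pi * hx * hy)
    return FeatureMap(training.channel_pair, (edges_x, edges_y),
                      np.asarray(classes), density, (hx, hy))


def t2flair_feature_map(table: pd.DataFrame, bins: int = 256,
                        h="auto", value_range=(0.0, 4095.0)) -> FeatureMap:
    """(T2, FLAIR) map over {parenchyma, CSF, lesion}; GM+WM pooled."""
    rows = table.copy()
    rows["code"] = rows["code"].replace({GM: PARENCHYMA, WM: PARENCHYMA})
    ts = TrainingSet(rows, ("t2", "flair"))
    return build_feature_map(ts, bins=bins, h=h, value_range=value_range)


def t1t2_feature_map(table: pd.DataFrame, bins: int = 256,
                     h="auto", value_range=(0.0, 4095.0)) -> FeatureMap:
    """(T1, T2) map over {GM, WM, CSF}; lesion rows are dropped."""
    rows = table[table["code"] != LESION].copy()
    ts = TrainingSet(rows, ("t1", "t2"))
    return build_feature_map(ts, bins=bins, h=h, value_range=value_range)


def classify_with_feature_map(volume: MultichannelVolume, mask: BinaryMask,
                              fmap: FeatureMap) -> LabelMap:
    """Label each in-mask voxel by its 2D-intensity bin; background outside.

    Out-of-range intensities clamp to the edge bins.  Warns if the volume
    does not look standardized (many intensities far outside the map range).
    """
    cx, cy = fmap.channel_pair
    vx = volume.channels[cx][mask.mask]
    vy = volume.channels[cy][mask.mask]
    lo, hi = fmap.bin_edges[0][0], fmap.bin_edges[0][-1]
    margin = 0.1 * (hi - lo)
    frac_out = np.mean((vx < lo - margin) | (vx > hi + margin) |
                       (vy < lo - margin) | (vy > hi + margin)) if vx.size else 0.0
    if frac_out > 0.1:
        warnings.warn("input intensities look unstandardized for this feature map",
                      stacklevel=2)
    labels = np.zeros(volume.shape, dtype=np.int32)
    lut = fmap.class_label
    labels[mask.mask] = lut[fmap.bin_index(vx, 0), fmap.bin_index(vy, 1)]
    return LabelMap(labels, volume.spacing)


def split_initial_classes(parzen_t2flair: LabelMap, parzen_t1t2: LabelMap,
                          brain_mask: BinaryMask,
                          ) -> tuple[BinaryMask, LabelMap, BinaryMask]:
    """Split the two first-pass classifications into EM inputs.

    Returns ``(lesion_mask, seeds, non_lesion_brain)``: lesions are only the
    (T2, FLAIR) lesion voxels and are excluded from the brain set passed to
    EM-HMRF; GM/WM seeds come from the (T1, T2) classification inside the
    (T2, FLAIR) parenchyma; CSF seeds come from the (T2, FLAIR) CSF class.
    """
    if parzen_t2flair.shape != parzen_t1t2.shape or parzen_t2flair.shape != brain_mask.shape:
        raise ValueError("grid mismatch between classifications")
    a = parzen_t2flair.labels
    b = parzen_t1t2.labels
    lesion = (a == LESION) & brain_mask.mask
    non_lesion_brain = brain_mask.mask & ~lesion
    seeds = np.zeros_like(a)
    parench = (a == PARENCHYMA) & non_lesion_brain
    seeds[parench & (b == GM)] = GM
    seeds[parench & (b == WM)] = WM
    seeds[(a == CSF) & non_lesion_brain] = CSF
    sp = parzen_t2flair.spacing
    return (BinaryMask(lesion, sp), LabelMap(seeds, sp), BinaryMask(non_lesion_brain, sp))
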