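"""False-lesion minimization cascade and fuzzy-connectedness delineation.

Rules, applied in order: (1) lesion voxels inside the cortical-GM atlas mask
become GM (WM lesions do not sit in the cortex); (2) lesion voxels in the
rim within ``rim_depth`` voxels of the brain surface become GM (registration
artefacts); (3) lesion components of <= ``min_lesion_voxels`` voxels become
GM; (4) fuzzy-connectedness growth from the surviving lesion voxels
recaptures the diffuse lesion rims; (5) lesion voxels inside the dilated
lateral-ventricle mask become CSF (choroid plexus); (6) WM/CSF voxels inside
the deep-GM atlas mask become GM.  Growth is barred from the CGM, LVC and
rim exclusion zones so it cannot undo the earlier rules.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .core import (
    CSF, GM, LESION, WM,
    AtlasMaskSet, BinaryMask, LabelMap, connected_components, morphology,
)

__all__ = [
    "FuzzyConfig", "RefinementConfig", "ConnectivityMap",
    "remove_cgm_lesions", "remove_rim_lesions", "remove_small_lesions",
    "compute_affinities", "propagate_strength", "fuzzy_connectedness",
    "delineate_lesions", "reclassify_choroid_plexus", "reclassify_dgm",
    "assemble_final_labels", "run_refinement",
]


@dataclass
class FuzzyConfig:
    """Affinity parameters for fuzzy connectedness on one channel.

    Face-adjacent voxels c, d get affinity

        kappa(c,d) = w1 * exp(-((f(c)+f(d))/2 - m)^2 / (2 s^2))
                   + w2 * exp(-((|f(c)-f(d)|) - m_g)^2 / (2 s_g^2))

    ``m``/``s`` (object mean/sd) and ``s_g`` default to the seed-voxel
    statistics when left as None; ``m_g`` defaults to 0.
    """

    w1: float = 0.5
    w2: float = 0.5
    theta: float = 0.8
    channel: str = "flair"
    m: float | None = None
    s: float | None = None
    m_g: float = 0.0
    s_g: float | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.w1 + self.w2, 1.0):
            raise ValueError("affinity weights w1 + w2 must sum to 1")
        if not (0.0 < self.theta <= 1.0):
            raise ValueError("inclusion threshold theta must be in (0, 1]")


@dataclass
class RefinementConfig:
    min_lesion_voxels: int = 3
    rim_depth: int = 2
    lvc_dilate: int = 1
    component_connectivity: int = 26
    reclassify_dgm_lesions: bool = False   # keep dGM-mask lesions as lesion by default

    def __post_init__(self) -> None:
        if min(self.min_lesion_voxels, self.rim_depth, self.lvc_dilate) < 0:
            raise ValueError("refinement parameters must be non-negative")


@dataclass
class ConnectivityMap:
    """Fuzzy connectedness strength in [0, 1] from the seed set."""
    strength: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# veto rules

def _check_grids(labels: LabelMap, mask: BinaryMask) -> None:
    if labels.shape != mask.shape:
        raise ValueError(f"grid mismatch: {labels.shape} vs {mask.shape}")


def remove_cgm_lesions(labels: LabelMap, cgm: BinaryMask) -> LabelMap:
    """Lesion voxels inside the cortical-GM atlas mask are relabelled GM."""
    _check_grids(labels, cgm)
    out = labels.copy()
    out.labels[(out.labels == LESION) & cgm.mask] = GM
    return out


def remove_rim_lesions(labels: LabelMap, brain_mask: BinaryMask,
                       rim_depth: int = 2) -> LabelMap:
    """Lesion voxels within ``rim_depth`` voxels of the brain surface -> GM."""
    _check_grids(labels, brain_mask)
    if rim_depth < 0:
        raise ValueError("rim_depth must be >= 0")
    out = labels.copy()
    if rim_depth == 0:
        return out
    eroded = morphology(brain_mask, "erode", radius=rim_depth)
    if not eroded.mask.any():
        raise ValueError(f"rim_depth {rim_depth} erodes the brain mask to nothing")
    rim = brain_mask.mask & ~eroded.mask
    out.labels[(out.labels == LESION) & rim] = GM
    return out


def remove_small_lesions(labels: LabelMap, min_voxels: int = 3,
                         connectivity: int = 26) -> LabelMap:
    """Lesion components of <= ``min_voxels`` voxels are relabelled GM."""
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    out = labels.copy()
    if min_voxels == 0:
        return out
    lesions = BinaryMask(out.labels == LESION, out.spacing)
    if not lesions.mask.any():
        return out
    comp = connected_components(lesions, connectivity)
    small = np.flatnonzero(comp.sizes <= min_voxels) + 1
    if small.size:
        out.labels[np.isin(comp.labels, small)] = GM
    return out


# ---------------------------------------------------------------------------
# fuzzy connectedness

def compute_affinities(channel_grid: np.ndarray, mask: np.ndarray,
                       config: FuzzyConfig, m: float, s: float, s_g: float,
                       ) -> List[np.ndarray]:
    """Per-axis face affinities; entry a has shape with axis ``a`` shortened by 1.

    Affinity is 0 whenever either face voxel is outside the mask.
    """
    f = np.asarray(channel_grid, dtype=float)
    out: List[np.ndarray] = []
    for a in range(3):
        hi = [slice(None)] * 3
        lo = [slice(None)] * 3
        hi[a], lo[a] = slice(1, None), slice(0, -1)
        fa, fb = f[tuple(lo)], f[tuple(hi)]
        mean = 0.5 * (fa + fb)
        grad = np.abs(fa - fb)
        kappa = (config.w1 * np.exp(-((mean - m) ** 2) / (2.0 * s ** 2))
                 + config.w2 * np.exp(-((grad - config.m_g) ** 2) / (2.0 * s_g ** 2)))
        kappa[~(mask[tuple(lo)] & mask[tuple(hi)])] = 0.0
        out.append(kappa)
    return out


def propagate_strength(affinities: List[np.ndarray], seeds: np.ndarray,
                       mask: np.ndarray) -> np.ndarray:
    """Max-min path strength from the seed set by best-first propagation.

    strength(v) = max over paths seed->v of the minimum face affinity along
    the path; 1 on seeds, 0 outside the mask.
    """
    if not seeds.any():
        raise ValueError("empty seed set")
    if np.any(seeds & ~mask):
        raise ValueError("seeds must lie inside the mask")
    shape = seeds.shape
    strength = np.zeros(shape)
    strength[seeds] = 1.0
    heap: list[tuple[float, int]] = []
    flat_strength = strength.ravel()
    strides = (shape[1] * shape[2], shape[2], 1)
    for idx in np.flatnonzero(seeds.ravel()):
        heapq.heappush(heap, (-1.0, int(idx)))
    visited = np.zeros(seeds.size, dtype=bool)
    mask_flat = mask.ravel()

    def face_affinity(i3: tuple[int, int, int], axis: int, direction: int) -> float:
        pos = list(i3)
        if direction < 0:
            pos[axis] -= 1
        if pos[axis] < 0 or pos[axis] >= shape[axis] - 1:
            return 0.0
        return float(affinities[axis][tuple(pos)])

    while heap:
        negs, idx = heapq.heappop(heap)
        if visited[idx]:
            continue
        visited[idx] = True
        s_here = -negs
        x, rem = divmod(idx, strides[0])
        y, z = divmod(rem, strides[1])
        for axis, direction in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
            n3 = [x, y, z]
            n3[axis] += direction
            if not (0 <= n3[axis] < shape[axis]):
                continue
            nidx = n3[0] * strides[0] + n3[1] * strides[1] + n3[2]
            if visited[nidx] or not mask_flat[nidx]:
                continue
            cand = min(s_here, face_affinity((x, y, z), axis, direction))
            if cand > flat_strength[nidx]:
                flat_strength[nidx] = cand
                heapq.heappush(heap, (-cand, int(nidx)))
    return strength


def fuzzy_connectedness(channel_grid: np.ndarray, seeds: BinaryMask,
                        brain_mask: BinaryMask, config: FuzzyConfig | None = None,
                        ) -> ConnectivityMap:
    """Connectedness strength of every brain voxel to the lesion seed set."""
    config = config or FuzzyConfig()
    if not seeds.mask.any():
        raise ValueError("empty seed set")
    seed_vals = np.asarray(channel_grid)[seeds.mask]
    m = config.m if config.m is not None else float(seed_vals.mean())
    s = config.s if config.s is not None else float(max(seed_vals.std(), 1e-6))
    s_g = config.s_g if config.s_g is not None else float(max(seed_vals.std(), 1e-6))
    if s <= 0 or s_g <= 0:
        raise ValueError("affinity spreads must be positive")
    aff = compute_affinities(channel_grid, brain_mask.mask, config, m, s, s_g)
    strength = propagate_strength(aff, seeds.mask, brain_mask.mask)
    return ConnectivityMap(strength, seeds.spacing)


def delineate_lesions(labels: LabelMap, connectivity_map: ConnectivityMap,
                      theta: float, protected: AtlasMaskSet,
                      brain_mask: BinaryMask, rules: RefinementConfig,
                      ) -> LabelMap:
    """Grow lesions to voxels with strength >= theta, respecting veto zones.

    Voxels inside the CGM mask, inside the dilated+closed LVC mask, or in the
    brain-surface rim are never added, so growth cannot undo earlier rules.
    """
    if not (0.0 < theta <= 1.0):
        raise ValueError("theta must be in (0, 1]")
    out = labels.copy()
    grow = (connectivity_map.strength >= theta) & brain_mask.mask
    lvc_zone = _dilated_lvc(protected.lvc, rules.lvc_dilate)
    grow &= ~protected.cgm.mask
    grow &= ~lvc_zone.mask
    if rules.rim_depth > 0:
        eroded = morphology(brain_mask, "erode", radius=rules.rim_depth)
        grow &= eroded.mask
    tissue = np.isin(out.labels, (GM, WM))
    out.labels[grow & tissue] = LESION
    return out


# ---------------------------------------------------------------------------
# anatomy-driven reclassification

def _dilated_lvc(lvc: BinaryMask, lvc_dilate: int) -> BinaryMask:
    zone = lvc
    if lvc_dilate > 0:
        zone = morphology(zone, "dilate", radius=lvc_dilate)
        zone = morphology(zone, "close", radius=lvc_dilate)
    return zone


def reclassify_choroid_plexus(labels: LabelMap, lvc: BinaryMask,
                              lvc_dilate: int = 1) -> LabelMap:
    """Lesion voxels inside the dilated+closed LVC mask become CSF."""
    _check_grids(labels, lvc)
    zone = _dilated_lvc(lvc, lvc_dilate)
    out = labels.copy()
    out.labels[(out.labels == LESION) & zone.mask] = CSF
    return out


def reclassify_dgm(labels: LabelMap, dgm: BinaryMask,
                   include_lesions: bool = False) -> LabelMap:
    """WM and CSF voxels inside the deep-GM atlas mask become GM.

    Lesion voxels in the mask are kept as lesion unless ``include_lesions``.
    """
    _check_grids(labels, dgm)
    out = labels.copy()
    codes = (WM, CSF, LESION) if include_lesions else (WM, CSF)
    out.labels[np.isin(out.labels, codes) & dgm.mask] = GM
    return out


def assemble_final_labels(cerebral: LabelMap, cerebellar: LabelMap,
                          lesions: BinaryMask, cerebellum_mask: BinaryMask,
                          ) -> LabelMap:
    """Combine cerebral GM/WM/CSF, cerebellar GM/WM and the lesion mask."""
    for other in (cerebellar.labels, lesions.mask, cerebellum_mask.mask):
        if other.shape != cerebral.shape:
            raise ValueError("grid mismatch between label maps")
    if np.any((cerebellar.labels > 0) & ~cerebellum_mask.mask):
        raise ValueError("cerebellar labels outside the cerebellum mask")
    out = cerebral.copy()
    out.labels[cerebellum_mask.mask] = cerebellar.labels[cerebellum_mask.mask]
    out.labels[lesions.mask] = LESION
    return out


# ---------------------------------------------------------------------------
# full cascade

def run_refinement(labels: LabelMap, channel_grid: np.ndarray,
                   atlas: AtlasMaskSet, brain_mask: BinaryMask,
                   rules: RefinementConfig | None = None,
                   fuzzy: FuzzyConfig | None = None,
                   collect_stages: bool = False):
    """Apply the full false-positive cascade; optionally return stage maps.

    Order: CGM -> rim -> small components -> fuzzy growth -> LVC/choroid ->
    dGM.  Idempotent: a second application is a no-op.
    """
    rules = rules or RefinementConfig()
    fuzzy = fuzzy or FuzzyConfig()
    stages = [("input", labels)]
    lab = remove_cgm_lesions(labels, atlas.cgm)
    stages.append(("cgm", lab))
    lab = remove_rim_lesions(lab, brain_mask, rules.rim_depth)
    stages.append(("rim", lab))
    lab = remove_small_lesions(lab, rules.min_lesion_voxels,
                               rules.component_connectivity)
    stages.append(("small", lab))
    seeds = BinaryMask(lab.labels == LESION, lab.spacing)
    if seeds.mask.any():
        cmap = fuzzy_connectedness(channel_grid, seeds, brain_mask, fuzzy)
        lab = delineate_lesions(lab, cmap, fuzzy.theta, atlas, brain_mask, rules)
        # growth may assemble new sub-threshold fragments; re-apply the size rule
        lab = remove_small_lesions(lab, rules.min_lesion_voxels,
                                   rules.component_connectivity)
    stages.append(("fuzzy", lab))
    lab = reclassify_choroid_plexus(lab, atlas.lvc, rules.lvc_dilate)
    stages.append(("lvc", lab))
    lab = reclassify_dgm(lab, atlas.dgm, rules.reclassify_dgm_lesions)
    stages.append(("dgm", lab))
    if collect_stages:
        return lab, stages
    return lab
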