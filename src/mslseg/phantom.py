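"""Deterministic synthetic multichannel 3D MS brain phantom.

The phantom is a parametric nested-ellipsoid brain: an outer CSF rim, a
cortical GM ribbon, a WM interior carrying two ellipsoidal lateral
ventricles, thalamus-like deep-GM blobs, a cerebellum sub-ellipsoid with its
own GM/WM contrast, spherical white-matter lesions, and choroid-plexus decoy
blobs inside the ventricles with lesion-like intensities.  Per-channel
intensities are class mean x smooth multiplicative bias field (low-order
polynomial) + noise.  Everything — geometry, ground-truth labels, atlas
masks, brain mask, training points, bias fields — is derived from one seeded
RNG, so a (spec, seed) pair fully determines the output bit-for-bit.

Default contrast respects the qualitative MS appearance on each sequence:
lesions hyperintense on T2/FLAIR and hypointense on T1, CSF brightest on T2
and nulled on FLAIR, deep GM hypointense on T2 (hence prone to be labelled
WM by intensity-only classifiers — the failure mode the atlas rule fixes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    BACKGROUND, CSF, GM, WM, LESION,
    AtlasMaskSet, BinaryMask, LabelMap, MultichannelVolume,
)

__all__ = [
    "PhantomSpec", "PhantomOutput", "generate_phantom", "sample_training_points",
    "DEFAULT_CLASS_INTENSITIES", "DEFAULT_TRAINING_COUNTS", "REGION",
]

CHANNELS = ("t1", "t2", "flair")

# Arbitrary-unit class means per channel.  "dgm", "choroid", "cereb_*" are
# intensity regions, not truth classes: dgm/cereb_gm are truth GM, cereb_wm
# is truth WM, choroid is truth CSF.
DEFAULT_CLASS_INTENSITIES: Dict[str, Dict[str, float]] = {
    "csf":      {"t1": 40.0,  "t2": 160.0, "flair": 30.0},
    "gm":       {"t1": 90.0,  "t2": 95.0,  "flair": 95.0},
    "wm":       {"t1": 150.0, "t2": 55.0,  "flair": 70.0},
    "lesion":   {"t1": 42.0,  "t2": 130.0, "flair": 150.0},
    "dgm":      {"t1": 110.0, "t2": 58.0,  "flair": 75.0},
    "choroid":  {"t1": 42.0,  "t2": 130.0, "flair": 150.0},
    "cereb_gm": {"t1": 80.0,  "t2": 100.0, "flair": 100.0},
    "cereb_wm": {"t1": 135.0, "t2": 62.0,  "flair": 78.0},
}

DEFAULT_TRAINING_COUNTS: Dict[str, int] = {"gm": 100, "wm": 111, "csf": 124, "lesion": 168}


class REGION:
    """Codes of the intensity-homogeneous regions of the phantom."""
    BG = 0
    CSF_RIM = 1
    CGM = 2
    WM = 3
    LESION = 4
    VENTRICLE = 5
    DGM = 6
    CHOROID = 7
    CEREB_GM = 8
    CEREB_WM = 9


_REGION_INTENSITY = {
    REGION.CSF_RIM: "csf", REGION.VENTRICLE: "csf", REGION.CGM: "gm",
    REGION.WM: "wm", REGION.LESION: "lesion", REGION.DGM: "dgm",
    REGION.CHOROID: "choroid", REGION.CEREB_GM: "cereb_gm",
    REGION.CEREB_WM: "cereb_wm",
}

_REGION_TRUTH = {
    REGION.CSF_RIM: CSF, REGION.VENTRICLE: CSF, REGION.CHOROID: CSF,
    REGION.CGM: GM, REGION.DGM: GM, REGION.CEREB_GM: GM,
    REGION.WM: WM, REGION.CEREB_WM: WM, REGION.LESION: LESION,
    REGION.BG: BACKGROUND,
}

# Geometry in voxel units on the reference 64^3 grid; scaled with the shape.
_GEOM = {
    "brain_r": (26.0, 29.0, 24.0),
    "gm_outer_r": (24.0, 27.0, 22.0),
    "wm_outer_r": (21.0, 24.0, 19.0),
    "ventricles": [((24.0, 28.0, 34.0), (4.0, 7.0, 4.0)),
                   ((40.0, 28.0, 34.0), (4.0, 7.0, 4.0))],
    "dgm": [((20.0, 38.0, 32.0), (3.0, 4.0, 3.0)),
            ((44.0, 38.0, 32.0), (3.0, 4.0, 3.0))],
    "cereb_center": (32.0, 44.0, 20.0),
    "cereb_r": (10.0, 8.0, 7.0),
    "cereb_inner_r": (8.0, 6.0, 5.0),
}


@dataclass
class PhantomSpec:
    shape: Tuple[int, int, int] = (64, 64, 64)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    class_intensities: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_INTENSITIES.items()})
    n_lesions: int = 6
    lesion_radius_range: Tuple[float, float] = (3.0, 4.5)   # mm
    lesion_margin_mm: float = 2.0                            # clearance to WM border
    n_choroid_decoys: int = 3
    choroid_radius_mm: float = 1.6
    bias_amplitude: float = 0.2       # fractional amplitude of multiplicative field
    noise_sd: float = 4.0             # intensity units
    noise_model: str = "gaussian"     # or "rician"
    atlas_perturbation: int = 0       # voxels of atlas-mask dilation
    seed: int = 0

    def validate(self) -> None:
        t = self.class_intensities
        need = set(DEFAULT_CLASS_INTENSITIES)
        if set(t) != need:
            raise ValueError(f"class_intensities must define {sorted(need)}")
        # contrast contract the classifiers rely on
        if not (t["csf"]["t2"] > t["lesion"]["t2"] > t["gm"]["t2"] > t["wm"]["t2"]):
            raise ValueError("invalid T2 ordering: need CSF > lesion > GM > WM")
        if not (t["lesion"]["flair"] > t["gm"]["flair"] > t["wm"]["flair"] > t["csf"]["flair"]):
            raise ValueError("invalid FLAIR ordering: need lesion > GM > WM > CSF")
        if not (t["wm"]["t1"] > t["gm"]["t1"] > t["csf"]["t1"]):
            raise ValueError("invalid T1 ordering: need WM > GM > CSF")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.n_lesions < 0 or self.n_choroid_decoys < 0:
            raise ValueError("counts must be non-negative")
        if not (0 <= self.bias_amplitude < 1):
            raise ValueError("bias_amplitude must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("invalid lesion_radius_range")


@dataclass
class PhantomOutput:
    volume: MultichannelVolume
    truth: LabelMap
    atlas: AtlasMaskSet
    brain_mask: BinaryMask
    training_points: pd.DataFrame
    bias_fields: Dict[str, np.ndarray]
    region: np.ndarray            # intensity-region codes (REGION.*)
    spec: PhantomSpec


def _ellipsoid(shape: Tuple[int, int, int], center: Tuple[float, float, float],
               radii: Tuple[float, float, float]) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    q = sum(((idx[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    return q <= 1.0


def _scale_pt(pt, shape) -> Tuple[float, float, float]:
    return tuple(pt[a] * shape[a] / 64.0 for a in range(3))


def _paint_geometry(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    shape = tuple(spec.shape)
    sc = lambda p: _scale_pt(p, shape)
    center = tuple(s / 2.0 for s in shape)

    region = np.zeros(shape, dtype=np.int16)
    brain = _ellipsoid(shape, center, sc(_GEOM["brain_r"]))
    gm_out = _ellipsoid(shape, center, sc(_GEOM["gm_outer_r"]))
    wm_out = _ellipsoid(shape, center, sc(_GEOM["wm_outer_r"]))
    region[brain] = REGION.CSF_RIM
    region[gm_out] = REGION.CGM
    region[wm_out] = REGION.WM

    # cerebellum sub-ellipsoid with its own GM shell / WM core
    cereb = _ellipsoid(shape, sc(_GEOM["cereb_center"]), sc(_GEOM["cereb_r"]))
    cereb_in = _ellipsoid(shape, sc(_GEOM["cereb_center"]), sc(_GEOM["cereb_inner_r"]))
    region[cereb] = REGION.CEREB_GM
    region[cereb_in] = REGION.CEREB_WM

    for c, r in _GEOM["ventricles"]:
        region[_ellipsoid(shape, sc(c), sc(r))] = REGION.VENTRICLE
    for c, r in _GEOM["dgm"]:
        blob = _ellipsoid(shape, sc(c), sc(r))
        region[blob & (region == REGION.WM)] = REGION.DGM

    _place_choroid(region, spec, rng)
    _place_lesions(region, spec, rng)
    return region


def _mm_distance_grid(shape, center, spacing) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    return np.sqrt(sum(((idx[a] - center[a]) * spacing[a]) ** 2 for a in range(3)))


def _place_spheres(region: np.ndarray, spec: PhantomSpec, rng: np.random.Generator,
                   host_code: int, new_code: int, radii_mm: np.ndarray,
                   margin_mm: float, what: str) -> None:
    """Place non-overlapping spheres (mm metric) fully inside the host region."""
    spacing = np.asarray(spec.spacing)
    host = region == host_code
    # mm distance to the nearest non-host voxel: a sphere of radius r centred
    # at c fits inside the host iff edt(c) >= r + margin
    edt = ndimage.distance_transform_edt(host, sampling=spacing)
    placed: list[tuple[np.ndarray, float]] = []
    for i, r in enumerate(radii_mm):
        ok = edt >= (r + margin_mm)
        cand = np.argwhere(ok)
        rng.shuffle(cand)
        center = None
        for c in cand[:2000]:
            if all(np.sqrt((((c - pc) * spacing) ** 2).sum()) >= r + pr + 1.0
                   for pc, pr in placed):
                center = c
                break
        if center is None:
            raise ValueError(
                f"{what} #{i + 1} (radius {r:.2f} mm) does not fit in the host region")
        d = _mm_distance_grid(region.shape, center, spacing)
        region[(d <= r) & host] = new_code
        placed.append((center.astype(float), float(r)))


def _place_lesions(region: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> None:
    if spec.n_lesions == 0:
        return
    lo, hi = spec.lesion_radius_range
    radii = rng.uniform(lo, hi, size=spec.n_lesions)
    _place_spheres(region, spec, rng, REGION.WM, REGION.LESION, radii,
                   spec.lesion_margin_mm, "lesion")


def _place_choroid(region: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> None:
    if spec.n_choroid_decoys == 0:
        return
    radii = np.full(spec.n_choroid_decoys, spec.choroid_radius_mm)
    _place_spheres(region, spec, rng, REGION.VENTRICLE, REGION.CHOROID, radii,
                   0.5, "choroid decoy")


def _bias_field(shape, brain: np.ndarray, amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude*q, q a normalized quadratic."""
    coef = rng.normal(size=9)
    if amplitude == 0.0:
        return np.ones(shape)
    idx = np.indices(shape, dtype=np.float64)
    u = [2.0 * idx[a] / (shape[a] - 1) - 1.0 for a in range(3)]
    q = (coef[0] * u[0] + coef[1] * u[1] + coef[2] * u[2]
         + coef[3] * u[0] * u[1] + coef[4] * u[0] * u[2] + coef[5] * u[1] * u[2]
         + coef[6] * u[0] ** 2 + coef[7] * u[1] ** 2 + coef[8] * u[2] ** 2)
    q = q - q[brain].mean()
    peak = np.abs(q[brain]).max()
    if peak > 0:
        q = q / peak
    return 1.0 + amplitude * q


def generate_phantom(spec: PhantomSpec | None = None, **overrides) -> PhantomOutput:
    """Generate the full phantom for ``spec`` (see :class:`PhantomSpec`)."""
    if spec is None:
        spec = PhantomSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)

    region = _paint_geometry(spec, rng)
    brain = region != REGION.BG

    mean_lut = np.zeros((10, len(CHANNELS)))
    for rc, cls in _REGION_INTENSITY.items():
        for j, ch in enumerate(CHANNELS):
            mean_lut[rc, j] = spec.class_intensities[cls][ch]

    bias_fields: Dict[str, np.ndarray] = {}
    channels: Dict[str, np.ndarray] = {}
    for j, ch in enumerate(CHANNELS):
        b = _bias_field(shape, brain, spec.bias_amplitude, rng)
        bias_fields[ch] = b
        signal = mean_lut[region, j] * b
        if spec.noise_sd > 0:
            if spec.noise_model == "gaussian":
                signal = signal + rng.normal(0.0, spec.noise_sd, size=shape)
            else:  # rician
                n1 = rng.normal(0.0, spec.noise_sd, size=shape)
                n2 = rng.normal(0.0, spec.noise_sd, size=shape)
                signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)
        channels[ch] = signal

    volume = MultichannelVolume(channels, spec.spacing)
    truth_codes = np.array([_REGION_TRUTH[c] for c in range(10)], dtype=np.int32)
    truth = LabelMap(truth_codes[region], spec.spacing)

    atlas = _atlas_from_region(region, spec)
    brain_mask = BinaryMask(brain, spec.spacing)

    training = sample_training_points(
        PhantomOutput(volume, truth, atlas, brain_mask, pd.DataFrame(),
                      bias_fields, region, spec),
        seed=int(rng.integers(0, 2 ** 31 - 1)))

    return PhantomOutput(volume, truth, atlas, brain_mask, training,
                         bias_fields, region, spec)


def _atlas_from_region(region: np.ndarray, spec: PhantomSpec) -> AtlasMaskSet:
    st = ndimage.generate_binary_structure(3, 1)
    def mk(mask: np.ndarray) -> BinaryMask:
        if spec.atlas_perturbation > 0:
            mask = ndimage.binary_dilation(mask, st, iterations=spec.atlas_perturbation)
        return BinaryMask(mask, spec.spacing)
    cgm = region == REGION.CGM
    lvc = (region == REGION.VENTRICLE) | (region == REGION.CHOROID)
    dgm = region == REGION.DGM
    cereb = (region == REGION.CEREB_GM) | (region == REGION.CEREB_WM)
    atl = AtlasMaskSet(mk(cgm), mk(lvc), mk(dgm), mk(cereb))
    if spec.atlas_perturbation > 0:
        # keep the mandatory disjointness after dilation
        atl.dgm.mask &= ~atl.cgm.mask
    return atl


# regions a class's training points are drawn from: each class is sampled
# from its intensity-canonical cerebral region, emulating the expert picking
# representative voxels (deep GM / choroid / cerebellum are deliberately not
# representative of their truth class and are excluded)
_TRAINING_REGIONS = {
    "csf": (REGION.CSF_RIM, REGION.VENTRICLE),
    "gm": (REGION.CGM,),
    "wm": (REGION.WM,),
    "lesion": (REGION.LESION,),
}

_CLASS_CODE = {"csf": CSF, "gm": GM, "wm": WM, "lesion": LESION}


def sample_training_points(output: PhantomOutput,
                           n_per_class: Mapping[str, int] | None = None,
                           seed: int = 0,
                           channels: Mapping[str, np.ndarray] | None = None,
                           ) -> pd.DataFrame:
    """Sample interior voxels of each class and record channel intensities.

    ``channels`` overrides the grids the intensities are read from (e.g. the
    standardized volume); voxel selection is unchanged.  Default counts are
    GM 100, WM 111, CSF 124, lesion 168.
    """
    if n_per_class is None:
        n_per_class = dict(DEFAULT_TRAINING_COUNTS)
    rng = np.random.default_rng(seed)
    st = ndimage.generate_binary_structure(3, 1)
    grids = channels if channels is not None else output.volume.channels
    rows = []
    for cls, n in n_per_class.items():
        if cls not in _TRAINING_REGIONS:
            raise ValueError(f"unknown class {cls!r}")
        mask = np.isin(output.region, _TRAINING_REGIONS[cls])
        if not mask.any():
            raise ValueError(f"class {cls!r} absent from the phantom")
        interior = ndimage.binary_erosion(mask, st, border_value=0)
        coords = np.argwhere(interior)
        if len(coords) < n:
            raise ValueError(
                f"class {cls!r}: only {len(coords)} interior voxels, {n} requested")
        pick = coords[rng.choice(len(coords), size=n, replace=False)]
        for c in pick:
            row = {"class": cls, "code": _CLASS_CODE[cls]}
            for ch in CHANNELS:
                row[ch] = float(grids[ch][tuple(c)])
            row.update({"x": int(c[0]), "y": int(c[1]), "z": int(c[2])})
            rows.append(row)
    return pd.DataFrame(rows)
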