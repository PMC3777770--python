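"""Volume/label data model, NIfTI I/O and shared spatial utilities.

Conventions used throughout the package:

* voxel coordinates are 0-based integer ``(x, y, z)`` indices in array order;
* physical distances are computed in mm from the per-axis voxel spacing
  (anisotropic spacing is supported everywhere);
* tissue label codes are fixed: 0 background, 1 CSF, 2 GM, 3 WM, 4 lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "BACKGROUND", "CSF", "GM", "WM", "LESION", "CODE_TABLE",
    "MultichannelVolume", "LabelMap", "BinaryMask", "AtlasMaskSet",
    "ComponentLabeling",
    "read_volume", "write_volume", "read_mask", "write_mask",
    "read_label_map", "write_label_map",
    "extract_boundary", "boundary_mask", "connected_components", "morphology",
]

BACKGROUND = 0
CSF = 1
GM = 2
WM = 3
LESION = 4

CODE_TABLE: Dict[int, str] = {
    BACKGROUND: "background", CSF: "csf", GM: "gm", WM: "wm", LESION: "lesion",
}

# face / edge / vertex adjacency structuring elements
_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

Spacing = Tuple[float, float, float]


def _check_spacing(spacing: Iterable[float]) -> Spacing:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValueError(f"spacing must be 3 positive reals, got {s}")
    return s  # type: ignore[return-value]


@dataclass
class MultichannelVolume:
    """Co-registered 3D scalar grids, one per MR channel, on a shared grid."""

    channels: Dict[str, np.ndarray]
    spacing: Spacing = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {name: np.asarray(g).shape for name, g in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(sh) != 3 for sh in shapes.values()):
            raise ValueError(f"all channels must be 3D, got shapes {shapes}")
        if any(sh != first for sh in shapes.values()):
            raise ValueError(f"grid mismatch between channels: {shapes}")
        for name, g in self.channels.items():
            g = np.asarray(g, dtype=np.float64) if not np.issubdtype(
                np.asarray(g).dtype, np.floating) else np.asarray(g)
            if not np.all(np.isfinite(g)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            self.channels[name] = g
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> Tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def stack(self, channel_names: Iterable[str]) -> np.ndarray:
        """Channels stacked on the last axis, shape (*grid, n_channels)."""
        return np.stack([self.channels[c] for c in channel_names], axis=-1)


@dataclass
class BinaryMask:
    mask: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise ValueError("mask must be 3D")
        if m.dtype != np.bool_:
            uniq = np.unique(m)
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValueError("mask values must be strictly boolean (0/1)")
            m = m.astype(bool)
        self.mask = m
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.mask.sum())

    def volume_mm3(self) -> float:
        return self.count() * self.voxel_volume


@dataclass
class LabelMap:
    """Per-voxel tissue code grid; canonical codes in :data:`CODE_TABLE`."""

    labels: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)
    code_table: Dict[int, str] = field(default_factory=lambda: dict(CODE_TABLE))

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("label grid must be 3D")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("labels must be integers")
            lab = np.round(lab).astype(np.int32)
        if lab.min() < 0:
            raise ValueError("negative label codes are not allowed")
        self.labels = lab.astype(np.int32, copy=False)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    def class_mask(self, code: int) -> BinaryMask:
        return BinaryMask(self.labels == code, self.spacing)

    def class_counts(self) -> Dict[int, int]:
        codes, counts = np.unique(self.labels, return_counts=True)
        return {int(c): int(n) for c, n in zip(codes, counts)}

    def class_volume_mm3(self, code: int) -> float:
        return float((self.labels == code).sum()) * float(np.prod(self.spacing))

    def copy(self) -> "LabelMap":
        return LabelMap(self.labels.copy(), self.spacing, dict(self.code_table))


@dataclass
class AtlasMaskSet:
    """Subject-space atlas masks driving the false-positive rules."""

    cgm: BinaryMask
    lvc: BinaryMask
    dgm: BinaryMask
    cerebellum: BinaryMask

    def __post_init__(self) -> None:
        shapes = {n: getattr(self, n).shape for n in ("cgm", "lvc", "dgm", "cerebellum")}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"atlas masks must share one grid, got {shapes}")
        if np.any(self.dgm.mask & self.cgm.mask):
            raise ValueError("dgm and cgm atlas masks must be disjoint")


# ---------------------------------------------------------------------------
# NIfTI I/O

def _load_nifti(path: str | Path) -> tuple[np.ndarray, Spacing, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got shape {data.shape}")
    spacing = _check_spacing(img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def read_volume(paths: Mapping[str, str | Path],
                expected_channels: Iterable[str] | None = None) -> MultichannelVolume:
    """Read one NIfTI file per channel into a :class:`MultichannelVolume`.

    ``paths`` maps channel id (e.g. ``"t1"``) to a NIfTI-1 path.  No
    resampling is performed — channels on mismatched grids are an error.
    """
    if expected_channels is not None:
        missing = set(expected_channels) - set(paths)
        if missing:
            raise ValueError(f"missing channels: {sorted(missing)}")
    channels: Dict[str, np.ndarray] = {}
    spacing: Spacing | None = None
    affine = None
    for name, p in paths.items():
        data, sp, aff = _load_nifti(p)
        if spacing is None:
            spacing, affine = sp, aff
        else:
            if data.shape != next(iter(channels.values())).shape:
                raise ValueError(
                    f"grid mismatch: channel {name!r} shape {data.shape} vs "
                    f"{next(iter(channels.values())).shape}")
            if not np.allclose(sp, spacing):
                raise ValueError(f"grid mismatch: channel {name!r} spacing {sp} vs {spacing}")
        channels[name] = data
    return MultichannelVolume(channels, spacing, affine)


def write_volume(vol: MultichannelVolume, directory: str | Path,
                 suffix: str = ".nii.gz") -> Dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: Dict[str, Path] = {}
    for name, grid in vol.channels.items():
        p = directory / f"{name}{suffix}"
        nib.save(nib.Nifti1Image(grid.astype(np.float64), vol.affine), str(p))
        out[name] = p
    return out


def read_mask(path: str | Path) -> BinaryMask:
    data, spacing, _ = _load_nifti(path)
    return BinaryMask(data > 0.5, spacing)


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))
    return path


def read_label_map(path: str | Path) -> LabelMap:
    data, spacing, _ = _load_nifti(path)
    return LabelMap(np.round(data).astype(np.int32), spacing)


def write_label_map(labels: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(labels.spacing) + [1.0])
    nib.save(nib.Nifti1Image(labels.labels.astype(np.uint8), affine), str(path))
    return path


# ---------------------------------------------------------------------------
# Spatial utilities

def boundary_mask(mask: BinaryMask) -> BinaryMask:
    """Mask voxels with >= 1 face-adjacent outside voxel (volume edge counts)."""
    if not mask.mask.any():
        raise ValueError("boundary of an empty mask is undefined")
    interior = ndimage.binary_erosion(mask.mask, _STRUCTS[6], border_value=0)
    return BinaryMask(mask.mask & ~interior, mask.spacing)


def extract_boundary(mask: BinaryMask) -> np.ndarray:
    """Boundary voxel coordinates as an (N, 3) int array (6-connectivity)."""
    return np.argwhere(boundary_mask(mask).mask)


@dataclass
class ComponentLabeling:
    labels: np.ndarray           # 0 = background, 1..n_components
    n_components: int
    sizes: np.ndarray            # voxels, index c-1 for component c
    sizes_mm3: np.ndarray

    def component_mask(self, c: int) -> np.ndarray:
        return self.labels == c


def connected_components(mask: BinaryMask, connectivity: int = 26) -> ComponentLabeling:
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    lab, n = ndimage.label(mask.mask, structure=_STRUCTS[connectivity])
    sizes = np.bincount(lab.ravel(), minlength=n + 1)[1:].astype(np.int64)
    return ComponentLabeling(lab, int(n), sizes, sizes * mask.voxel_volume)


def morphology(mask: BinaryMask, op: str, radius: int = 1) -> BinaryMask:
    """Binary morphology with a face-connected structuring element.

    ``erode``/``dilate``/``close`` iterate the 6-connected element ``radius``
    times; ``close`` treats the volume border as foreground during its erosion
    phase so closing never shrinks the input.  ``fill_holes`` fills cavities
    not connected to the volume border.
    """
    st = _STRUCTS[6]
    m = mask.mask
    if op == "fill_holes":
        return BinaryMask(ndimage.binary_fill_holes(m), mask.spacing)
    if radius < 1:
        raise ValueError(f"radius must be >= 1 for {op!r}")
    if op == "erode":
        out = ndimage.binary_erosion(m, st, iterations=radius, border_value=0)
    elif op == "dilate":
        out = ndimage.binary_dilation(m, st, iterations=radius, border_value=0)
    elif op == "close":
        d = ndimage.binary_dilation(m, st, iterations=radius, border_value=0)
        out = ndimage.binary_erosion(d, st, iterations=radius, border_value=1)
    else:
        raise ValueError(f"unknown morphology op {op!r}")
    return BinaryMask(out, mask.spacing)
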