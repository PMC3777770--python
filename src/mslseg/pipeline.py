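"""End-to-end orchestration: preprocess -> Parzen -> EM-HMRF -> refinement.

Two entry points:

* :func:`segment_case` — in-memory pipeline on an already standardized
  volume plus atlas masks and a (standardized-scale) training table;
* :func:`run_pipeline` — disk-to-disk run driven by a validated YAML config,
  writing every intermediate artifact and a provenance manifest.

:func:`run_phantom_pipeline` wires a synthetic phantom through the whole
flow (diffusion, self-standardization, training-point sampling, both Parzen
maps, cerebral + cerebellar EM-HMRF, the false-positive cascade) and, when
ground truth is available, records the lesion-metric trajectory after every
cascade stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    CSF, GM, LESION, WM,
    AtlasMaskSet, BinaryMask, LabelMap, MultichannelVolume,
    read_mask, read_volume, write_label_map, write_mask, write_volume,
)
from .evaluate import EvaluationReport, evaluate_lesions
from .hmrf import EMResult, HMRFConfig, em_hmrf_segment, segment_cerebellum
from .parzen import (
    classify_with_feature_map, split_initial_classes,
    t1t2_feature_map, t2flair_feature_map,
)
from .phantom import PhantomOutput, sample_training_points
from .preprocess import (
    anisotropic_diffusion, extract_brain_mask, learn_standard_scale,
    standardize_intensities,
)
from .refine import (
    FuzzyConfig, RefinementConfig, assemble_final_labels, run_refinement,
)

__all__ = [
    "DiffusionConfig", "ScaleConfig", "ParzenConfig", "PipelineConfig",
    "PipelineResult", "validate_config", "segment_case",
    "run_phantom_pipeline", "run_pipeline",
]

CHANNELS = ("t1", "t2", "flair")


@dataclass
class DiffusionConfig:
    iterations: int = 5
    kappa: Optional[float] = None      # None: median-gradient heuristic
    dt: float = 1.0 / 14.0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("diffusion.iterations must be >= 1")
        if not (0 < self.dt <= 1.0 / 6.0 + 1e-12):
            raise ValueError("diffusion.dt must be in (0, 1/6]")
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("diffusion.kappa must be positive")


@dataclass
class ScaleConfig:
    standard_range: Tuple[float, float] = (0.0, 4095.0)

    def __post_init__(self) -> None:
        lo, hi = self.standard_range
        if not lo < hi:
            raise ValueError("scale.standard_range must be increasing")


@dataclass
class ParzenConfig:
    bins: int = 256
    bandwidth: str | Tuple[float, float] = "auto"

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("parzen.bins must be >= 2")


@dataclass
class PipelinePaths:
    t1: str = ""
    t2: str = ""
    flair: str = ""
    cgm: str = ""
    lvc: str = ""
    dgm: str = ""
    cerebellum: str = ""
    training: str = ""
    out_dir: str = "out"
    brain_mask: str = ""      # optional: skip brain extraction
    truth: str = ""           # optional: reference label map for evaluation


@dataclass
class PipelineConfig:
    seed: int = 0
    paths: PipelinePaths = field(default_factory=PipelinePaths)
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    scale: ScaleConfig = field(default_factory=ScaleConfig)
    parzen: ParzenConfig = field(default_factory=ParzenConfig)
    hmrf: HMRFConfig = field(default_factory=HMRFConfig)
    fuzzy: FuzzyConfig = field(default_factory=FuzzyConfig)
    refine: RefinementConfig = field(default_factory=RefinementConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_SECTIONS = {
    "paths": PipelinePaths, "diffusion": DiffusionConfig, "scale": ScaleConfig,
    "parzen": ParzenConfig, "hmrf": HMRFConfig, "fuzzy": FuzzyConfig,
    "refine": RefinementConfig,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {section!r}: {sorted(unknown)}")
    if "standard_range" in data:
        data = {**data, "standard_range": tuple(data["standard_range"])}
    return cls(**data)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse + validate a YAML pipeline config; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict = {"seed": int(raw.get("seed", 0))}
    for name, cls in _SECTIONS.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ValueError(f"section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, raw[name], name)
    cfg = PipelineConfig(**kwargs)
    for key in ("t1", "t2", "flair"):
        p = getattr(cfg.paths, key)
        if p and not Path(p).exists():
            raise ValueError(f"paths.{key}: file not found: {p}")
    return cfg


@dataclass
class PipelineResult:
    final_labels: LabelMap
    brain_mask: BinaryMask
    std_volume: MultichannelVolume
    parzen_t2flair: LabelMap
    parzen_t1t2: LabelMap
    initial_lesions: BinaryMask
    seeds: LabelMap
    cerebral: EMResult
    cerebellar: EMResult | None
    stage_labels: List[Tuple[str, LabelMap]]
    stage_metrics: List[Tuple[str, EvaluationReport]] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def lesion_mask(self) -> BinaryMask:
        return self.final_labels.class_mask(LESION)


def segment_case(std_volume: MultichannelVolume, brain_mask: BinaryMask,
                 atlas: AtlasMaskSet, training: pd.DataFrame,
                 config: PipelineConfig | None = None,
                 truth: LabelMap | None = None) -> PipelineResult:
    """Run classification + refinement on a standardized multichannel volume.

    ``training`` must carry class codes and standardized t1/t2/flair columns.
    When ``truth`` is given, lesion metrics are recorded after the Parzen
    stage and after every refinement stage.
    """
    config = config or PipelineConfig()
    vr = config.scale.standard_range

    fmap_t2f = t2flair_feature_map(training, bins=config.parzen.bins,
                                   h=config.parzen.bandwidth, value_range=vr)
    fmap_t1t2 = t1t2_feature_map(training, bins=config.parzen.bins,
                                 h=config.parzen.bandwidth, value_range=vr)
    parzen_t2f = classify_with_feature_map(std_volume, brain_mask, fmap_t2f)
    parzen_t1t2 = classify_with_feature_map(std_volume, brain_mask, fmap_t1t2)
    lesions0, seeds, non_lesion_brain = split_initial_classes(
        parzen_t2f, parzen_t1t2, brain_mask)

    cereb_mask = BinaryMask(atlas.cerebellum.mask & non_lesion_brain.mask,
                            brain_mask.spacing)
    cerebral_mask = BinaryMask(non_lesion_brain.mask & ~cereb_mask.mask,
                               brain_mask.spacing)

    cerebral = em_hmrf_segment(std_volume, cerebral_mask, seeds, config.hmrf,
                               channels=("t1", "t2"), classes=(CSF, GM, WM))
    cerebellar = None
    if cereb_mask.mask.any():
        cerebellar = segment_cerebellum(std_volume, cereb_mask, seeds, config.hmrf,
                                        channels=("t1", "t2"))

    cereb_labels = (cerebellar.labels if cerebellar is not None
                    else LabelMap(np.zeros(brain_mask.shape, dtype=np.int32),
                                  brain_mask.spacing))
    combined = assemble_final_labels(cerebral.labels, cereb_labels,
                                     lesions0, cereb_mask)

    final, stages = run_refinement(
        combined, std_volume.channels[config.fuzzy.channel], atlas, brain_mask,
        config.refine, config.fuzzy, collect_stages=True)

    result = PipelineResult(
        final_labels=final, brain_mask=brain_mask, std_volume=std_volume,
        parzen_t2flair=parzen_t2f, parzen_t1t2=parzen_t1t2,
        initial_lesions=lesions0, seeds=seeds, cerebral=cerebral,
        cerebellar=cerebellar, stage_labels=stages)

    if truth is not None:
        ref = truth.class_mask(LESION)
        for name, lab in stages:
            seg = lab.class_mask(LESION)
            try:
                result.stage_metrics.append(
                    (name, evaluate_lesions(ref, seg, brain_mask,
                                            mode="componentwise",
                                            connectivity=config.refine.component_connectivity)))
            except ValueError:
                pass  # e.g. empty segmentation at some stage
    return result


def preprocess_volume(volume: MultichannelVolume, config: PipelineConfig,
                      brain_mask: BinaryMask | None = None,
                      ) -> tuple[MultichannelVolume, BinaryMask]:
    """Diffusion-denoise, brain-extract (from T2) and standardize a volume."""
    if brain_mask is None:
        brain_mask = extract_brain_mask(volume.channels["t2"], volume.spacing)
    dcfg = config.diffusion
    std_channels: Dict[str, np.ndarray] = {}
    for ch in volume.channels:
        den = anisotropic_diffusion(volume.channels[ch], dcfg.iterations,
                                    dcfg.kappa, dcfg.dt)
        scale = learn_standard_scale([den], [brain_mask],
                                     config.scale.standard_range)
        std_channels[ch] = standardize_intensities(den, brain_mask, scale)
    return MultichannelVolume(std_channels, volume.spacing), brain_mask


def run_phantom_pipeline(phantom: PhantomOutput,
                         config: PipelineConfig | None = None,
                         use_truth_brain_mask: bool = True) -> PipelineResult:
    """Full pipeline on a synthetic phantom, evaluated against its truth."""
    config = config or PipelineConfig()
    t0 = time.time()
    mask0 = phantom.brain_mask if use_truth_brain_mask else None
    std_volume, brain_mask = preprocess_volume(phantom.volume, config, mask0)
    # training intensities re-sampled from the standardized grids at the
    # phantom's training voxels (one shipped feature map serves every case)
    training = sample_training_points(phantom, seed=config.seed,
                                      channels=std_volume.channels)
    result = segment_case(std_volume, brain_mask, phantom.atlas, training,
                          config, truth=phantom.truth)
    result.manifest = {
        "mslseg_version": __version__, "seed": config.seed,
        "config_hash": config.config_hash(),
        "elapsed_s": round(time.time() - t0, 2),
        "phantom_seed": phantom.spec.seed,
    }
    return result


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Disk-to-disk pipeline run; writes artifacts + manifest to out_dir."""
    t_start = time.time()
    paths = config.paths
    for key in ("t1", "t2", "flair", "cgm", "lvc", "dgm", "cerebellum", "training"):
        if not getattr(paths, key):
            raise ValueError(f"paths.{key} is required")
    out_dir = Path(paths.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    timings: Dict[str, float] = {}
    t = time.time()
    volume = read_volume({"t1": paths.t1, "t2": paths.t2, "flair": paths.flair})
    atlas = AtlasMaskSet(read_mask(paths.cgm), read_mask(paths.lvc),
                         read_mask(paths.dgm), read_mask(paths.cerebellum))
    training = pd.read_csv(paths.training)
    if "code" not in training.columns:
        code_map = {"csf": CSF, "gm": GM, "wm": WM, "lesion": LESION}
        training["code"] = training["class"].map(code_map)
    brain0 = read_mask(paths.brain_mask) if paths.brain_mask else None
    timings["load"] = time.time() - t

    t = time.time()
    std_volume, brain_mask = preprocess_volume(volume, config, brain0)
    timings["preprocess"] = time.time() - t

    truth = None
    if paths.truth:
        from .core import read_label_map
        truth = read_label_map(paths.truth)

    t = time.time()
    result = segment_case(std_volume, brain_mask, atlas, training, config, truth)
    timings["segment"] = time.time() - t

    t = time.time()
    write_mask(brain_mask, out_dir / "brain_mask.nii.gz")
    write_volume(std_volume, out_dir / "standardized")
    write_label_map(result.parzen_t2flair, out_dir / "parzen_t2flair.nii.gz")
    write_label_map(result.parzen_t1t2, out_dir / "parzen_t1t2.nii.gz")
    write_label_map(result.seeds, out_dir / "seeds.nii.gz")
    write_mask(result.initial_lesions, out_dir / "initial_lesions.nii.gz")
    for name, lab in result.stage_labels:
        write_label_map(lab, out_dir / f"refine_{name}.nii.gz")
    write_label_map(result.final_labels, out_dir / "final_labels.nii.gz")
    timings["write"] = time.time() - t

    result.manifest = {
        "mslseg_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "elapsed_s": round(time.time() - t_start, 3),
        "em_converged": result.cerebral.converged,
        "em_flags": result.cerebral.flags,
        "class_counts": result.final_labels.class_counts(),
        "stage_metrics": [(n, m.to_dict()) for n, m in result.stage_metrics],
    }
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    return result
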