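"""Pipeline configuration and stage orchestration.

A single YAML file configures every stage; unknown keys are rejected before
any work starts so a typo cannot silently fall back to a default.  Stages
communicate through files in the output directory:

    preprocessed/   whitened + margin-padded slices, offsets.json
    transforms/     pairwise_*.json (step 1), composed_*.json (step 2)
    registered/     slices warped into the frame of slice 0
    masks/          final per-slice vessel masks (+ overlays/)
    volume.tif      reconstructed voxel volume (multi-page TIFF)
    stats.json      vascular network statistics

Re-running a stage with unchanged inputs and config reproduces identical
outputs, and per-slice work parallelizes over ``workers`` without affecting
the result.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml
from joblib import Parallel, delayed

from . import image_io
from .image_io import SliceImage, VoxelVolume, read_stack, write_mask, write_volume
from .phantom import PhantomConfig, generate_phantom
from .preprocess import PreprocessConfig, preprocess_slice
from .reconstruction import ReconstructionConfig, network_stats, reconstruct
from .registration import RegistrationConfig, apply_transform, register_stack
from .segmentation import SegmentationConfig, render_overlay, segment_stack


__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("preprocess", "register", "segment", "reconstruct")


def _from_mapping(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in mapping:
            v = mapping[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    register: RegistrationConfig = field(default_factory=RegistrationConfig)
    segment: SegmentationConfig = field(default_factory=SegmentationConfig)
    reconstruct: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    workers: int = 1
    log_level: str = "INFO"
    pixel_size_um: float = image_io.DEFAULT_PIXEL_SIZE_UM
    slice_thickness_um: float = image_io.DEFAULT_SLICE_THICKNESS_UM

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        sections = {
            "preprocess": PreprocessConfig,
            "register": RegistrationConfig,
            "segment": SegmentationConfig,
            "reconstruct": ReconstructionConfig,
            "phantom": PhantomConfig,
        }
        kwargs = {}
        for name, section_cls in sections.items():
            if name in d:
                kwargs[name] = _from_mapping(section_cls, d.pop(name) or {})
        known = {"workers", "log_level", "pixel_size_um", "slice_thickness_um"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        cfg = cls(**kwargs)
        # the registration's pre-alignment shares the preprocess settings
        cfg.register.prealign = cfg.preprocess
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing input for {what}: expected {path}")
    return path


def stage_simulate(cfg: PipelineConfig, out_dir: str | Path, seed: int | None = None) -> Path:
    """Generate a phantom dataset: slices, truth masks, landmarks, transforms."""
    out = Path(out_dir)
    pcfg = cfg.phantom
    if seed is not None:
        pcfg = dataclasses.replace(pcfg, seed=seed)
    slices, truth = generate_phantom(pcfg)
    image_io.write_stack(slices, out / "slices")
    for z, (m, a) in enumerate(zip(truth.slice_masks, truth.artifact_masks)):
        write_mask(m, out / "truth_masks" / f"mask_{z:04d}.png")
        write_mask(a, out / "artifact_masks" / f"artifact_{z:04d}.png")
    write_volume(truth.volume_truth, out / "truth_volume.tif")
    for z, lm in enumerate(truth.landmarks_per_slice):
        image_io.write_landmarks(lm, out / "landmarks" / f"landmarks_{z:04d}.csv")
    image_io.write_json(
        {"transforms": [t.to_dict() for t in truth.true_transforms]},
        out / "true_transforms.json",
    )
    return out


def stage_preprocess(cfg: PipelineConfig, in_dir: str | Path, out_dir: str | Path) -> list[SliceImage]:
    src = _require(Path(in_dir), "preprocess")
    stack = read_stack(src, pixel_size_um=cfg.pixel_size_um)
    results = Parallel(n_jobs=cfg.workers)(
        delayed(preprocess_slice)(s, cfg.preprocess) for s in stack
    )
    processed = [r[0] for r in results]
    offsets = [r[1] for r in results]
    out = Path(out_dir)
    image_io.write_stack(processed, out / "preprocessed")
    image_io.write_json(
        {"offsets_xy": offsets, "original_shape": list(stack[0].shape)},
        out / "preprocessed" / "offsets.json",
    )
    return processed


def stage_register(cfg: PipelineConfig, work_dir: str | Path) -> list[SliceImage]:
    work = Path(work_dir)
    src = _require(work / "preprocessed", "register")
    stack = read_stack(src, pixel_size_um=cfg.pixel_size_um)
    transforms = register_stack(
        stack, cfg.register, workers=cfg.workers, transforms_dir=work / "transforms"
    )
    for t in transforms:
        t.save(work / "transforms" / f"composed_{t.source_index:04d}_to_0000.json")
    registered = Parallel(n_jobs=cfg.workers)(
        delayed(apply_transform)(img, t, stack[0].shape)
        for img, t in zip(stack, transforms)
    )
    image_io.write_stack(registered, work / "registered")
    return registered


def stage_segment(cfg: PipelineConfig, work_dir: str | Path) -> list[np.ndarray]:
    import imageio.v3 as iio

    work = Path(work_dir)
    src = _require(work / "registered", "segment")
    stack = read_stack(src, pixel_size_um=cfg.pixel_size_um)
    segmented = segment_stack(stack, cfg.segment, workers=cfg.workers)
    overlay_dir = work / "masks" / "overlays"
    overlay_dir.mkdir(parents=True, exist_ok=True)
    for seg in segmented:
        write_mask(seg.final, work / "masks" / f"mask_{seg.index:04d}.png")
        iio.imwrite(overlay_dir / f"overlay_{seg.index:04d}.png", render_overlay(seg))
    return [seg.final for seg in segmented]


def stage_reconstruct(cfg: PipelineConfig, work_dir: str | Path) -> VoxelVolume:
    work = Path(work_dir)
    src = _require(work / "masks", "reconstruct")
    masks = [image_io.read_mask(p) for p in sorted(src.glob("mask_*.png"))]
    if not masks:
        raise FileNotFoundError(f"missing input for reconstruct: no mask_*.png in {src}")
    spacing = (cfg.slice_thickness_um, cfg.pixel_size_um, cfg.pixel_size_um)
    volume = reconstruct(masks, spacing_um=spacing, cfg=cfg.reconstruct)
    write_volume(volume, work / "volume.tif")
    stats = network_stats(volume, cfg.reconstruct)
    image_io.write_json(
        {
            "vessel_count": stats.vessel_count,
            "z_extent_um": stats.z_extent_um,
            "min_diameter_um": stats.min_diameter_um,
            "median_diameters_um": stats.median_diameters_um,
            "total_vessel_volume_um3": stats.total_vessel_volume_um3,
        },
        work / "stats.json",
    )
    return volume


def run_pipeline(
    cfg: PipelineConfig,
    in_dir: str | Path,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> Path:
    """Run the requested stages in order; returns the output directory.

    ``in_dir`` feeds the first requested stage (a slice directory for
    ``preprocess``); later stages read the previous stage's artifacts from
    ``out_dir``.  A run log with the config digest is written alongside.
    """
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages {bad}; valid: {STAGES}")
    stages = tuple(s for s in STAGES if s in stages)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if "preprocess" in stages:
        stage_preprocess(cfg, in_dir, out)
    if "register" in stages:
        stage_register(cfg, out)
    if "segment" in stages:
        stage_segment(cfg, out)
    if "reconstruct" in stages:
        stage_reconstruct(cfg, out)

    image_io.write_json(
        {"config_digest": cfg.digest(), "stages": list(stages), "workers": cfg.workers},
        out / "run.json",
    )
    return out
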