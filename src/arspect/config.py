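"""YAML (de)serialization of the structured configuration objects.

Every spec object used by the pipeline round-trips through plain dicts,
so experiments are reproducible from a single YAML file.  Prediction
regions are named (``ortho4``, ``full3x3``) or given as explicit offset
lists.
"""

from __future__ import annotations

import pathlib

import yaml

from .armodel import ARFilterSpec, FULL3X3, ORTHO4, PredictionRegion
from .errors import ConfigurationError
from .phantom import CylinderSpec, PhantomSpec, default_3dmac
from .pipeline import ExperimentConfig
from .projector import AcquisitionSpec
from .recon import ReconConfig

__all__ = [
    "region_to_name",
    "region_from_config",
    "ar_spec_to_dict",
    "ar_spec_from_dict",
    "experiment_from_yaml",
    "experiment_to_yaml",
]


def region_to_name(region: PredictionRegion):
    if region == ORTHO4:
        return "ortho4"
    if region == FULL3X3:
        return "full3x3"
    return [list(o) for o in region.offsets]


def region_from_config(value) -> PredictionRegion:
    if isinstance(value, str):
        name = value.lower()
        if name == "ortho4":
            return ORTHO4
        if name == "full3x3":
            return FULL3X3
        raise ConfigurationError(f"unknown prediction region name {value!r}")
    return PredictionRegion(tuple(tuple(o) for o in value))


def ar_spec_to_dict(spec: ARFilterSpec) -> dict:
    return {
        "region": region_to_name(spec.region),
        "block_size": spec.block_size,
        "overlap_fraction": spec.overlap_fraction,
        "iterations": spec.iterations,
    }


def ar_spec_from_dict(d: dict) -> ARFilterSpec:
    return ARFilterSpec(
        region=region_from_config(d["region"]),
        block_size=int(d["block_size"]),
        overlap_fraction=float(d.get("overlap_fraction", 0.75)),
        iterations=int(d.get("iterations", 1)),
    )


def _cylinder_to_dict(c: CylinderSpec) -> dict:
    return {
        "center": list(c.center),
        "diameter": c.diameter,
        "length": c.length,
        "relative_activity": c.relative_activity,
    }


def _cylinder_from_dict(d: dict) -> CylinderSpec:
    return CylinderSpec(
        center=tuple(d["center"]),
        diameter=float(d["diameter"]),
        length=float(d["length"]),
        relative_activity=float(d["relative_activity"]),
    )


def phantom_to_config(spec: PhantomSpec):
    return {
        "body": _cylinder_to_dict(spec.body),
        "objects": [_cylinder_to_dict(o) for o in spec.objects],
    }


def phantom_from_config(value) -> PhantomSpec:
    if value in (None, "default"):
        return default_3dmac()
    return PhantomSpec(
        body=_cylinder_from_dict(value["body"]),
        objects=tuple(_cylinder_from_dict(o) for o in value["objects"]),
    )


def acquisition_from_dict(d: dict | None) -> AcquisitionSpec:
    d = d or {}
    return AcquisitionSpec(
        n_angles=int(d.get("n_angles", 120)),
        arc_degrees=float(d.get("arc_degrees", 360.0)),
        detector_bins=int(d.get("detector_bins", 64)),
        bin_size=float(d.get("bin_size", 4.0)),
        counts_per_projection=d.get("counts_per_projection"),
    )


def recon_from_dict(d: dict | None) -> ReconConfig:
    d = d or {}
    return ReconConfig(
        algorithm=d.get("algorithm", "OSEM"),
        osem_subsets=int(d.get("osem_subsets", 8)),
        osem_iterations=int(d.get("osem_iterations", 10)),
        butterworth_cutoff=d.get("butterworth_cutoff"),
        butterworth_order=int(d.get("butterworth_order", 2)),
        butterworth_stage=d.get("butterworth_stage", "none"),
        clamp_cutoff=bool(d.get("clamp_cutoff", False)),
    )


def experiment_from_yaml(path) -> ExperimentConfig:
    """Load an ExperimentConfig from a YAML file."""
    raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    return ExperimentConfig(
        phantom=phantom_from_config(raw.get("phantom")),
        acquisition=acquisition_from_dict(raw.get("acquisition")),
        count_levels=tuple(raw.get("count_levels", (50_000.0, 100_000.0, 150_000.0))),
        seeds=tuple(raw.get("seeds", (1,))),
        matrix=int(raw.get("matrix", 64)),
        voxel_size=float(raw.get("voxel_size", 4.0)),
        n_slices=int(raw.get("n_slices", 64)),
        cov_tolerance=float(raw.get("cov_tolerance", 0.05)),
        output_dir=raw.get("output_dir"),
    )


def experiment_to_yaml(config: ExperimentConfig, path) -> None:
    """Write an ExperimentConfig to YAML (phantom serialized explicitly)."""
    g = config.acquisition
    doc = {
        "phantom": phantom_to_config(config.phantom),
        "acquisition": {
            "n_angles": g.n_angles,
            "arc_degrees": g.arc_degrees,
            "detector_bins": g.detector_bins,
            "bin_size": g.bin_size,
        },
        "count_levels": list(config.count_levels),
        "seeds": list(config.seeds),
        "matrix": config.matrix,
        "voxel_size": config.voxel_size,
        "n_slices": config.n_slices,
        "cov_tolerance": config.cov_tolerance,
        "output_dir": config.output_dir,
    }
    pathlib.Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
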