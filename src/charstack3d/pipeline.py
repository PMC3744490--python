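"""End-to-end pipeline: segment → mesh → measure → summarize, with a run
manifest so every reported number is traceable to the inputs, the config
and the thresholds actually used."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .assemblage import (
    AssemblageSummary,
    estimate_total_volume,
    size_sorting,
    summarize,
)
from .morphometrics import ParticleMorphometrics, measure_particle
from .segmentation import (
    LabelVolume,
    binarize,
    filter_particles,
    label_particles,
    select_n_particles,
    suppress_bottom_reflection,
)
from .stack_io import (
    AnalysisConfig,
    DataError,
    IntensityStack,
    read_stack,
    write_mesh,
    write_morphometrics_table,
)
from .surface_reconstruction import extract_surface, mesh_statistics


@dataclass
class StageLog:
    """Particle counts through the filtering stages of one sample."""

    sample_id: str
    threshold_used: float | None
    n_labeled: int
    n_after_filter: int
    n_selected: int


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline invocation."""

    version: str
    config_hash: str
    config: dict
    inputs: dict[str, str]  # path -> sha256
    stages: list[StageLog] = field(default_factory=list)
    timestamp: str = ""

    def to_json(self, path: Path) -> None:
        doc = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _config_dict(config: AnalysisConfig) -> dict:
    d = dataclasses.asdict(config)
    d["spacing"] = dataclasses.asdict(config.spacing)
    return d


def _config_hash(config: AnalysisConfig) -> str:
    canon = yaml.safe_dump(_config_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def segment_stack(stack: IntensityStack, config: AnalysisConfig) -> LabelVolume:
    """Threshold, de-artifact, label, filter and (optionally) cap a stack."""
    mask = binarize(stack, config.threshold)
    if config.bottom_reflection_slices:
        mask = suppress_bottom_reflection(mask, config.bottom_reflection_slices)
    labels = label_particles(mask, config.connectivity)
    labels = filter_particles(
        labels,
        min_voxels=config.min_voxels,
        min_projected_area=config.min_projected_area,
        border_policy=config.border_policy,
    )
    if config.select_n is not None:
        labels = select_n_particles(labels, config.select_n)
    return labels


def measure_stack(
    labels: LabelVolume, config: AnalysisConfig
) -> list[ParticleMorphometrics]:
    """Mesh and measure every labeled particle."""
    records = []
    for pid in labels.labels():
        mesh = extract_surface(labels, pid)
        stats = mesh_statistics(mesh)
        records.append(
            measure_particle(labels, pid, stats, shape_tolerance=config.shape_tolerance)
        )
    return records


def _summary_dict(s: AssemblageSummary, records) -> dict:
    d = dataclasses.asdict(s)
    sorting = size_sorting(records) if s.n >= 2 else None
    d["size_sorting"] = dataclasses.asdict(sorting) if sorting else None
    return d


def compare_samples(samples: list[dict]) -> dict:
    """Count vs total-volume comparison across >= 2 samples.

    Each entry needs ``sample_id``, ``particle_count`` (slide count) and
    ``median_volume_um3``. The report gives both orderings, all pairwise
    total-volume ratios, and flags when counting and volumetry rank the
    samples differently — the failure mode of count-only fire proxies
    under differential fragmentation.
    """
    if len(samples) < 2:
        raise DataError("compare_samples needs at least two samples")
    rows = []
    for s in samples:
        est = estimate_total_volume(int(s["particle_count"]), float(s["median_volume_um3"]))
        rows.append(
            {
                "sample_id": s["sample_id"],
                "particle_count": est.particle_count,
                "median_volume_mm3": est.median_particle_volume,
                "estimated_total_mm3": est.estimated_total,
            }
        )
    by_count = sorted(rows, key=lambda r: r["particle_count"], reverse=True)
    by_volume = sorted(rows, key=lambda r: r["estimated_total_mm3"], reverse=True)
    count_order = [r["sample_id"] for r in by_count]
    volume_order = [r["sample_id"] for r in by_volume]
    ratios = {}
    for i, ri in enumerate(rows):
        for rj in rows[i + 1 :]:
            hi, lo = ri, rj
            if rj["estimated_total_mm3"] > ri["estimated_total_mm3"]:
                hi, lo = rj, ri
            key = f"{hi['sample_id']}/{lo['sample_id']}"
            ratios[key] = hi["estimated_total_mm3"] / lo["estimated_total_mm3"]
    return {
        "samples": rows,
        "count_order": count_order,
        "total_volume_order": volume_order,
        "ordering_reversed": count_order != volume_order,
        "total_volume_ratios": {k: round(v, 4) for k, v in ratios.items()},
    }


def run_pipeline(
    stack_paths: list,
    config: AnalysisConfig,
    out_dir,
    slide_counts: dict[str, int] | None = None,
    meshes: bool = False,
) -> dict:
    """Run segment → mesh → measure → summarize over one or more stacks.

    Writes ``particles_<sample>.csv`` per stack, a combined
    ``summary.json``, optional per-particle meshes, and ``manifest.json``.
    ``slide_counts`` optionally maps sample ids to whole-slide particle
    counts for total-volume estimation (defaults to the measured count).
    Outputs are deterministic for identical inputs and config (the
    manifest carries the only timestamp).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config_hash=_config_hash(config),
        config=_config_dict(config),
        inputs={str(p): _sha256(p) for p in stack_paths},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    summary_doc: dict = {"samples": {}}
    per_sample = []
    for path in stack_paths:
        path = Path(path)
        sample_id = path.stem
        stack = read_stack(path, config.spacing)
        mask = binarize(stack, config.threshold)
        if config.bottom_reflection_slices:
            mask = suppress_bottom_reflection(mask, config.bottom_reflection_slices)
        labels = label_particles(mask, config.connectivity)
        n_labeled = labels.n_particles
        labels = filter_particles(
            labels,
            min_voxels=config.min_voxels,
            min_projected_area=config.min_projected_area,
            border_policy=config.border_policy,
        )
        n_filtered = labels.n_particles
        if config.select_n is not None:
            labels = select_n_particles(labels, config.select_n)
        if labels.n_particles == 0:
            raise DataError(f"stage segmentation: no particles found in {path.name}")
        records = measure_stack(labels, config)
        write_morphometrics_table(records, out_dir / f"particles_{sample_id}.csv")
        if meshes:
            mesh_dir = out_dir / "meshes"
            mesh_dir.mkdir(exist_ok=True)
            for pid in labels.labels():
                write_mesh(
                    extract_surface(labels, pid),
                    mesh_dir / f"{sample_id}_particle_{pid:04d}.obj",
                )
        summary = summarize(records, sample_id, area_metric=config.area_metric)
        count = (slide_counts or {}).get(sample_id, summary.n)
        est = estimate_total_volume(count, summary.median_volume)
        est_mean = estimate_total_volume(count, summary.mean_volume)
        manifest.stages.append(
            StageLog(
                sample_id=sample_id,
                threshold_used=mask.threshold_used,
                n_labeled=n_labeled,
                n_after_filter=n_filtered,
                n_selected=labels.n_particles,
            )
        )
        summary_doc["samples"][sample_id] = {
            **_summary_dict(summary, records),
            "total_volume": {
                "particle_count": est.particle_count,
                "median_volume_mm3": est.median_particle_volume,
                "estimated_total_mm3": est.estimated_total,
                "estimated_total_mm3_mean_based": est_mean.estimated_total,
            },
        }
        per_sample.append(
            {
                "sample_id": sample_id,
                "particle_count": count,
                "median_volume_um3": summary.median_volume,
            }
        )
    if len(per_sample) >= 2:
        summary_doc["comparison"] = compare_samples(per_sample)
    (out_dir / "summary.json").write_text(
        json.dumps(summary_doc, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    manifest.to_json(out_dir / "manifest.json")
    return summary_doc


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
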