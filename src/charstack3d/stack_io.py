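"""Image-stack, table and configuration I/O with explicit physical units.

Conventions used throughout the package:

* voxel grids are indexed ``(z, y, x)``, 0-based;
* physical coordinates are in micrometres (µm), computed as
  ``index * spacing`` with a voxel-*center* convention;
* per-particle quantities are reported in µm³ / µm², assemblage totals
  in mm³ (1 mm³ = 1e9 µm³).

Voxel spacing is always supplied explicitly (from configuration or one of
the acquisition presets below); vendor TIFF metadata is never parsed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile
import yaml


class ConfigError(ValueError):
    """Invalid or inconsistent analysis configuration."""


class DataError(ValueError):
    """Invalid input data (missing file, wrong layout, bad values)."""


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical edge lengths of one voxel, in µm.

    ``dz != dx`` (anisotropy) is the normal case for confocal stacks and is
    preserved through every downstream computation.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"spacing.{name} must be strictly positive, got {v!r}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.dx * self.dy * self.dz

    def as_zyx(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)


#: Acquisition preset for the 10x reflectance mode used on mesofossil
#: (>150 µm sieve fraction) slides.
MESOFOSSIL_SPACING = VoxelSpacing(dx=2.768, dy=2.768, dz=5.00)

#: Acquisition preset for the 20x reflectance mode used on microfossil
#: (palynological) slides.
MICROFOSSIL_SPACING = VoxelSpacing(dx=0.526, dy=0.526, dz=1.060)


@dataclass
class IntensityStack:
    """A 3D grayscale reflectance volume with physical spacing.

    ``voxels`` is ``(z, y, x)``; slice 0 is the shallowest focal plane and
    the last slice the deepest (closest to the slide).
    """

    voxels: np.ndarray
    spacing: VoxelSpacing
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise DataError(f"stack must be 3D (z, y, x), got shape {self.voxels.shape}")
        vmax = 2**self.bit_depth - 1
        if self.voxels.size and (self.voxels.min() < 0 or self.voxels.max() > vmax):
            raise DataError(
                f"intensities outside [0, {vmax}] for bit depth {self.bit_depth}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


_CONNECTIVITIES = (6, 18, 26)
_BORDER_POLICIES = ("keep", "drop", "flag")


@dataclass
class AnalysisConfig:
    """Parameters controlling the segmentation → morphometry pipeline.

    Defaults follow the reflectance-confocal charcoal workflow: automatic
    (two-class inter-class-variance) thresholding, diagonal-inclusive
    26-connectivity, minimum-size noise filtering, border particles kept
    but flagged, and an area→volume conversion factor of 13.
    """

    spacing: VoxelSpacing = field(default_factory=lambda: MESOFOSSIL_SPACING)
    threshold: Union[str, float] = "auto"  # "auto" or a fixed intensity
    min_voxels: int = 10
    min_projected_area: float = 0.0  # µm²
    connectivity: int = 26
    border_policy: str = "flag"
    bottom_reflection_slices: int = 0
    conversion_factor: float = 13.0  # µm³ volume per µm² area
    select_n: int | None = None  # raster-order particle cap, None = all
    shape_tolerance: float = 0.2  # relative tol for sphere/oblate/prolate classes
    area_metric: str = "surface_area"  # assemblage area statistic source

    def __post_init__(self) -> None:
        if self.min_voxels < 0:
            raise ConfigError(f"min_voxels must be >= 0, got {self.min_voxels}")
        if self.min_projected_area < 0:
            raise ConfigError("min_projected_area must be >= 0")
        if self.connectivity not in _CONNECTIVITIES:
            raise ConfigError(
                f"connectivity must be one of {_CONNECTIVITIES}, got {self.connectivity}"
            )
        if self.border_policy not in _BORDER_POLICIES:
            raise ConfigError(
                f"border_policy must be one of {_BORDER_POLICIES}, got {self.border_policy!r}"
            )
        if self.bottom_reflection_slices < 0:
            raise ConfigError("bottom_reflection_slices must be >= 0")
        if self.conversion_factor <= 0:
            raise ConfigError("conversion_factor must be > 0")
        if not (0 < self.shape_tolerance < 1):
            raise ConfigError("shape_tolerance must be in (0, 1)")
        if self.area_metric not in ("surface_area", "projected_area"):
            raise ConfigError("area_metric must be 'surface_area' or 'projected_area'")
        if isinstance(self.threshold, str) and self.threshold != "auto":
            try:
                self.threshold = float(self.threshold)
            except ValueError:
                raise ConfigError(
                    f"threshold must be 'auto' or a number, got {self.threshold!r}"
                ) from None


def load_config(path: Union[str, Path]) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML.

    Absent fields take the documented defaults; unknown keys raise a
    warning (not an error) so configs stay forward compatible.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    doc = yaml.safe_load(path.read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> AnalysisConfig:
    doc = dict(doc)
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(doc) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2)
        for k in unknown:
            doc.pop(k)
    if "spacing" in doc and doc["spacing"] is not None:
        sp = doc["spacing"]
        if isinstance(sp, dict):
            extra = set(sp) - {"dx", "dy", "dz"}
            if extra:
                raise ConfigError(f"unknown spacing keys: {sorted(extra)}")
            doc["spacing"] = VoxelSpacing(**{k: float(v) for k, v in sp.items()})
        elif isinstance(sp, (list, tuple)) and len(sp) == 3:
            doc["spacing"] = VoxelSpacing(*map(float, sp))
        elif not isinstance(sp, VoxelSpacing):
            raise ConfigError(f"spacing must be a dx/dy/dz mapping, got {sp!r}")
    return AnalysisConfig(**doc)


def read_stack(
    path: Union[str, Path],
    spacing: VoxelSpacing,
    bit_depth: int | None = None,
) -> IntensityStack:
    """Read a multi-page grayscale TIFF as an :class:`IntensityStack`.

    The slice count equals the page count; intensities are passed through
    without rescaling. Spacing is attached from the argument, never parsed
    from vendor tags.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"stack file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        if "S" in series.axes or "C" in series.axes:
            raise DataError(
                f"{path.name}: multi-channel/RGB pages are not supported; "
                "provide a single reflectance channel"
            )
        arr = series.asarray()
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise DataError(f"{path.name}: expected 2D/3D grayscale data, got shape {arr.shape}")
    if bit_depth is None:
        bit_depth = 8 * arr.dtype.itemsize if arr.dtype.kind == "u" else 16
    return IntensityStack(voxels=arr, spacing=spacing, bit_depth=bit_depth)


def write_stack(stack: IntensityStack, path: Union[str, Path]) -> None:
    """Write a stack as an uncompressed multi-page grayscale TIFF."""
    tifffile.imwrite(Path(path), np.asarray(stack.voxels), photometric="minisblack")


# ---------------------------------------------------------------------------
# morphometrics tables

#: Stable column order of the per-particle table; units are embedded in the
#: column names so the header documents them.
MORPHOMETRICS_COLUMNS = [
    "particle_id",
    "volume_um3",
    "surface_area_um2",
    "projected_area_um2",
    "n_triangles",
    "bbox_length_um",
    "bbox_width_um",
    "bbox_depth_um",
    "manual_volume_um3",
    "semi_axis_a_um",
    "semi_axis_b_um",
    "semi_axis_c_um",
    "shape_class",
    "circularity",
    "aspect_ratio",
    "border_flag",
]


def write_morphometrics_table(records: list, path: Union[str, Path]) -> None:
    """Write per-particle records as CSV, one row per particle.

    An empty record list yields a header-only file.
    """
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=MORPHOMETRICS_COLUMNS)
    df.to_csv(Path(path), index=False)


def read_morphometrics_table(path: Union[str, Path]) -> list:
    """Read a morphometrics CSV back into ParticleMorphometrics records."""
    from .morphometrics import ParticleMorphometrics

    path = Path(path)
    if not path.exists():
        raise DataError(f"table not found: {path}")
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(ParticleMorphometrics(**d))
    return records


# ---------------------------------------------------------------------------
# meshes


def write_mesh(mesh, path: Union[str, Path], fmt: str | None = None) -> None:
    """Write a triangle mesh as ASCII OBJ or PLY (inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=int)
    if fmt == "obj":
        lines = [f"# particle {mesh.particle_id}; vertex units: um"]
        lines += [f"v {x:.6f} {y:.6f} {z:.6f}" for x, y, z in v]
        lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in f]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "ply":
        header = [
            "ply",
            "format ascii 1.0",
            f"comment particle {mesh.particle_id}; vertex units: um",
            f"element vertex {len(v)}",
            "property float x",
            "property float y",
            "property float z",
            f"element face {len(f)}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        body = [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in v]
        body += [f"3 {a} {b} {c}" for a, b, c in f]
        path.write_text("\n".join(header + body) + "\n")
    else:
        raise ConfigError(f"unsupported mesh format {fmt!r}; use 'obj' or 'ply'")
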