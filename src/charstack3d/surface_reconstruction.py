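"""Per-particle triangle surfaces and their statistics.

Each labeled particle is turned into a closed ("watertight") triangle mesh
by marching-cubes isosurface extraction at level 0.5 on its binary
indicator field, computed on the *physical* (anisotropic) grid so that one
z-step contributes dz µm, not one unit. A one-voxel zero padding around
the particle guarantees closure even when the particle touches a stack
face or consists of a single voxel.

Surface statistics are the triangle count, the total triangle area, and
the enclosed volume via the divergence theorem (sum of signed tetrahedra
against the origin). The voxel-count × voxel-volume product is retained as
an independent volume oracle; the two estimators agree to within a few
percent for particles larger than ~100 voxels and converge as particles
grow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from .segmentation import LabelVolume
from .stack_io import DataError


@dataclass
class TriangleMesh:
    """Closed, consistently outward-oriented triangle surface in µm."""

    vertices: np.ndarray  # (N, 3) float, (x, y, z) µm
    faces: np.ndarray  # (M, 3) int vertex indices
    particle_id: int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DataError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise DataError("faces must be (M, 3)")


@dataclass(frozen=True)
class SurfaceStatistics:
    """Mesh summary: triangle count, total area (µm²), enclosed volume (µm³)."""

    n_triangles: int
    surface_area: float
    enclosed_volume: float


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def _triangle_area_sum(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    return float(0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1).sum())


def count_open_edges(faces: np.ndarray) -> int:
    """Number of undirected edges not shared by exactly two triangles."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int((counts != 2).sum())


def extract_surface(
    labels: LabelVolume, particle_id: int, smoothing_sigma: float = 0.0
) -> TriangleMesh:
    """Marching-cubes surface of one particle, in µm coordinates.

    ``smoothing_sigma`` > 0 applies a light Gaussian to the indicator field
    (in voxel units) before extraction; the default 0 extracts directly
    from the binary field. The mesh is oriented so that its enclosed
    (signed) volume is positive.
    """
    labels._check(particle_id)
    sl = labels.object_slices()[particle_id - 1]
    if sl is None:
        raise KeyError(f"particle {particle_id} has no voxels")
    binary = labels.voxels[sl] == particle_id
    field = np.pad(binary, 1).astype(np.float32)
    if smoothing_sigma > 0:
        field = ndimage.gaussian_filter(field, smoothing_sigma)
    dz, dy, dx = labels.spacing.as_zyx()
    verts, faces, _, _ = marching_cubes(field, level=0.5, spacing=(dz, dy, dx))
    # verts are (z, y, x) physical offsets within the padded crop; shift to
    # absolute stack coordinates (voxel-center convention) and flip to xyz.
    origin = np.array(
        [
            (sl[0].start - 1) * dz,
            (sl[1].start - 1) * dy,
            (sl[2].start - 1) * dx,
        ]
    )
    verts = verts + origin
    verts = verts[:, ::-1]  # (z, y, x) -> (x, y, z)
    if _signed_volume(verts, faces) < 0:
        faces = faces[:, ::-1]
    return TriangleMesh(vertices=verts, faces=faces, particle_id=particle_id)


def mesh_statistics(mesh: TriangleMesh) -> SurfaceStatistics:
    """Triangle count, total surface area, and divergence-theorem volume.

    Rejects non-watertight meshes: both quantities are only meaningful for
    a closed surface.
    """
    open_edges = count_open_edges(mesh.faces)
    if open_edges:
        raise DataError(
            f"mesh for particle {mesh.particle_id} is not watertight: "
            f"{open_edges} open edge(s)"
        )
    return SurfaceStatistics(
        n_triangles=int(len(mesh.faces)),
        surface_area=_triangle_area_sum(mesh.vertices, mesh.faces),
        enclosed_volume=abs(_signed_volume(mesh.vertices, mesh.faces)),
    )


def voxel_volume_oracle(labels: LabelVolume, particle_id: int) -> float:
    """Independent volume estimate: voxel count × (dx·dy·dz) in µm³."""
    count = labels.voxel_count(particle_id)
    if count == 0:
        raise KeyError(f"particle {particle_id} has no voxels (filtered out?)")
    return count * labels.spacing.voxel_volume
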