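"""Threshold, filter and label charcoal particles in a reflectance stack.

Charcoal is opaque and highly reflective, so under reflected laser light
particles appear bright on a dark background; a single intensity threshold
separates the two classes. "Smoothing" here means minimum-size removal of
speckle objects, not blurring. Labeling discovers connected components in
deterministic raster-scan order so that particle identities are stable
across runs and selection of the first *n* particles mimics an unbiased
top-left-to-bottom-right transect of the slide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .stack_io import DataError, IntensityStack, VoxelSpacing

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class BinaryMask:
    """Boolean particle/background field with the source stack's spacing."""

    voxels: np.ndarray
    spacing: VoxelSpacing
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise DataError(f"mask must be 3D, got shape {self.voxels.shape}")


@dataclass
class LabelVolume:
    """Integer-labeled particle field; 0 = background, labels 1..n_particles.

    ``border_flags[i]`` is True when particle ``i + 1`` touches any face of
    the stack (and may therefore be truncated by the field of view).
    """

    voxels: np.ndarray
    spacing: VoxelSpacing
    n_particles: int
    border_flags: np.ndarray
    connectivity: int = 26
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.border_flags = np.asarray(self.border_flags, dtype=bool)
        if self.voxels.ndim != 3:
            raise DataError(f"label volume must be 3D, got shape {self.voxels.shape}")
        if len(self.border_flags) != self.n_particles:
            raise DataError("border_flags length must equal n_particles")

    def labels(self) -> range:
        return range(1, self.n_particles + 1)

    def object_slices(self) -> list:
        """Bounding-box slices per label (cached; index = label - 1)."""
        cached = self.metadata.get("_object_slices")
        if cached is None or len(cached) != self.n_particles:
            cached = ndimage.find_objects(self.voxels, max_label=self.n_particles)
            self.metadata["_object_slices"] = cached
        return cached

    def crop(self, particle_id: int) -> np.ndarray:
        """Boolean indicator of one particle within its bounding box."""
        self._check(particle_id)
        sl = self.object_slices()[particle_id - 1]
        if sl is None:
            raise KeyError(f"particle {particle_id} has no voxels (filtered out?)")
        return self.voxels[sl] == particle_id

    def voxel_count(self, particle_id: int) -> int:
        return int(self.crop(particle_id).sum())

    def _check(self, particle_id: int) -> None:
        if not 1 <= particle_id <= self.n_particles:
            raise KeyError(
                f"particle {particle_id} not in label volume (1..{self.n_particles})"
            )


def binarize(stack: IntensityStack, threshold_spec: str | float = "auto") -> BinaryMask:
    """Threshold a reflectance stack: voxel is foreground iff intensity >= t.

    ``threshold_spec="auto"`` computes the two-class inter-class-variance
    (Otsu) split of the intensity histogram and records the value used in
    ``BinaryMask.threshold_used``; the split assigns background <= t <
    foreground. Automatic mode fails explicitly on a constant-intensity
    stack, where no two-class split exists.
    """
    v = np.asarray(stack.voxels)
    if isinstance(threshold_spec, str):
        if threshold_spec != "auto":
            raise DataError(f"unknown threshold spec {threshold_spec!r}")
        if v.max() == v.min():
            raise DataError(
                "automatic threshold failed: constant-intensity stack "
                f"(all voxels = {v.flat[0]})"
            )
        t = float(threshold_otsu(v))
        mask = v > t
    else:
        t = float(threshold_spec)
        mask = v >= t
    return BinaryMask(voxels=mask, spacing=stack.spacing, threshold_used=t)


def suppress_bottom_reflection(mask: BinaryMask, n_slices: int) -> BinaryMask:
    """Zero out the ``n_slices`` deepest z-planes of the mask.

    Light reflecting back off the slide can paint a spurious bright sheet
    across the deepest focal plane(s) of very thick particles; deleting
    those planes removes the artifact without touching anything above.
    """
    depth = mask.voxels.shape[0]
    if n_slices < 0:
        raise DataError("n_slices must be >= 0")
    if n_slices >= depth:
        raise DataError(f"cannot drop {n_slices} slices from a {depth}-slice stack")
    out = mask.voxels.copy()
    if n_slices:
        out[depth - n_slices :] = False
    return BinaryMask(voxels=out, spacing=mask.spacing, threshold_used=mask.threshold_used)


def _raster_relabel(lab: np.ndarray, n: int) -> np.ndarray:
    """Renumber labels 1..n by raster order of each label's first voxel."""
    if n == 0:
        return lab
    flat = lab.ravel()
    values, first_idx = np.unique(flat, return_index=True)
    keep = values > 0
    values, first_idx = values[keep], first_idx[keep]
    order = np.argsort(first_idx, kind="stable")
    lut = np.zeros(n + 1, dtype=lab.dtype)
    lut[values[order]] = np.arange(1, len(values) + 1, dtype=lab.dtype)
    return lut[lab]


def _border_flags(lab: np.ndarray, n: int) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    if n == 0:
        return flags
    faces = [lab[0], lab[-1], lab[:, 0], lab[:, -1], lab[:, :, 0], lab[:, :, -1]]
    touching = np.unique(np.concatenate([f.ravel() for f in faces]))
    touching = touching[touching > 0]
    flags[touching - 1] = True
    return flags


def label_particles(mask: BinaryMask, connectivity: int = 26) -> LabelVolume:
    """Connected-component labeling under 6/18/26 3D connectivity.

    Components are numbered 1..n in raster-scan (z, then y, then x) order
    of their first-encountered voxel, independent of how the underlying
    labeling pass traverses the volume.
    """
    if connectivity not in _STRUCTURES:
        raise DataError(f"connectivity must be one of (6, 18, 26), got {connectivity}")
    lab, n = ndimage.label(mask.voxels, structure=_STRUCTURES[connectivity])
    lab = _raster_relabel(lab.astype(np.int32), n)
    return LabelVolume(
        voxels=lab,
        spacing=mask.spacing,
        n_particles=int(n),
        border_flags=_border_flags(lab, n),
        connectivity=connectivity,
        metadata={"threshold_used": mask.threshold_used},
    )


def _projected_area_voxels(lab: np.ndarray, slices_by_label: list, particle_id: int) -> int:
    sl = slices_by_label[particle_id - 1]
    if sl is None:
        return 0
    crop = lab[sl] == particle_id
    return int(crop.any(axis=0).sum())


def filter_particles(
    labels: LabelVolume,
    min_voxels: int = 0,
    min_projected_area: float = 0.0,
    border_policy: str = "flag",
) -> LabelVolume:
    """Remove noise objects and apply the border policy.

    Components with fewer than ``min_voxels`` voxels or an x–y projected
    area below ``min_projected_area`` (µm²) are removed; no upper size
    limit is ever applied. Survivors are renumbered consecutively in their
    original (raster) order. Border components are kept (``keep``),
    removed (``drop``) or kept-and-flagged (``flag``).
    """
    if border_policy not in ("keep", "drop", "flag"):
        raise DataError(f"unknown border_policy {border_policy!r}")
    lab, n = labels.voxels, labels.n_particles
    if n == 0:
        return labels
    counts = np.bincount(lab.ravel(), minlength=n + 1)
    keep = counts[1:] >= max(min_voxels, 0)
    if min_projected_area > 0:
        dxdy = labels.spacing.dx * labels.spacing.dy
        slices = ndimage.find_objects(lab, max_label=n)
        for pid in range(1, n + 1):
            if keep[pid - 1]:
                area = _projected_area_voxels(lab, slices, pid) * dxdy
                if area < min_projected_area:
                    keep[pid - 1] = False
    if border_policy == "drop":
        keep &= ~labels.border_flags
    old_ids = np.flatnonzero(keep) + 1
    lut = np.zeros(n + 1, dtype=lab.dtype)
    lut[old_ids] = np.arange(1, len(old_ids) + 1, dtype=lab.dtype)
    new_lab = lut[lab]
    new_flags = labels.border_flags[old_ids - 1]
    if border_policy == "keep":
        new_flags = np.zeros(len(old_ids), dtype=bool)
    meta = dict(labels.metadata)
    meta.pop("_object_slices", None)
    meta["removed_by_filter"] = int(n - len(old_ids))
    return LabelVolume(
        voxels=new_lab,
        spacing=labels.spacing,
        n_particles=int(len(old_ids)),
        border_flags=new_flags,
        connectivity=labels.connectivity,
        metadata=meta,
    )


def select_n_particles(labels: LabelVolume, n: int) -> LabelVolume:
    """Retain the first ``n`` particles in raster order.

    This is the deterministic stand-in for imaging every particle met on a
    left-to-right transect until a fixed count (100 in the original
    workflow) is reached. If fewer than ``n`` particles exist, all are
    retained and ``metadata['selection_shortfall']`` records the deficit.
    """
    if n < 1:
        raise DataError(f"n must be >= 1, got {n}")
    total = labels.n_particles
    kept = min(n, total)
    lab = labels.voxels.copy()
    lab[lab > kept] = 0
    meta = dict(labels.metadata)
    meta.pop("_object_slices", None)
    meta["selection_shortfall"] = max(0, n - total)
    meta["selected_n"] = kept
    return LabelVolume(
        voxels=lab,
        spacing=labels.spacing,
        n_particles=kept,
        border_flags=labels.border_flags[:kept],
        connectivity=labels.connectivity,
        metadata=meta,
    )
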