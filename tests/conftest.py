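"""Shared fixtures: small rendered stacks and published reference values."""

from __future__ import annotations

import numpy as np
import pytest

import charstack3d as cs

# ---------------------------------------------------------------------------
# Published reference measurements for slide-mounted charcoal assemblages
# (modern Miombo-woodland micro/mesofossil fractions and a Cretaceous
# mesofossil fraction), used as fixed numeric inputs.

# manual (L·W·D) vs rendered volume for large bonfire fragments, mm³
BONFIRE_VOLUMES_MM3 = {
    "A": {"rendered": 0.0132, "manual": 0.0326, "factor": 2.47},
    "B1": {"rendered": 0.0138, "manual": 0.0385, "factor": 2.79},
    "B2": {"rendered": 0.00369, "manual": 0.0117, "factor": 3.17},
    "C1": {"rendered": 0.0460, "manual": 0.180, "factor": 3.91},
    "C2": {"rendered": 0.0361, "manual": 0.0862, "factor": 2.39},
}

# per-sample descriptive statistics (µm³ / µm²)
ASSEMBLAGE_STATS = {
    "modern_microfossil": {"mean_volume": 143661, "median_volume": 125579,
                           "median_area": 35225},
    "modern_mesofossil": {"mean_volume": 8018072, "median_volume": 6313344,
                          "median_area": 478260},
    "cretaceous_mesofossil": {"mean_volume": 1660692, "median_volume": 1227426,
                              "median_area": 132949},
}

# whole-slide particle counts and the published total-volume estimates (mm³)
SLIDE_TOTALS = {
    "cretaceous_mesofossil": {"count": 216, "median_volume_um3": 1227426,
                              "total_mm3": 0.2651},
    "modern_mesofossil": {"count": 142, "median_volume_um3": 6313344,
                          "total_mm3": 0.8965},
}


def render_single(
    semi_axes,
    spacing=None,
    angle=0.0,
    pad_xy=6,
    pad_z=4,
    intensity=200,
):
    """One ellipsoid centred in its own minimal stack; returns a LabelVolume."""
    sp = spacing or cs.VoxelSpacing(1.0, 1.0, 1.0)
    a, b, c = semi_axes
    half_xy = a + b  # loose bound on any in-plane rotation
    nx = int(2 * half_xy / sp.dx) + 2 * pad_xy
    ny = int(2 * half_xy / sp.dy) + 2 * pad_xy
    nz = int(2 * c / sp.dz) + 2 * pad_z
    vox = np.zeros((nz, ny, nx), dtype=np.uint8)
    center = ((nx // 2) * sp.dx, (ny // 2) * sp.dy, (nz // 2) * sp.dz)
    cs.render_ellipsoid(vox, sp, center, (a, b, c), angle, intensity)
    stack = cs.IntensityStack(vox, sp, 8)
    return cs.label_particles(cs.binarize(stack, intensity // 2))


def block_mask(shape, blocks, spacing=None):
    """Boolean mask with the given (zslice, yslice, xslice) blocks set."""
    sp = spacing or cs.VoxelSpacing(1.0, 1.0, 1.0)
    vox = np.zeros(shape, dtype=bool)
    for sl in blocks:
        vox[sl] = True
    return cs.BinaryMask(vox, sp)


@pytest.fixture(scope="session")
def sphere_labels():
    """Digitized sphere, r = 15 voxels, isotropic unit spacing."""
    return render_single((15, 15, 15))


@pytest.fixture(scope="session")
def small_assemblage():
    """A 12-particle synthetic assemblage at mesofossil spacing (fast)."""
    params = cs.GeneratorParams(
        shape=(30, 560, 560),
        n_particles=12,
        median_volume_um3=8e5,
        sigma_log=0.5,
        seed=11,
    )
    stack, truth = cs.generate_assemblage(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def measured_small_assemblage(small_assemblage):
    params, stack, truth = small_assemblage
    cfg = cs.AnalysisConfig()
    labels = cs.segment_stack(stack, cfg)
    records = cs.measure_stack(labels, cfg)
    return params, labels, records, truth


def match_truth(labels, truth, spacing):
    """Map each ground-truth particle to its measured label via its center."""
    pids = []
    for t in truth:
        iz = int(round(t.center_z_um / spacing.dz))
        iy = int(round(t.center_y_um / spacing.dy))
        ix = int(round(t.center_x_um / spacing.dx))
        pid = int(labels.voxels[iz, iy, ix])
        assert pid > 0, "truth center fell on background"
        pids.append(pid)
    return pids
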