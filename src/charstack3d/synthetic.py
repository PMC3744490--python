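"""Ground-truthed synthetic reflectance stacks.

No raw confocal charcoal stacks are publicly deposited, so validation
rests on synthetic assemblages that emulate the relevant physics of a
slide: sparse, bright, predominantly oblate particles on a dark
background, rendered into an anisotropic voxel grid of limited axial
depth (slides run roughly 40–215 µm thick). Particles are smooth solid
ellipsoids — sufficient for validating volume/area/shape estimators,
though real charcoal is angular and fractured (a stated fidelity limit).

Defaults reproduce the mesofossil acquisition mode: voxel spacing
(2.768, 2.768, 5.0) µm, a 150 µm-deep stack, 100 particles per
assemblage with lognormal volumes (median 1.2×10⁶ µm³, σ_log 0.8) and
oblate axis ratios, flakes lying flat with random in-plane orientation,
foreground/background intensities 200/10 at 8 bits with Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .stack_io import DataError, IntensityStack, MESOFOSSIL_SPACING, VoxelSpacing

THOMSEN_P = 1.6075


def thomsen_surface_area(a: float, b: float, c: float) -> float:
    """Approximate ellipsoid surface area (max error ≈ 1.06%)."""
    p = THOMSEN_P
    term = (a**p * b**p + a**p * c**p + b**p * c**p) / 3.0
    return 4.0 * math.pi * term ** (1.0 / p)


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    return 4.0 / 3.0 * math.pi * a * b * c


@dataclass(frozen=True)
class GeneratorParams:
    """Conditions for one synthetic assemblage; all lengths in µm."""

    shape: tuple[int, int, int] = (30, 1600, 1600)  # (z, y, x) voxels
    spacing: VoxelSpacing = field(default_factory=lambda: MESOFOSSIL_SPACING)
    n_particles: int = 100
    median_volume_um3: float = 1.2e6
    sigma_log: float = 0.8
    b_over_a: tuple[float, float] = (0.82, 0.98)
    c_over_b: tuple[float, float] = (0.2, 0.5)
    orientation: str = "random_z"  # flakes lie flat; rotate about z only
    foreground: float = 200.0
    background: float = 10.0
    noise_sd: float = 5.0
    bottom_reflection: bool = False
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise DataError("n_particles must be >= 0")
        if self.orientation not in ("random_z", "axis_aligned"):
            raise DataError(f"unknown orientation {self.orientation!r}")
        if self.sigma_log < 0 or self.median_volume_um3 <= 0:
            raise DataError("volume distribution parameters must be positive")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Analytic truth for one rendered particle."""

    particle_id: int
    a_um: float
    b_um: float
    c_um: float
    center_x_um: float
    center_y_um: float
    center_z_um: float
    angle_deg: float  # in-plane rotation about z
    volume_um3: float  # 4/3·π·abc
    surface_area_um2: float  # Thomsen approximation
    voxel_count: int
    thin_flag: bool  # c below half the slice spacing (rendering floor hit)


def _rotation_about_z(angle_deg: float) -> np.ndarray:
    t = math.radians(angle_deg)
    return np.array(
        [[math.cos(t), -math.sin(t), 0.0], [math.sin(t), math.cos(t), 0.0], [0.0, 0.0, 1.0]]
    )


def render_ellipsoid(
    voxels: np.ndarray,
    spacing: VoxelSpacing,
    center_um: tuple[float, float, float],
    semi_axes_um: tuple[float, float, float],
    rotation: np.ndarray | float | None = None,
    intensity: float = 200.0,
) -> int:
    """Rasterize a solid rotated ellipsoid into ``voxels`` (in place).

    A voxel is set when its *center* (index × spacing) falls inside the
    ellipsoid; anisotropic spacing is respected by working in physical
    coordinates. Semi-axes thinner than half a voxel spacing are rendered
    at the one-voxel discretization floor. Returns the number of voxels
    set; raises if the ellipsoid does not fit inside the stack.
    """
    a, b, c = semi_axes_um
    if min(a, b, c) <= 0:
        raise DataError("semi-axes must be positive")
    if rotation is None:
        R = np.eye(3)
    elif np.isscalar(rotation):
        R = _rotation_about_z(float(rotation))
    else:
        R = np.asarray(rotation, dtype=float)
    cx, cy, cz = center_um
    sp = np.array([spacing.dx, spacing.dy, spacing.dz])
    nz, ny, nx = voxels.shape
    # exact support half-extent of the rotated ellipsoid along each axis
    extent = np.sqrt(((R * np.array([a, b, c])) ** 2).sum(axis=1))
    lo = (np.array([cx, cy, cz]) - extent) / sp
    hi = (np.array([cx, cy, cz]) + extent) / sp
    if (lo < -0.5).any() or (hi > np.array([nx, ny, nz]) - 0.5).any():
        raise DataError(
            f"ellipsoid at {center_um} with extent {extent} exceeds stack bounds"
        )
    # discretization floor: semi-axes never below half a voxel spacing, so
    # even paper-thin particles render at least one voxel thick
    ea = max(a, min(spacing.dx, spacing.dy) / 2.0 + 1e-9)
    eb = max(b, min(spacing.dx, spacing.dy) / 2.0 + 1e-9)
    ec = max(c, spacing.dz / 2.0 + 1e-9)
    i0 = np.maximum(np.floor(lo).astype(int), 0)
    i1 = np.minimum(np.ceil(hi).astype(int) + 1, [nx, ny, nz])
    xs = np.arange(i0[0], i1[0]) * spacing.dx - cx
    ys = np.arange(i0[1], i1[1]) * spacing.dy - cy
    zs = np.arange(i0[2], i1[2]) * spacing.dz - cz
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)  # physical coords relative to the center
    local = pts @ R  # row-vector form of R.T @ p: world -> body frame
    inside = (
        (local[..., 0] / ea) ** 2 + (local[..., 1] / eb) ** 2 + (local[..., 2] / ec) ** 2
    ) <= 1.0
    sub = voxels[i0[2] : i1[2], i0[1] : i1[1], i0[0] : i1[0]]
    sub[inside] = intensity
    return int(inside.sum())


def add_noise(stack: IntensityStack, sd: float, seed: int) -> IntensityStack:
    """Additive Gaussian noise, clipped to the bit-depth range."""
    if sd < 0:
        raise DataError("noise SD must be >= 0")
    if sd == 0:
        return stack
    rng = np.random.default_rng(seed)
    vmax = 2**stack.bit_depth - 1
    noisy = stack.voxels.astype(float) + rng.normal(0.0, sd, size=stack.voxels.shape)
    noisy = np.clip(np.rint(noisy), 0, vmax).astype(stack.voxels.dtype)
    return IntensityStack(voxels=noisy, spacing=stack.spacing, bit_depth=stack.bit_depth)


def _sample_particle(rng: np.random.Generator, params: GeneratorParams, depth_um: float):
    """Draw (a, b, c) from the volume/ratio distributions, rejecting shapes
    too thick to mount within the stack depth (bounded retries)."""
    mu = math.log(params.median_volume_um3)
    for _ in range(200):
        vol = math.exp(rng.normal(mu, params.sigma_log))
        rba = rng.uniform(*params.b_over_a)
        rcb = rng.uniform(*params.c_over_b)
        a = (3.0 * vol / (4.0 * math.pi * rba * rba * rcb)) ** (1.0 / 3.0)
        b, c = rba * a, rcb * rba * a
        if 2 * c <= depth_um - 3 * params.spacing.dz:
            return a, b, c
    raise DataError("could not sample a particle thin enough for the stack depth")


def generate_assemblage(
    params: GeneratorParams,
) -> tuple[IntensityStack, list[GroundTruthRecord]]:
    """Render a ground-truthed assemblage of non-touching oblate particles.

    Placement is rejection-sampled so that particle footprints (enclosing
    circles in x–y, padded by two voxels) never overlap — rendered
    particles are therefore disjoint under 26-connectivity and the
    ground-truth count equals the connected-component count. Deterministic
    for a fixed seed. Raises with the achieved count if packing fails.
    """
    nz, ny, nx = params.shape
    sp = params.spacing
    depth_um = nz * sp.dz
    width_um, height_um = nx * sp.dx, ny * sp.dy
    if params.n_particles:
        # feasibility guard: mean footprint must stay a sparse fraction
        mean_vol = params.median_volume_um3 * math.exp(params.sigma_log**2 / 2)
        a_typ = (3 * mean_vol / (4 * math.pi * 0.9 * 0.9 * 0.35)) ** (1 / 3)
        if params.n_particles * math.pi * a_typ**2 > 0.3 * width_um * height_um:
            raise DataError(
                "infeasible packing: expected particle footprint exceeds 30% "
                "of the stack area; enlarge the stack or reduce n_particles"
            )
    rng = np.random.default_rng(params.seed)
    dtype = np.uint8 if params.bit_depth <= 8 else np.uint16
    voxels = np.full(params.shape, round(params.background), dtype=dtype)
    placed: list[tuple[float, float, float]] = []  # (cx, cy, clearance radius)
    truth: list[GroundTruthRecord] = []
    margin = 2.0 * max(sp.dx, sp.dy)
    for pid in range(1, params.n_particles + 1):
        a = b = c = None
        for _ in range(500):
            a, b, c = _sample_particle(rng, params, depth_um)
            r_clear = a + margin
            cx = rng.uniform(a + margin, width_um - sp.dx - a - margin)
            cy = rng.uniform(a + margin, height_um - sp.dy - a - margin)
            cz = depth_um / 2.0 - sp.dz / 2.0
            if all(
                math.hypot(cx - px, cy - py) > r_clear + pr for px, py, pr in placed
            ):
                break
        else:
            raise DataError(
                f"packing failed after 500 retries: placed {len(truth)} of "
                f"{params.n_particles} particles"
            )
        angle = float(rng.uniform(0, 180)) if params.orientation == "random_z" else 0.0
        count = render_ellipsoid(
            voxels,
            sp,
            center_um=(cx, cy, cz),
            semi_axes_um=(a, b, c),
            rotation=angle,
            intensity=params.foreground,
        )
        placed.append((cx, cy, a + margin))
        truth.append(
            GroundTruthRecord(
                particle_id=pid,
                a_um=a,
                b_um=b,
                c_um=c,
                center_x_um=cx,
                center_y_um=cy,
                center_z_um=cz,
                angle_deg=angle,
                volume_um3=ellipsoid_volume(a, b, c),
                surface_area_um2=thomsen_surface_area(a, b, c),
                voxel_count=count,
                thin_flag=c < sp.dz / 2,
            )
        )
    if params.bottom_reflection:
        voxels[-1] = round(params.foreground)
    stack = IntensityStack(voxels=voxels, spacing=sp, bit_depth=params.bit_depth)
    if params.noise_sd > 0:
        # derive the noise stream from the placement seed deterministically
        stack = add_noise(stack, params.noise_sd, seed=params.seed + 1_000_003)
    return stack, truth


def truth_to_frame(truth: list[GroundTruthRecord]):
    """Ground-truth records as a pandas DataFrame (for CSV export)."""
    import dataclasses

    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(t) for t in truth])


def slab_assemblage(
    radii_um: list[float],
    thickness_um: float = 26.0,
    spacing: VoxelSpacing | None = None,
) -> list["IntensityStack"]:
    """Uniform-thickness circular slabs, one per (small) stack.

    Thin slabs of thickness t satisfy V ≈ t·A_footprint and mesh area
    A ≈ 2·A_footprint, hence V ≈ (t/2)·A_mesh — the geometric basis of the
    area→volume conversion factor (t = 26 µm gives k = 13).
    """
    sp = spacing or VoxelSpacing(2.768, 2.768, 2.0)
    stacks = []
    n_slices = int(round(thickness_um / sp.dz))
    if abs(n_slices * sp.dz - thickness_um) > 1e-9:
        raise DataError("thickness must be an integer number of slices")
    for r in radii_um:
        nxy = int(math.ceil(2 * (r + 4 * sp.dx) / sp.dx))
        nz = n_slices + 4
        voxels = np.zeros((nz, nxy, nxy), dtype=np.uint8)
        cx = (nxy - 1) / 2 * sp.dx
        cy = (nxy - 1) / 2 * sp.dy
        ys = np.arange(nxy) * sp.dy - cy
        xs = np.arange(nxy) * sp.dx - cx
        YY, XX = np.meshgrid(ys, xs, indexing="ij")
        disc = (XX**2 + YY**2) <= r**2
        voxels[2 : 2 + n_slices][:, disc] = 200
        stacks.append(IntensityStack(voxels=voxels, spacing=sp, bit_depth=8))
    return stacks
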