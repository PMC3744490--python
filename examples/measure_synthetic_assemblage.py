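"""Generate a small ground-truthed assemblage and run the full pipeline.

Builds a synthetic reflectance z-stack of 12 oblate "charcoal" particles,
segments and meshes them, and compares the recovered per-particle volumes
with the generator's analytic truth.
"""

import numpy as np

import charstack3d as cs

params = cs.GeneratorParams(
    shape=(30, 560, 560),  # 150 µm deep at dz = 5 µm, ~1.55 mm across
    n_particles=12,
    median_volume_um3=8e5,
    sigma_log=0.5,
    seed=11,
)
stack, truth = cs.generate_assemblage(params)
print(f"stack: {stack.shape} voxels at spacing "
      f"({params.spacing.dx}, {params.spacing.dy}, {params.spacing.dz}) µm")

cfg = cs.AnalysisConfig()  # auto threshold, 26-connectivity, min 10 voxels
labels = cs.segment_stack(stack, cfg)
records = cs.measure_stack(labels, cfg)
print(f"segmented {labels.n_particles} particles "
      f"(generator placed {len(truth)})\n")

print(f"{'id':>3} {'mesh V (µm³)':>14} {'true V (µm³)':>14} {'err':>7} {'class':>9}")
for t in truth:
    # records are in raster order; match each truth particle via its center
    iz = int(round(t.center_z_um / params.spacing.dz))
    iy = int(round(t.center_y_um / params.spacing.dy))
    ix = int(round(t.center_x_um / params.spacing.dx))
    r = next(r for r in records if r.particle_id == labels.voxels[iz, iy, ix])
    err = (r.volume_um3 - t.volume_um3) / t.volume_um3
    print(f"{r.particle_id:>3} {r.volume_um3:>14.0f} {t.volume_um3:>14.0f} "
          f"{err:>+6.1%} {r.shape_class:>9}")

summary = cs.summarize(records, "synthetic")
print(f"\nsample median volume: {summary.median_volume:,.0f} µm³ "
      f"(true median {np.median([t.volume_um3 for t in truth]):,.0f} µm³)")
print("The per-particle error is discretization noise: each ellipsoid is "
      "rasterized into ~5 µm slices before the surface is rebuilt.")
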