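"""Map water density and mobility around the valve.

Computes the voxelized water density (count nm^-3) and the mean water
displacement over 10 ps in the 4 x 4 x 6 nm box anchored on the valve,
then extracts the axial slice through the valve plane.  With a
semi-permeable barrier the slice shows a depleted band at the seal.
"""

import numpy as np

from valvewatch import (
    BarrierSystemParams,
    density_grid,
    displacement_grid,
    generate_barrier_system,
    grid_slice,
)

params = BarrierSystemParams(
    n_waters=300, n_frames=500, crossing_probability=0.1,
    barrier_half_thickness=0.3, seed=4,
)
trajectory, _ = generate_barrier_system(params)

rho = density_grid(trajectory, voxel_edge=0.5)
disp = displacement_grid(trajectory, voxel_edge=0.5, dt_ps=10.0)

print(f"density grid {rho.shape}, mean in-box density "
      f"{rho.values[rho.values > 0].mean():.2f} waters/nm^3")
print(f"time-averaged waters inside the box: {rho.total_mass():.1f}")

# axial profile: average density per z-layer (z=0 is the valve plane)
z = rho.origin[2] + (np.arange(rho.shape[2]) + 0.5) * rho.voxel_edge
profile = rho.values.mean(axis=(0, 1))
for zi, d in zip(z[3:9], profile[3:9]):
    bar = "#" * int(d * 20)
    print(f"  z = {zi:+.2f} nm  density {d:5.2f}  {bar}")

plane = grid_slice(disp, axis=2, position=0.5)
print(f"\nmean 10-ps displacement just above the valve: "
      f"{plane[plane > 0].mean():.3f} nm")
print("The depleted band at z ~ 0 is the hydrophobic seal; displacement")
print("away from it matches free Brownian motion.")
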