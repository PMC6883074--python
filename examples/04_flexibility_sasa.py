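"""Per-residue flexibility and hydrophobic cavity surface area.

Recovers known fluctuation amplitudes (RMSF = sqrt(3)*sigma for an
isotropic tether) and quantifies the growth of solvent-exposed
hydrophobic area as a ring of leucine side-chain carbons expands —
the signature of a cavity opening between conformational states.
"""

import numpy as np

from valvewatch import generate_tethered_system, rmsf_profile, sasa_series
from valvewatch.core import Topology, Trajectory

sigmas = [0.02, 0.05, 0.10]
trajectory, truth = generate_tethered_system(sigmas, 5000, seed=1)
profile = rmsf_profile(trajectory, None, "name CA")
print("tethered-particle RMSF recovery:")
for sigma, got in zip(sigmas, profile.rmsf):
    print(f"  sigma {sigma:.2f} nm -> RMSF {got:.4f} nm "
          f"(expected sqrt(3)*sigma = {np.sqrt(3) * sigma:.4f})")

# expanding hydrophobic ring
n_ring, frames = 8, 30
theta = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
radii = np.linspace(0.25, 0.8, frames)
pos = np.empty((frames, n_ring, 3))
for t, r in enumerate(radii):
    pos[t] = np.column_stack(
        [5 + r * np.cos(theta), 5 + r * np.sin(theta), np.full(n_ring, 5.0)]
    )
topology = Topology(
    names=np.array(["CD1"] * n_ring),
    elements=np.array(["C"] * n_ring),
    resids=np.arange(1, n_ring + 1),
    resnames=np.array(["LEU"] * n_ring),
    chainids=np.array(["A"] * n_ring),
)
ring = Trajectory(topology, pos, np.tile([10.0, 10.0, 10.0], (frames, 1)),
                  np.arange(frames) * 10.0)
series = sasa_series(ring, list(range(1, 9)), stride_ps=10.0, window_ps=50.0)
print(f"\nhydrophobic SASA of the ring: {series.smoothed[0]:.2f} nm^2 closed "
      f"-> {series.smoothed[-1]:.2f} nm^2 open "
      f"({series.smoothed[-1] / series.smoothed[0]:.1f}x)")
print("A >= 2x increase in exposed hydrophobic area is the quantitative")
print("signature of the upper cavity expanding in the outward-facing state.")
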