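"""Roof geometry: salt-bridge distances, boxplot statistics, axial shift.

Samples an atom-pair distance series from a synthetic system whose
separation follows a known Gaussian mixture (emulating the bimodal valve
geometry of the outward-facing state), summarises it with mean-centred
boxplot statistics, and recovers a known valve shift between two
conformational states.
"""

import numpy as np

from valvewatch import (
    boxplot_stats,
    distance_probability,
    distance_series,
    generate_distance_pair_system,
    generate_shifted_pair,
    valve_axial_shift,
)
from valvewatch.core import select

# inward-facing-like valve: one narrow distance population at 1.05 nm
inward, _ = generate_distance_pair_system([(1.0, 1.05, 0.02)], 3000, seed=1)
(series,) = distance_series(inward, "1:CA-2:CA", stride_ps=1000.0)
stats = boxplot_stats(series)
print(f"inward-like pair: mean {stats.mean:.3f} nm, "
      f"Q1-Q3 [{stats.q1:.3f}, {stats.q3:.3f}], "
      f"extremes [{stats.minimum:.3f}, {stats.maximum:.3f}] (n={stats.n})")

# outward-facing-like valve: bimodal, 1.1 and 1.5 nm
outward, _ = generate_distance_pair_system(
    [(0.5, 1.1, 0.03), (0.5, 1.5, 0.03)], 3000, seed=2
)
(series,) = distance_series(outward, "1:CA-2:CA", stride_ps=1000.0)
dist = distance_probability([series], bin_width=0.05)
modes = dist.mode_centers(min_probability=0.05)
print(f"outward-like pair: distance modes at {np.round(modes, 2)} nm "
      f"(probabilities sum to {dist.probability.sum():.3f})")

# valve shift between states: a rigid 0.3 nm upward translation
from valvewatch import BarrierSystemParams, generate_barrier_system

traj, _ = generate_barrier_system(BarrierSystemParams(n_waters=10, n_frames=2, seed=3))
valve = select(traj.topology, "resid 554-555 and name CA")
a, b, truth = generate_shifted_pair(traj.frame(0), (0.1, 0.0, 0.3))
shift = valve_axial_shift(a, b, valve)
print(f"recovered valve axial shift: {shift:+.3f} nm "
      f"(generator truth: {truth.shift_vector[2]:+.3f} nm)")
print("\nThe single narrow inward mode vs the split outward modes is the")
print("rigid-to-flexible signature of the valve's conformational change.")
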