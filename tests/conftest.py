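import numpy as np
import pytest

from valvewatch import BarrierSystemParams, generate_barrier_system
from valvewatch.core import Topology, Trajectory


@pytest.fixture(scope="session")
def barrier_run():
    """A moderately leaky barrier system with its ground truth."""
    params = BarrierSystemParams(
        n_waters=150, n_frames=400, crossing_probability=0.3, seed=11
    )
    traj, gt = generate_barrier_system(params)
    return params, traj, gt


@pytest.fixture(scope="session")
def sealed_run():
    params = BarrierSystemParams(
        n_waters=150, n_frames=400, crossing_probability=0.0, seed=12
    )
    traj, gt = generate_barrier_system(params)
    return params, traj, gt


def make_water_system(water_positions, box=(6.0, 6.0, 10.0), valve_z=5.0,
                      n_frames=None, frame_spacing=10.0):
    """Hand-built system: the standard valve scaffold plus scripted waters.

    ``water_positions`` is (n_frames, n_waters, 3) or (n_waters, 3)
    (static, repeated ``n_frames`` times).
    """
    water_positions = np.asarray(water_positions, dtype=float)
    if water_positions.ndim == 2:
        if n_frames is None:
            n_frames = 10
        water_positions = np.tile(water_positions[None], (n_frames, 1, 1))
    n_frames, n_waters = water_positions.shape[:2]
    cx, cy = box[0] / 2, box[1] / 2
    scaffold = []
    names, resids, chains = [], [], []
    for chain, dx in (("A", -0.5), ("B", 0.5)):
        for k, resid in enumerate((554, 555)):
            scaffold.append((cx + dx, cy + (k - 0.5) * 0.4, valve_z))
            names.append("CA")
            resids.append(resid)
            chains.append(chain)
    ns = len(scaffold)
    top = Topology(
        names=np.array(names + ["OW"] * n_waters),
        elements=np.array(["C"] * ns + ["O"] * n_waters),
        resids=np.array(resids + list(range(1, n_waters + 1))),
        resnames=np.array(["LEU"] * ns + ["SOL"] * n_waters),
        chainids=np.array(chains + ["W"] * n_waters),
    )
    pos = np.empty((n_frames, ns + n_waters, 3))
    pos[:, :ns] = np.asarray(scaffold)
    pos[:, ns:] = water_positions
    boxes = np.tile(np.asarray(box, float), (n_frames, 1))
    times = np.arange(n_frames) * frame_spacing
    return Trajectory(top, pos, boxes, times), ns
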