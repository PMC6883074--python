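"""Voxelized water density and mean-displacement maps around the valve.

Grids span exactly the valve-anchored density box (default 4 x 4 x 6 nm,
0.1 nm voxels).  Density is the time-averaged water count per voxel
divided by the voxel volume (count nm^-3); the displacement map is the
mean minimum-image travel distance |r(t+dt) - r(t)| of the waters that
start in each voxel, with dt defaulting to the 10 ps analysis stride.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import AtomSelection, Trajectory, minimum_image_displacement, select
from .flux import (
    DEFAULT_VALVE_SELECTION,
    DEFAULT_WATER_SELECTION,
    CompartmentBoxes,
    anchor_boxes,
)

__all__ = [
    "ScalarGrid",
    "density_grid",
    "displacement_grid",
    "grid_slice",
    "average_grids",
    "write_dx",
]


@dataclass
class ScalarGrid:
    """A voxel grid of densities or mean displacements.

    ``origin`` is the low corner (nm) in the anchored frame of reference
    (relative to the box centre when the boxes are re-anchored);
    ``values`` has shape (nx, ny, nz); ``semantics`` is "density"
    (count nm^-3) or "displacement" (nm).
    """

    origin: np.ndarray
    voxel_edge: float
    values: np.ndarray
    semantics: str
    n_frames: int
    counts: np.ndarray | None = None   # per-voxel sample counts (displacement)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.voxel_edge <= 0:
            raise ValueError("voxel edge must be > 0")
        if self.semantics not in ("density", "displacement"):
            raise ValueError("semantics must be 'density' or 'displacement'")
        if self.semantics == "density" and np.any(self.values < -1e-12):
            raise ValueError("density values must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return self.voxel_edge ** 3

    def total_mass(self) -> float:
        """Sum(density * voxel volume) = time-averaged in-box water count."""
        if self.semantics != "density":
            raise ValueError("total_mass only defined for density grids")
        return float(self.values.sum() * self.voxel_volume)

    def compatible(self, other: "ScalarGrid") -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel_edge - other.voxel_edge) < 1e-9
            and np.allclose(self.origin, other.origin)
            and self.semantics == other.semantics
        )


def _grid_geometry(boxes: CompartmentBoxes, voxel_edge: float):
    dims = np.asarray(boxes.density_box_dims, dtype=float)
    if voxel_edge > dims.min():
        raise ValueError("voxel edge larger than the density box")
    shape = np.maximum(np.round(dims / voxel_edge).astype(int), 1)
    # origin relative to the (moving) box centre
    origin = -dims / 2.0
    return origin, shape


def _in_box_voxel_indices(
    rel: np.ndarray, origin: np.ndarray, shape: np.ndarray, voxel_edge: float
):
    """Voxel index per position (relative to box centre); mask for in-box."""
    f = (rel - origin) / voxel_edge
    idx = np.floor(f).astype(int)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    return idx, ok


def density_grid(
    trajectory: Trajectory,
    valve_selection: AtomSelection | str = DEFAULT_VALVE_SELECTION,
    water_selection: AtomSelection | str = DEFAULT_WATER_SELECTION,
    voxel_edge: float = 0.1,
    reanchor: bool = True,
    density_box_dims=(4.0, 4.0, 6.0),
    axis: int = 2,
) -> ScalarGrid:
    """Time-averaged water density (count nm^-3) on the anchored grid."""
    if isinstance(valve_selection, str):
        valve_selection = select(trajectory.topology, valve_selection, allow_empty=False)
    if isinstance(water_selection, str):
        water_selection = select(trajectory.topology, water_selection, allow_empty=False)
    boxes0 = anchor_boxes(
        trajectory.frame(0), valve_selection, density_box_dims=density_box_dims, axis=axis
    )
    origin, shape = _grid_geometry(boxes0, voxel_edge)
    counts = np.zeros(shape, dtype=float)
    for i in range(trajectory.n_frames):
        frame = trajectory.frame(i)
        boxes = (
            anchor_boxes(frame, valve_selection, density_box_dims=density_box_dims, axis=axis)
            if reanchor
            else boxes0
        )
        rel = minimum_image_displacement(
            boxes.center, frame.positions[water_selection.indices], frame.box
        )
        idx, ok = _in_box_voxel_indices(rel, origin, shape, voxel_edge)
        np.add.at(counts, tuple(idx[ok].T), 1.0)
    values = counts / (trajectory.n_frames * voxel_edge ** 3)
    return ScalarGrid(
        origin=origin,
        voxel_edge=voxel_edge,
        values=values,
        semantics="density",
        n_frames=trajectory.n_frames,
    )


def displacement_grid(
    trajectory: Trajectory,
    valve_selection: AtomSelection | str = DEFAULT_VALVE_SELECTION,
    water_selection: AtomSelection | str = DEFAULT_WATER_SELECTION,
    voxel_edge: float = 0.1,
    dt_ps: float = 10.0,
    reanchor: bool = True,
    density_box_dims=(4.0, 4.0, 6.0),
    axis: int = 2,
) -> ScalarGrid:
    """Mean water travel distance over ``dt_ps`` per starting voxel (nm).

    For every frame t, waters inside the density box are binned by their
    position at t; |r(t+dt) - r(t)| (minimum image) is averaged per bin.
    Voxels never visited hold 0 with a zero sample count.
    """
    if isinstance(valve_selection, str):
        valve_selection = select(trajectory.topology, valve_selection, allow_empty=False)
    if isinstance(water_selection, str):
        water_selection = select(trajectory.topology, water_selection, allow_empty=False)
    spacing = trajectory.spacing
    if spacing <= 0:
        raise ValueError("displacement grid needs >= 2 frames")
    step = round(dt_ps / spacing)
    if step < 1 or abs(dt_ps / spacing - step) > 1e-6:
        raise ValueError(f"dt {dt_ps} ps is not a multiple of frame spacing {spacing}")
    if step >= trajectory.n_frames:
        raise ValueError("dt exceeds the trajectory span")
    boxes0 = anchor_boxes(
        trajectory.frame(0), valve_selection, density_box_dims=density_box_dims, axis=axis
    )
    origin, shape = _grid_geometry(boxes0, voxel_edge)
    acc = np.zeros(shape, dtype=float)
    nsamp = np.zeros(shape, dtype=float)
    widx = water_selection.indices
    for i in range(trajectory.n_frames - step):
        frame = trajectory.frame(i)
        later = trajectory.frame(i + step)
        boxes = (
            anchor_boxes(frame, valve_selection, density_box_dims=density_box_dims, axis=axis)
            if reanchor
            else boxes0
        )
        rel = minimum_image_displacement(boxes.center, frame.positions[widx], frame.box)
        idx, ok = _in_box_voxel_indices(rel, origin, shape, voxel_edge)
        disp = np.linalg.norm(
            minimum_image_displacement(
                frame.positions[widx], later.positions[widx], frame.box
            ),
            axis=1,
        )
        np.add.at(acc, tuple(idx[ok].T), disp[ok])
        np.add.at(nsamp, tuple(idx[ok].T), 1.0)
    with np.errstate(invalid="ignore"):
        values = np.where(nsamp > 0, acc / np.maximum(nsamp, 1), 0.0)
    return ScalarGrid(
        origin=origin,
        voxel_edge=voxel_edge,
        values=values,
        semantics="displacement",
        n_frames=trajectory.n_frames - step,
        counts=nsamp,
    )


def grid_slice(grid: ScalarGrid, axis: int, position: float) -> np.ndarray:
    """The 2D voxel plane nearest ``position`` (nm, grid coordinates)."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    lo = grid.origin[axis]
    hi = lo + grid.shape[axis] * grid.voxel_edge
    if not lo <= position < hi:
        raise ValueError(f"position {position} outside grid range [{lo}, {hi})")
    k = int((position - lo) / grid.voxel_edge)
    k = min(k, grid.shape[axis] - 1)
    return np.take(grid.values, k, axis=axis)


def average_grids(grids: list[ScalarGrid]) -> ScalarGrid:
    """Voxel-wise mean of replicate grids with identical geometry."""
    if not grids:
        raise ValueError("no grids to average")
    first = grids[0]
    for g in grids[1:]:
        if not first.compatible(g):
            raise ValueError("grid geometries do not match")
    values = np.mean([g.values for g in grids], axis=0)
    return ScalarGrid(
        origin=first.origin.copy(),
        voxel_edge=first.voxel_edge,
        values=values,
        semantics=first.semantics,
        n_frames=sum(g.n_frames for g in grids),
    )


def write_dx(grid: ScalarGrid, path: str | Path) -> None:
    """Write the grid as an OpenDX volumetric file."""
    from gridData import Grid as DXGrid

    g = DXGrid(
        grid.values,
        origin=np.asarray(grid.origin, dtype=float),
        delta=np.full(3, grid.voxel_edge),
    )
    g.export(str(path), file_format="dx")
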