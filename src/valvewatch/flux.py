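"""Valve-anchored compartment boxes and water-crossing counts.

The analysis volume is a pair of nested, axis-aligned boxes centred on
the di-leucine valve: a 4 x 4 x 6 nm density box, and inside it a
2 x 2 x 4 nm flux volume split at the valve plane into an upper and a
central sub-box of 2 x 2 x 2 nm each.  A water contributes one crossing
event when it is labelled *central* at one analysed frame and *upper*
at the next (or vice versa), with analysed frames 10 ps apart by
default; paths that leave through the box sides are not crossings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AtomSelection,
    Frame,
    Trajectory,
    minimum_image_displacement,
    select,
)

__all__ = [
    "CompartmentBoxes",
    "FluxEvent",
    "FluxRecord",
    "FluxSummary",
    "DEFAULT_VALVE_SELECTION",
    "anchor_boxes",
    "classify_waters",
    "count_crossings",
    "flux_summary",
    "DEFAULT_WATER_SELECTION",
]

#: Calpha atoms of the di-leucine motif in both chains
DEFAULT_VALVE_SELECTION = "resid 554-555 and name CA"
DEFAULT_WATER_SELECTION = "resname SOL HOH TIP3 WAT and name OW O OH2"

CENTRAL, UPPER, OUTSIDE = 0, 1, 2
_LABELS = {CENTRAL: "central", UPPER: "upper", OUTSIDE: "outside"}


@dataclass(frozen=True)
class CompartmentBoxes:
    """Valve-anchored analysis volumes.

    ``center`` sits at the valve centroid; the valve plane is the axial
    coordinate of the centre.  ``density_box_dims`` is the full outer box
    and ``flux_box_dims`` the full (upper+central) flux volume; the two
    sub-boxes share the valve-plane face.  ``axis`` is the membrane
    normal (0=x, 1=y, 2=z).
    """

    center: np.ndarray
    density_box_dims: tuple[float, float, float] = (4.0, 4.0, 6.0)
    flux_box_dims: tuple[float, float, float] = (2.0, 2.0, 4.0)
    axis: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if any(d <= 0 for d in self.density_box_dims + self.flux_box_dims):
            raise ValueError("box dimensions must be strictly positive")
        if any(
            f > d for f, d in zip(self.flux_box_dims, self.density_box_dims)
        ):
            raise ValueError("flux boxes must nest inside the density box")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")

    @property
    def valve_plane(self) -> float:
        """Axial coordinate of the valve plane (nm)."""
        return float(self.center[self.axis])

    def classify(self, positions: np.ndarray, box: np.ndarray) -> np.ndarray:
        """Label positions as CENTRAL / UPPER / OUTSIDE.

        Membership is evaluated on the minimum-image displacement from
        the box centre, so wrapped coordinates classify correctly.
        Boundaries are half-open; a point exactly on the valve plane is
        *upper*.
        """
        d = minimum_image_displacement(self.center, np.atleast_2d(positions), box)
        half = np.asarray(self.flux_box_dims) / 2.0
        lateral = [i for i in range(3) if i != self.axis]
        in_lateral = np.ones(len(d), dtype=bool)
        for i in lateral:
            in_lateral &= (d[:, i] >= -half[i]) & (d[:, i] < half[i])
        ax = d[:, self.axis]
        labels = np.full(len(d), OUTSIDE, dtype=np.int8)
        labels[in_lateral & (ax >= 0) & (ax < half[self.axis])] = UPPER
        labels[in_lateral & (ax >= -half[self.axis]) & (ax < 0)] = CENTRAL
        return labels

    def in_density_box(self, positions: np.ndarray, box: np.ndarray) -> np.ndarray:
        d = minimum_image_displacement(self.center, np.atleast_2d(positions), box)
        half = np.asarray(self.density_box_dims) / 2.0
        return np.all((d >= -half) & (d < half), axis=1)


@dataclass(frozen=True)
class FluxEvent:
    frame_from: int
    frame_to: int
    time: float           # ps, time of the later frame
    water: int            # global atom index
    direction: str        # "up" (central->upper) or "down"


@dataclass
class FluxRecord:
    """Crossing events and cumulative counts for one trajectory."""

    events: list[FluxEvent]
    times: np.ndarray              # analysed-pair times (ps, later frame)
    counts_per_interval: np.ndarray
    unique_waters_per_interval: np.ndarray
    stride_ps: float
    window_ps: float               # analysed time span

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.counts_per_interval)

    @property
    def total_events(self) -> int:
        return int(len(self.events))

    @property
    def total_unique(self) -> int:
        return int(self.unique_waters_per_interval.sum())


@dataclass(frozen=True)
class FluxSummary:
    mean: float
    sem: float
    per_replicate: tuple[int, ...]
    n_replicates: int


def anchor_boxes(
    frame: Frame,
    valve_selection: AtomSelection,
    density_box_dims=(4.0, 4.0, 6.0),
    flux_box_dims=(2.0, 2.0, 4.0),
    axis: int = 2,
) -> CompartmentBoxes:
    """Centre the analysis boxes on the valve-selection centroid."""
    if len(valve_selection) == 0:
        raise ValueError("valve selection is empty")
    if len(valve_selection) == 1:
        warnings.warn("anchoring boxes on a single atom", stacklevel=2)
    center = frame.positions[valve_selection.indices].mean(axis=0)
    return CompartmentBoxes(
        center=center,
        density_box_dims=tuple(density_box_dims),
        flux_box_dims=tuple(flux_box_dims),
        axis=axis,
    )


def classify_waters(
    frame: Frame, boxes: CompartmentBoxes, water_selection: AtomSelection
) -> np.ndarray:
    """Compartment label (CENTRAL/UPPER/OUTSIDE) per selected water."""
    return boxes.classify(frame.positions[water_selection.indices], frame.box)


def _analysis_indices(trajectory: Trajectory, stride_ps: float) -> np.ndarray:
    spacing = trajectory.spacing
    if spacing <= 0:
        raise ValueError("trajectory must have at least two frames")
    ratio = stride_ps / spacing
    step = round(ratio)
    if step < 1 or abs(ratio - step) > 1e-6:
        raise ValueError(
            f"stride {stride_ps} ps is not a multiple of the frame spacing "
            f"{spacing} ps"
        )
    return np.arange(0, trajectory.n_frames, step)


def count_crossings(
    trajectory: Trajectory,
    valve_selection: AtomSelection | str = DEFAULT_VALVE_SELECTION,
    water_selection: AtomSelection | str = DEFAULT_WATER_SELECTION,
    stride_ps: float = 10.0,
    reanchor: bool = True,
    density_box_dims=(4.0, 4.0, 6.0),
    flux_box_dims=(2.0, 2.0, 4.0),
    axis: int = 2,
) -> FluxRecord:
    """Count upper<->central water exchanges between analysed frames.

    Frames ``stride_ps`` apart are compared pairwise; a water counts once
    per pair when its label swaps between the two sub-boxes.  With
    ``reanchor`` (default) the boxes follow the valve centroid each
    analysed frame; otherwise they stay where the first frame put them.
    Both the raw event tally and the unique-molecule tally per interval
    are recorded.
    """
    if isinstance(valve_selection, str):
        valve_selection = select(trajectory.topology, valve_selection, allow_empty=False)
    if isinstance(water_selection, str):
        water_selection = select(trajectory.topology, water_selection, allow_empty=False)
    idx = _analysis_indices(trajectory, stride_ps)
    boxes0 = anchor_boxes(
        trajectory.frame(int(idx[0])), valve_selection,
        density_box_dims, flux_box_dims, axis,
    )

    def _boxes(i: int) -> CompartmentBoxes:
        if not reanchor:
            return boxes0
        return anchor_boxes(
            trajectory.frame(i), valve_selection,
            density_box_dims, flux_box_dims, axis,
        )

    events: list[FluxEvent] = []
    times, counts, uniques = [], [], []
    prev_labels = classify_waters(
        trajectory.frame(int(idx[0])), _boxes(int(idx[0])), water_selection
    )
    for j in range(1, len(idx)):
        i_prev, i_cur = int(idx[j - 1]), int(idx[j])
        labels = classify_waters(
            trajectory.frame(i_cur), _boxes(i_cur), water_selection
        )
        up = (prev_labels == CENTRAL) & (labels == UPPER)
        down = (prev_labels == UPPER) & (labels == CENTRAL)
        movers = np.nonzero(up | down)[0]
        t = float(trajectory.times[i_cur])
        for m in movers:
            events.append(
                FluxEvent(
                    frame_from=i_prev,
                    frame_to=i_cur,
                    time=t,
                    water=int(water_selection.indices[m]),
                    direction="up" if up[m] else "down",
                )
            )
        times.append(t)
        counts.append(len(movers))
        uniques.append(len(set(water_selection.indices[movers])))
        prev_labels = labels
    window = float(trajectory.times[int(idx[-1])] - trajectory.times[int(idx[0])])
    return FluxRecord(
        events=events,
        times=np.asarray(times),
        counts_per_interval=np.asarray(counts, dtype=int),
        unique_waters_per_interval=np.asarray(uniques, dtype=int),
        stride_ps=float(stride_ps),
        window_ps=window,
    )


def flux_summary(records: list[FluxRecord], window_rtol: float = 0.01) -> FluxSummary:
    """Mean +/- SEM of total crossing counts over replicate runs.

    Requires at least two replicates with matching analysis windows;
    the SEM uses the n-1 denominator.
    """
    if len(records) < 2:
        raise ValueError("flux_summary requires >= 2 replicates (SEM undefined)")
    windows = np.array([r.window_ps for r in records])
    if np.any(np.abs(windows - windows[0]) > window_rtol * windows[0]):
        raise ValueError(f"analysis windows differ: {windows.tolist()}")
    totals = np.array([r.total_events for r in records], dtype=float)
    n = len(totals)
    mean = float(totals.mean())
    sem = float(totals.std(ddof=1) / math.sqrt(n))
    return FluxSummary(
        mean=mean,
        sem=sem,
        per_replicate=tuple(int(t) for t in totals),
        n_replicates=n,
    )
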