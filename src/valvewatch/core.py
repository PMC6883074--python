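"""Core trajectory data model: topologies, frames, selections, periodic geometry.

Internal units are nanometres for lengths and picoseconds for times,
matching the native units of GROMACS-family trajectory formats.  PDB
coordinates (Ångström) are converted on read.  Boxes are orthorhombic
only; triclinic inputs are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "AtomSelection",
    "load_structure",
    "load_trajectory",
    "write_structure",
    "write_trajectory",
    "select",
    "minimum_image_displacement",
    "minimum_image_distance",
    "trim_equilibration",
]

A_TO_NM = 0.1
NM_TO_A = 10.0

#: tolerance (ps) for "constant frame spacing" checks
SPACING_RTOL = 1e-3


class TrajectoryError(ValueError):
    """Raised for malformed structures, trajectories or selections."""


@dataclass(frozen=True)
class Topology:
    """Atom/residue bookkeeping shared by every frame of a trajectory.

    All arrays have one entry per atom.  Residue identity is the
    (chain, resid) pair under the author numbering of the source file;
    no renumbering is ever performed, so resid 554 means transporter
    residue 554.
    """

    names: np.ndarray          # str atom names, e.g. "CA"
    elements: np.ndarray       # str element symbols
    resids: np.ndarray         # int residue sequence numbers
    resnames: np.ndarray       # str residue names
    chainids: np.ndarray       # str chain / segment identifiers
    bonds: np.ndarray | None = None   # optional (n_bonds, 2) atom-index pairs

    def __post_init__(self) -> None:
        n = len(self.names)
        if n == 0:
            raise TrajectoryError("topology must contain at least one atom")
        for attr in ("elements", "resids", "resnames", "chainids"):
            if len(getattr(self, attr)) != n:
                raise TrajectoryError(f"topology field {attr!r} length mismatch")
        if self.bonds is not None:
            b = np.asarray(self.bonds)
            if b.size and (b.min() < 0 or b.max() >= n):
                raise TrajectoryError("bond indices out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def to_mdanalysis(self):
        """Build an in-memory MDAnalysis Universe mirroring this topology.

        Used to delegate selection-expression parsing; cached per instance.
        """
        import MDAnalysis as mda

        cached = getattr(self, "_mda_universe", None)
        if cached is not None:
            return cached
        # residues: consecutive (chain, resid, resname) runs
        keys = list(zip(self.chainids, self.resids, self.resnames))
        resindex = np.zeros(self.n_atoms, dtype=int)
        res_keys = [keys[0]]
        for i in range(1, self.n_atoms):
            if keys[i] != keys[i - 1]:
                res_keys.append(keys[i])
            resindex[i] = len(res_keys) - 1
        seg_names = sorted(set(k[0] for k in res_keys))
        seg_index = {s: i for i, s in enumerate(seg_names)}
        residue_segindex = [seg_index[k[0]] for k in res_keys]
        u = mda.Universe.empty(
            self.n_atoms,
            n_residues=len(res_keys),
            atom_resindex=resindex,
            n_segments=len(seg_names),
            residue_segindex=residue_segindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", list(self.names))
        u.add_TopologyAttr("elements", list(self.elements))
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("chainIDs", list(self.chainids))
        u.add_TopologyAttr("segids", seg_names)
        object.__setattr__(self, "_mda_universe", u)
        return u


@dataclass(frozen=True)
class AtomSelection:
    """Ordered, duplicate-free set of atom indices plus the expression
    that produced it."""

    indices: np.ndarray
    expression: str

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise TrajectoryError("selection contains duplicate indices")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Frame:
    """One set of coordinates: positions (nm), orthorhombic box (nm), time (ps)."""

    positions: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TrajectoryError("positions must have shape (n_atoms, 3)")
        if self.box.shape != (3,):
            raise TrajectoryError(
                "box must be three orthorhombic edge lengths; "
                "triclinic boxes are not supported"
            )
        if np.any(self.box <= 0):
            raise TrajectoryError("box lengths must be strictly positive")
        if self.time < 0:
            raise TrajectoryError("frame time must be nonnegative")


class Trajectory:
    """An ordered stack of frames over a fixed topology.

    Coordinates are held in one (n_frames, n_atoms, 3) array; per-frame
    boxes in (n_frames, 3); times (ps) strictly increasing with constant
    spacing within a relative tolerance.
    """

    def __init__(
        self,
        topology: Topology,
        positions: np.ndarray,
        boxes: np.ndarray,
        times: np.ndarray,
    ) -> None:
        positions = np.asarray(positions, dtype=float)
        boxes = np.asarray(boxes, dtype=float)
        times = np.asarray(times, dtype=float)
        if positions.ndim != 3 or positions.shape[2] != 3:
            raise TrajectoryError("positions must have shape (n_frames, n_atoms, 3)")
        if positions.shape[1] != topology.n_atoms:
            raise TrajectoryError(
                f"coordinate count {positions.shape[1]} != "
                f"topology atom count {topology.n_atoms}"
            )
        if boxes.shape != (positions.shape[0], 3):
            raise TrajectoryError("boxes must have shape (n_frames, 3)")
        if np.any(boxes <= 0):
            raise TrajectoryError("box lengths must be strictly positive")
        if len(times) != positions.shape[0]:
            raise TrajectoryError("times length mismatch")
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise TrajectoryError("frame times must be strictly increasing")
            if np.any(np.abs(dt - dt[0]) > SPACING_RTOL * max(dt[0], 1.0)):
                raise TrajectoryError("frame spacing is not constant")
        self.topology = topology
        self.positions = positions
        self.boxes = boxes
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def spacing(self) -> float:
        """Frame spacing in ps (0.0 for a single-frame trajectory)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(self.positions[i], self.boxes[i], float(self.times[i]))

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)


# ---------------------------------------------------------------------------
# I/O (delegated to MDAnalysis; Å <-> nm conversion at the boundary)
# ---------------------------------------------------------------------------

def _box_from_dimensions(dimensions) -> np.ndarray:
    if dimensions is None or np.all(np.asarray(dimensions)[:3] == 0):
        # structure files without CRYST1: use a generous dummy box
        return np.array([100.0, 100.0, 100.0])
    dims = np.asarray(dimensions, dtype=float)
    if not np.allclose(dims[3:], 90.0):
        raise TrajectoryError("triclinic boxes are not supported")
    return dims[:3] * A_TO_NM


def _topology_from_universe(u) -> Topology:
    n = len(u.atoms)

    def _attr(name, default):
        try:
            return np.asarray(getattr(u.atoms, name)).astype(str)
        except (AttributeError, Exception):
            return np.full(n, default, dtype=object).astype(str)

    names = _attr("names", "X")
    try:
        elements = np.asarray(u.atoms.elements).astype(str)
    except Exception:
        elements = np.array([_guess_element(nm) for nm in names])
    try:
        chainids = np.asarray(u.atoms.chainIDs).astype(str)
    except Exception:
        chainids = _attr("segids", "A")
    bonds = None
    if hasattr(u, "bonds") and len(getattr(u, "bonds", [])) > 0:
        bonds = np.asarray([(b[0].index, b[1].index) for b in u.bonds], dtype=int)
    return Topology(
        names=names,
        elements=elements,
        resids=np.asarray(u.atoms.resids, dtype=int),
        resnames=np.asarray(u.atoms.resnames).astype(str),
        chainids=chainids,
        bonds=bonds,
    )


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].capitalize()
    if two in ("Cl", "Br", "Na", "Mg", "Fe", "Zn"):
        return two
    return stripped[0].upper()


def load_structure(path: str | Path, fmt: str | None = None) -> tuple[Topology, Frame]:
    """Read a PDB or GRO file into a topology plus a single frame (nm)."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"structure file not found: {path}")
    if path.stat().st_size == 0:
        raise TrajectoryError(f"structure file is empty: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt not in ("PDB", "GRO"):
        raise TrajectoryError(f"unknown structure format: {fmt}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=fmt)
        except Exception as exc:  # noqa: BLE001
            raise TrajectoryError(f"cannot parse {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise TrajectoryError(f"no atoms in {path}")
    top = _topology_from_universe(u)
    # MDAnalysis positions are Å for every format
    frame = Frame(
        positions=u.atoms.positions * A_TO_NM,
        box=_box_from_dimensions(u.dimensions),
        time=0.0,
    )
    return top, frame


def load_trajectory(topology: Topology, path: str | Path) -> Trajectory:
    """Read an XTC/DCD/TRR trajectory against an existing topology."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"trajectory file not found: {path}")
    u = topology.to_mdanalysis()
    try:
        # fresh universe so repeated loads don't fight over the cached one
        u2 = mda.Universe(u._topology.copy(), str(path), to_guess=())
    except (ValueError, OSError, IOError) as exc:
        if "number of atoms" in str(exc).lower():
            raise TrajectoryError(f"atom count mismatch: {exc}") from exc
        raise TrajectoryError(f"cannot read trajectory {path}: {exc}") from exc
    if len(u2.atoms) != topology.n_atoms:
        raise TrajectoryError(
            f"atom count mismatch: file {len(u2.atoms)} vs topology {topology.n_atoms}"
        )
    pos, boxes, times = [], [], []
    for ts in u2.trajectory:
        pos.append(ts.positions * A_TO_NM)
        boxes.append(_box_from_dimensions(ts.dimensions))
        times.append(ts.time)
    return Trajectory(topology, np.array(pos), np.array(boxes), np.array(times))


def write_structure(path: str | Path, topology: Topology, frame: Frame) -> None:
    """Write a single frame as PDB (nm -> Å)."""
    import MDAnalysis as mda

    u = topology.to_mdanalysis()
    u.atoms.positions = frame.positions * NM_TO_A
    u.dimensions = np.concatenate([frame.box * NM_TO_A, [90.0, 90.0, 90.0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    """Write frames to XTC/DCD/TRR (chosen by extension)."""
    import MDAnalysis as mda

    u = trajectory.topology.to_mdanalysis()
    n = trajectory.topology.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n) as w:
            for i in range(trajectory.n_frames):
                u.atoms.positions = trajectory.positions[i] * NM_TO_A
                u.dimensions = np.concatenate(
                    [trajectory.boxes[i] * NM_TO_A, [90.0, 90.0, 90.0]]
                )
                u.trajectory.ts.time = trajectory.times[i]
                u.trajectory.ts.frame = i
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select(
    topology: Topology, expression: str, *, allow_empty: bool = True
) -> AtomSelection:
    """Resolve a selection expression to an ordered atom-index set.

    The grammar is MDAnalysis's selection language (resid/resname/name/
    chainID/element with ranges and boolean combinations); the shorthand
    ``chain X`` is accepted for ``chainID X``.  An empty result triggers
    a warning, or an error when ``allow_empty=False``.
    """
    import re

    expr = re.sub(r"\bchain\s+", "chainID ", expression)
    u = topology.to_mdanalysis()
    try:
        ag = u.select_atoms(expr)
    except Exception as exc:  # noqa: BLE001
        raise TrajectoryError(f"bad selection {expression!r}: {exc}") from exc
    idx = np.sort(ag.indices)
    if len(idx) == 0:
        msg = f"selection {expression!r} matched no atoms"
        if not allow_empty:
            raise TrajectoryError(msg)
        warnings.warn(msg, stacklevel=2)
    return AtomSelection(indices=idx, expression=expression)


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vector(s) b - a under an orthorhombic box."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise TrajectoryError("box lengths must be strictly positive")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distance(s) between points under periodic boundaries (nm)."""
    d = minimum_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


def trim_equilibration(trajectory: Trajectory, t_start_ps: float) -> Trajectory:
    """Drop frames with time < ``t_start_ps`` (the equilibration window)."""
    if t_start_ps > trajectory.times[-1]:
        raise TrajectoryError(
            f"t_start {t_start_ps} ps is beyond the last frame "
            f"({trajectory.times[-1]} ps)"
        )
    keep = trajectory.times >= t_start_ps
    return Trajectory(
        trajectory.topology,
        trajectory.positions[keep],
        trajectory.boxes[keep],
        trajectory.times[keep],
    )
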