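"""Per-residue flexibility (RMSF) and hydrophobic cavity surface area.

RMSF is the root mean square fluctuation of an atom about its trajectory
mean after removing rigid-body motion by least-squares superposition.
Solvent-accessible surface area uses the Shrake-Rupley sphere-point
method (960 points per atom, 0.14 nm probe); cavity hydrophobicity is
quantified by summing the SASA of cavity residues of the hydrophobic
polarity class and smoothing with a 1 ns centred running average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import AtomSelection, Topology, Trajectory, select
from .geometry import superpose

__all__ = [
    "RMSFProfile",
    "SASASeries",
    "POLARITY_CLASSES",
    "VDW_RADII",
    "rmsf_profile",
    "average_rmsf_profiles",
    "classify_polarity",
    "shrake_rupley",
    "sphere_points",
    "sasa_series",
    "running_average",
]

#: polarity classes of the 20 standard residues.  Glycine and cysteine are
#: assigned to the polar class (no aliphatic side-chain surface / the thiol
#: is weakly polar); override by passing a custom table.
POLARITY_CLASSES: dict[str, str] = {
    **{r: "hydrophobic" for r in
       ("ALA", "VAL", "LEU", "ILE", "PHE", "MET", "TRP", "PRO")},
    **{r: "polar" for r in
       ("GLY", "CYS", "SER", "THR", "ASN", "GLN", "TYR")},
    **{r: "positive" for r in ("ARG", "LYS", "HIS")},
    **{r: "negative" for r in ("ASP", "GLU")},
}

#: heavy-atom van der Waals radii (nm), Bondi values
VDW_RADII: dict[str, float] = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
    "S": 0.180, "P": 0.180, "F": 0.147, "CL": 0.175,
}
DEFAULT_RADIUS = 0.170
PROBE_RADIUS = 0.14


@dataclass
class RMSFProfile:
    resids: np.ndarray
    chains: np.ndarray
    rmsf: np.ndarray          # nm, one per target residue
    fit_expression: str
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF must be nonnegative")


@dataclass
class SASASeries:
    times: np.ndarray         # ps
    raw: np.ndarray           # nm^2 per frame
    smoothed: np.ndarray      # nm^2, running average
    residue_set: tuple
    probe_radius: float
    class_filter: str | None

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.smoothed):
            raise ValueError("raw/smoothed length mismatch")
        if np.any(self.raw < 0):
            raise ValueError("SASA must be nonnegative")


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def _superpose_frames(
    positions: np.ndarray, fit_idx: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Batched Kabsch superposition of every frame onto a reference."""
    mob = positions[:, fit_idx]                     # (T, n, 3)
    cm = mob.mean(axis=1, keepdims=True)
    cr = reference.mean(axis=0)
    h = np.einsum("tni,nj->tij", mob - cm, reference - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("tij,tjk->tik", u, vt)))
    u[:, :, 2] *= d[:, None]
    rot = np.einsum("tij,tjk->tik", u, vt)          # mobile-row @ rot -> ref
    out = np.einsum("tni,tij->tnj", positions - cm, rot)
    return out + cr


def rmsf_profile(
    trajectory: Trajectory,
    fit_selection: AtomSelection | str | None = "name CA",
    target_selection: AtomSelection | str = "name CA",
) -> RMSFProfile:
    """Per-residue RMSF after rigid-body fitting.

    Frames are superposed onto their running mean structure (two fitting
    passes: first onto frame 0, then onto the resulting mean) using
    ``fit_selection``; RMSF_i = sqrt(<|r_i - <r_i>|^2>) is evaluated on
    the target atoms (one per residue, conventionally Calpha).  Pass
    ``fit_selection=None`` to skip the fit when the frames already share
    a reference frame (e.g. tethered synthetic systems); with very few
    fit atoms the superposition itself absorbs part of the fluctuation.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    top = trajectory.topology
    if isinstance(fit_selection, str):
        fit_selection = select(top, fit_selection, allow_empty=False)
    if isinstance(target_selection, str):
        target_selection = select(top, target_selection, allow_empty=False)
    pos = trajectory.positions
    if fit_selection is not None:
        fit_idx = fit_selection.indices
        aligned = _superpose_frames(pos, fit_idx, pos[0, fit_idx])
        mean = aligned.mean(axis=0)
        aligned = _superpose_frames(aligned, fit_idx, mean[fit_idx])
        fit_expr = fit_selection.expression
    else:
        aligned = pos
        fit_expr = "<none>"
    mean = aligned.mean(axis=0)
    tgt = target_selection.indices
    dev = aligned[:, tgt] - mean[tgt]
    rmsf = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))
    return RMSFProfile(
        resids=top.resids[tgt].copy(),
        chains=top.chainids[tgt].copy(),
        rmsf=rmsf,
        fit_expression=fit_expr,
    )


def average_rmsf_profiles(profiles: list[RMSFProfile]) -> RMSFProfile:
    """Average replicate RMSF profiles residue-by-residue."""
    if not profiles:
        raise ValueError("no profiles")
    first = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.resids, first.resids):
            raise ValueError("profiles cover different residues")
    return RMSFProfile(
        resids=first.resids.copy(),
        chains=first.chains.copy(),
        rmsf=np.mean([p.rmsf for p in profiles], axis=0),
        fit_expression=first.fit_expression,
        n_replicates=sum(p.n_replicates for p in profiles),
    )


# ---------------------------------------------------------------------------
# Polarity and SASA
# ---------------------------------------------------------------------------

def classify_polarity(residue_name: str, table: dict[str, str] | None = None) -> str:
    """Polarity class of a standard residue:
    hydrophobic / polar / positive / negative."""
    table = POLARITY_CLASSES if table is None else table
    key = residue_name.upper()
    if key not in table:
        raise ValueError(f"non-standard residue name: {residue_name!r}")
    return table[key]


def sphere_points(n: int = 960) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-section spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley(
    positions: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (nm^2), Shrake-Rupley.

    Each atom's solvent sphere (radius r_i + probe) is sampled at
    ``n_points`` quasi-uniform points; the accessible fraction is the
    fraction of points outside every neighbour's solvent sphere.
    """
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(positions)
    if radii.shape != (n,):
        raise ValueError("one radius per atom required")
    pts = sphere_points(n_points)
    solv = radii + probe_radius
    tree = cKDTree(positions)
    max_reach = 2.0 * solv.max()
    areas = np.empty(n)
    for i in range(n):
        neighbours = [
            j for j in tree.query_ball_point(positions[i], solv[i] + solv.max())
            if j != i
            and np.linalg.norm(positions[j] - positions[i]) < solv[i] + solv[j]
        ]
        surface = positions[i] + solv[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((surface - positions[j]) ** 2, axis=1)
            # strictly inside a neighbour sphere buries a point; exact
            # surface ties (degenerate coincident atoms) go to the
            # lower-index atom so overlapping duplicates are not
            # double-counted
            buried = d2 < solv[j] ** 2 - 1e-10
            if j < i:
                buried |= np.abs(d2 - solv[j] ** 2) <= 1e-10
            accessible &= ~buried
        areas[i] = 4.0 * np.pi * solv[i] ** 2 * accessible.mean()
    return areas


def _radii_for(topology: Topology) -> np.ndarray:
    return np.array(
        [VDW_RADII.get(e.upper(), DEFAULT_RADIUS) for e in topology.elements]
    )


def sasa_series(
    trajectory: Trajectory,
    cavity_residues,
    class_filter: str | None = "hydrophobic",
    probe_radius: float = PROBE_RADIUS,
    stride_ps: float = 10.0,
    window_ps: float = 1000.0,
    n_points: int = 960,
    polarity_table: dict[str, str] | None = None,
) -> SASASeries:
    """Summed SASA of cavity residues of one polarity class, per frame.

    ``cavity_residues`` is a list of resids or (chain, resid) pairs that
    line the cavity; the default filter keeps hydrophobic residues.  SASA is computed against all atoms in the topology, so
    occlusion by the rest of the protein is included.  Returns the raw
    10 ps series plus a 1 ns centred running average.
    """
    if not list(cavity_residues):
        raise ValueError("cavity residue list is empty")
    top = trajectory.topology
    mask = np.zeros(top.n_atoms, dtype=bool)
    for r in cavity_residues:
        chain, resid = r if isinstance(r, tuple) else (None, r)
        m = top.resids == resid
        if chain is not None:
            m &= top.chainids == chain
        if not np.any(m):
            raise ValueError(f"cavity residue {r} not in topology")
        mask |= m
    if class_filter is not None:
        for i in np.nonzero(mask)[0]:
            if classify_polarity(str(top.resnames[i]), polarity_table) != class_filter:
                mask[i] = False
    radii = _radii_for(top)
    spacing = trajectory.spacing
    if spacing > 0:
        step = round(stride_ps / spacing)
        if step < 1 or abs(stride_ps / spacing - step) > 1e-6:
            raise ValueError("stride incompatible with frame spacing")
    else:
        step = 1
    frames = np.arange(0, trajectory.n_frames, step)
    raw = np.empty(len(frames))
    for k, i in enumerate(frames):
        areas = shrake_rupley(
            trajectory.positions[i], radii, probe_radius, n_points
        )
        raw[k] = areas[mask].sum()
    times = trajectory.times[frames]
    dt = times[1] - times[0] if len(times) > 1 else stride_ps
    smoothed = running_average(raw, window_ps=window_ps, sample_ps=float(dt))
    return SASASeries(
        times=times,
        raw=raw,
        smoothed=smoothed,
        residue_set=tuple(cavity_residues),
        probe_radius=probe_radius,
        class_filter=class_filter,
    )


def running_average(
    series, window_ps: float = 1000.0, sample_ps: float = 10.0
) -> np.ndarray:
    """Centred running mean with symmetrically truncated edge windows.

    The window is ``window_ps / sample_ps`` samples wide.  Odd windows
    are symmetric about i; even windows take one extra sample on the
    trailing side.  Near the edges both sides shrink by the same amount,
    keeping the window centred.
    """
    v = np.asarray(series, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    if window_ps < sample_ps:
        raise ValueError("window must be at least one sampling interval")
    w = max(int(round(window_ps / sample_ps)), 1)
    lo0 = w // 2
    hi0 = w - 1 - lo0
    n = len(v)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    out = np.empty(n)
    for i in range(n):
        e = max(lo0 - i, hi0 - (n - 1 - i), 0)
        lo = max(lo0 - e, 0)
        hi = max(hi0 - e, 0)
        out[i] = (csum[i + hi + 1] - csum[i - lo]) / (lo + hi + 1)
    return out
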