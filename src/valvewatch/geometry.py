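"""Distance statistics for salt-bridge and valve geometry.

Distances use the minimum-image convention and are reported in nm.  Atom
pairs are given in a small spec language, ``"585:CD-426:CZ"``: residue
number, colon, atom name, for each endpoint.  Without chain qualifiers
the pair is resolved once per chain (the two transporter halves each get
a series); with qualifiers (``"A/554:CA-B/554:CA"``) a single cross-
chain series is produced.  Boxplot statistics follow the convention of
mean centre line, quartile box (inclusive linear interpolation) and
min/max whiskers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    AtomSelection,
    Frame,
    Topology,
    Trajectory,
    minimum_image_distance,
    select,
)

__all__ = [
    "PairSpec",
    "DistanceSeries",
    "BoxplotStats",
    "DistanceDistribution",
    "parse_pair_spec",
    "distance_series",
    "boxplot_stats",
    "distance_probability",
    "detect_salt_bridge",
    "valve_axial_shift",
    "superpose",
]

#: side-chain charged-group heavy atoms per residue type
CHARGED_GROUP_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
}

_ENDPOINT_RE = re.compile(r"^(?:(?P<chain>\w+)/)?(?P<resid>\d+):(?P<name>\w+'?)$")


@dataclass(frozen=True)
class PairSpec:
    resid_a: int
    name_a: str
    resid_b: int
    name_b: str
    chain_a: str | None = None
    chain_b: str | None = None

    @property
    def label(self) -> str:
        def side(chain, resid, name):
            return (f"{chain}/" if chain else "") + f"{resid}:{name}"

        return (
            side(self.chain_a, self.resid_a, self.name_a)
            + "-"
            + side(self.chain_b, self.resid_b, self.name_b)
        )


def parse_pair_spec(spec: str) -> PairSpec:
    """Parse ``"585:CD-426:CZ"`` or ``"A/585:CD-B/426:CZ"``."""
    parts = spec.split("-")
    if len(parts) != 2:
        raise ValueError(f"pair spec must have two endpoints: {spec!r}")
    ends = []
    for part in parts:
        m = _ENDPOINT_RE.match(part.strip())
        if m is None:
            raise ValueError(f"bad pair endpoint {part!r} (expected [CHAIN/]RESID:NAME)")
        ends.append(m)
    a, b = ends
    return PairSpec(
        resid_a=int(a["resid"]),
        name_a=a["name"],
        resid_b=int(b["resid"]),
        name_b=b["name"],
        chain_a=a["chain"],
        chain_b=b["chain"],
    )


@dataclass
class DistanceSeries:
    label: str
    times: np.ndarray       # ps
    distances: np.ndarray   # nm
    chain: str = ""
    construct: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.times) != len(self.distances):
            raise ValueError("times/distances length mismatch")
        if np.any(self.distances <= 0):
            raise ValueError("distances must be > 0")

    def __len__(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class BoxplotStats:
    mean: float
    q1: float
    q3: float
    minimum: float
    maximum: float
    n: int


@dataclass
class DistanceDistribution:
    bin_edges: np.ndarray     # nm, contiguous
    probability: np.ndarray   # sums to 1
    n: int
    per_series: list[np.ndarray] | None = None

    def mode_centers(self, min_probability: float = 0.0) -> np.ndarray:
        """Centres of local maxima of the probability histogram.

        ``min_probability`` suppresses noise peaks below that mass.
        """
        p = self.probability
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        if len(p) == 1:
            return centers
        peaks = []
        for i in range(len(p)):
            left = p[i - 1] if i > 0 else -np.inf
            right = p[i + 1] if i < len(p) - 1 else -np.inf
            if p[i] > max(min_probability, 0) and p[i] >= left and p[i] > right:
                peaks.append(i)
        return centers[peaks]


def _resolve_atom(
    topology: Topology, resid: int, name: str, chain: str | None
) -> int:
    expr = f"resid {resid} and name {name}"
    if chain:
        expr = f"chainID {chain} and " + expr
    sel = select(topology, expr)
    if len(sel) == 0:
        where = f"chain {chain}, " if chain else ""
        raise ValueError(
            f"cannot resolve atom {name} of residue {resid} ({where}is the "
            f"residue mutated or the name wrong?)"
        )
    if len(sel) > 1:
        raise ValueError(
            f"atom spec {resid}:{name} ({chain or 'any chain'}) is ambiguous: "
            f"{len(sel)} matches; add a chain qualifier"
        )
    return int(sel.indices[0])


def distance_series(
    trajectory: Trajectory,
    pair_spec: PairSpec | str,
    stride_ps: float = 1000.0,
    construct: str = "",
) -> list[DistanceSeries]:
    """Minimum-image distance time series for an atom pair.

    Default sampling is one point per ns.  Unqualified specs yield one
    series per chain containing the first endpoint's residue (the two
    transporter halves); fully qualified specs yield a single series.
    """
    if isinstance(pair_spec, str):
        pair_spec = parse_pair_spec(pair_spec)
    top = trajectory.topology
    spacing = trajectory.spacing
    if spacing <= 0:
        step = 1
    else:
        step = round(stride_ps / spacing)
        if step < 1 or abs(stride_ps / spacing - step) > 1e-6:
            raise ValueError(
                f"stride {stride_ps} ps incompatible with frame spacing {spacing} ps"
            )
    frames = np.arange(0, trajectory.n_frames, step)

    if pair_spec.chain_a or pair_spec.chain_b:
        chain_pairs = [(pair_spec.chain_a, pair_spec.chain_b)]
    else:
        seen: list[str] = []
        for c, r in zip(top.chainids, top.resids):
            if r == pair_spec.resid_a and c not in seen:
                seen.append(c)
        if not seen:
            raise ValueError(f"residue {pair_spec.resid_a} not present")
        chain_pairs = [(c, c) for c in seen]

    out = []
    for ca, cb in chain_pairs:
        ia = _resolve_atom(top, pair_spec.resid_a, pair_spec.name_a, ca)
        ib = _resolve_atom(top, pair_spec.resid_b, pair_spec.name_b, cb)
        d = minimum_image_distance(
            trajectory.positions[frames, ia],
            trajectory.positions[frames, ib],
            trajectory.boxes[frames],
        )
        out.append(
            DistanceSeries(
                label=pair_spec.label,
                times=trajectory.times[frames],
                distances=d,
                chain=ca or "",
                construct=construct,
            )
        )
    return out


def boxplot_stats(values) -> BoxplotStats:
    """Mean-centred boxplot statistics: quartile box, min/max whiskers.

    Quartiles use inclusive linear interpolation; the centre is the
    arithmetic mean (not the median).
    """
    if isinstance(values, DistanceSeries):
        values = values.distances
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    return BoxplotStats(
        mean=float(v.mean()),
        q1=float(q1),
        q3=float(q3),
        minimum=float(v.min()),
        maximum=float(v.max()),
        n=int(v.size),
    )


def distance_probability(
    series_list: list[DistanceSeries] | list[np.ndarray],
    bin_width: float = 0.05,
) -> DistanceDistribution:
    """Pooled, normalised distance histogram over replicate series."""
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    arrays = [
        s.distances if isinstance(s, DistanceSeries) else np.asarray(s, dtype=float)
        for s in series_list
    ]
    if not arrays:
        raise ValueError("no series supplied")
    pooled = np.concatenate(arrays)
    lo = np.floor(pooled.min() / bin_width) * bin_width
    hi = np.ceil(pooled.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(pooled, bins=edges)
    per = [np.histogram(a, bins=edges)[0] / max(len(a), 1) for a in arrays]
    return DistanceDistribution(
        bin_edges=edges,
        probability=counts / counts.sum(),
        n=int(pooled.size),
        per_series=per,
    )


def _charged_atoms(topology: Topology, resid: int, chain: str | None) -> AtomSelection:
    mask = topology.resids == resid
    if chain:
        mask &= topology.chainids == chain
    if not np.any(mask):
        raise ValueError(f"residue {resid} not found")
    resname = str(topology.resnames[mask][0])
    if resname not in CHARGED_GROUP_ATOMS:
        raise ValueError(
            f"residue {resid} ({resname}) is not a charged type; cannot test a salt bridge"
        )
    names = CHARGED_GROUP_ATOMS[resname]
    idx = np.nonzero(mask & np.isin(topology.names, names))[0]
    if len(idx) == 0:
        raise ValueError(
            f"residue {resid} ({resname}) has no charged-group heavy atoms "
            f"({'/'.join(names)}) in this topology"
        )
    return AtomSelection(indices=idx, expression=f"charged atoms of {resname}{resid}")


def detect_salt_bridge(
    traj_or_frame: Trajectory | Frame,
    residue_a: int | tuple[str, int],
    residue_b: int | tuple[str, int],
    cutoff: float = 0.4,
    topology: Topology | None = None,
) -> tuple[float, np.ndarray]:
    """Fraction of frames with a salt bridge, plus the min-distance series.

    Bridged means the minimum cross distance between side-chain charged
    heavy atoms (Arg/Lys N, Glu/Asp O) is below ``cutoff`` (nm).
    Symmetric in residue order.  A residue may be given as ``resid`` or
    ``(chain, resid)``.
    """
    if isinstance(traj_or_frame, Frame):
        if topology is None:
            raise ValueError("topology required when passing a single Frame")
        positions = traj_or_frame.positions[None]
        boxes = traj_or_frame.box[None]
        top = topology
    else:
        positions = traj_or_frame.positions
        boxes = traj_or_frame.boxes
        top = traj_or_frame.topology

    def _norm(r):
        return r if isinstance(r, tuple) else (None, r)

    ca, ra = _norm(residue_a)
    cb, rb = _norm(residue_b)
    sel_a = _charged_atoms(top, ra, ca)
    sel_b = _charged_atoms(top, rb, cb)
    n_frames = positions.shape[0]
    mins = np.empty(n_frames)
    for t in range(n_frames):
        pa = positions[t, sel_a.indices]
        pb = positions[t, sel_b.indices]
        d = minimum_image_distance(pa[:, None, :], pb[None, :, :], boxes[t])
        mins[t] = d.min()
    fraction = float(np.mean(mins < cutoff))
    return fraction, mins


def valve_cross_distances(
    topology: Topology,
    frame: Frame,
    resids: tuple[int, ...] = (554, 555),
    atom_name: str = "CA",
) -> dict[int, float]:
    """Cross-dimer distance per valve residue (nm).

    For each resid, the minimum-image distance between its ``atom_name``
    atoms in the first two chains that contain it — the valve-geometry
    measure used to compare inward- and outward-facing states.
    """
    out = {}
    for resid in resids:
        chains = []
        for c, r, n in zip(topology.chainids, topology.resids, topology.names):
            if r == resid and n == atom_name and c not in chains:
                chains.append(c)
        if len(chains) < 2:
            raise ValueError(
                f"residue {resid} ({atom_name}) not present in two chains"
            )
        ia = _resolve_atom(topology, resid, atom_name, chains[0])
        ib = _resolve_atom(topology, resid, atom_name, chains[1])
        out[resid] = float(
            minimum_image_distance(
                frame.positions[ia], frame.positions[ib], frame.box
            )
        )
    return out


def valve_backbone_gap(
    topology: Topology,
    frame: Frame,
    resids: tuple[int, ...] = (554, 555),
    backbone_names: tuple[str, ...] = ("N", "CA", "C", "O"),
) -> float:
    """Distance between the per-chain backbone centroids of the valve (nm).

    The valve "gap" is measured between the centroids of the backbone
    atoms of the di-leucine residues in each transporter half; both the
    residue window and the backbone atom set are configurable.
    """
    chains = []
    for c, r in zip(topology.chainids, topology.resids):
        if r in resids and c not in chains:
            chains.append(c)
    if len(chains) < 2:
        raise ValueError("valve residues not present in two chains")
    centroids = []
    for c in chains[:2]:
        mask = (
            (topology.chainids == c)
            & np.isin(topology.resids, resids)
            & np.isin(topology.names, backbone_names)
        )
        if not np.any(mask):
            raise ValueError(f"no backbone atoms for valve residues in chain {c}")
        centroids.append(frame.positions[mask].mean(axis=0))
    return float(minimum_image_distance(centroids[0], centroids[1], frame.box))


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation matrix, translation) such that
    ``mobile @ R.T + t`` best fits the reference (Kabsch).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("selection mismatch: point sets differ in shape")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cr, mobile - cm)
    r = rot.as_matrix()
    t = cr - cm @ r.T
    return r, t


def valve_axial_shift(
    structure_a: Frame,
    structure_b: Frame,
    valve_selection: AtomSelection,
    fit_selection: AtomSelection | None = None,
    axis: int = 2,
) -> float:
    """Signed axial displacement of the valve centroid between two states.

    When ``fit_selection`` is given (conventionally the transmembrane-
    domain Calpha atoms, which stay put while the valve moves), structure
    b is first least-squares superposed onto structure a on those atoms;
    without it the structures are taken as already sharing a frame of
    reference.  The return value is the difference of the valve centroids
    along ``axis`` (nm); positive means b sits higher.
    """
    if len(valve_selection) == 0:
        raise ValueError("valve selection is empty")
    if fit_selection is not None:
        r, t = superpose(
            structure_b.positions[fit_selection.indices],
            structure_a.positions[fit_selection.indices],
        )
        moved_b = structure_b.positions[valve_selection.indices] @ r.T + t
    else:
        moved_b = structure_b.positions[valve_selection.indices]
    ca = structure_a.positions[valve_selection.indices].mean(axis=0)
    cb = moved_b.mean(axis=0)
    return float((cb - ca)[axis])
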