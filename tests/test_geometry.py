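"""Distance series, boxplot statistics, salt bridges and axial shift."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from valvewatch import (
    boxplot_stats,
    detect_salt_bridge,
    distance_probability,
    distance_series,
    generate_distance_pair_system,
    generate_shifted_pair,
    valve_axial_shift,
)
from valvewatch.core import AtomSelection, Topology, Trajectory, select
from valvewatch.geometry import (
    parse_pair_spec,
    valve_backbone_gap,
    valve_cross_distances,
)

from conftest import make_water_system


class TestPairSpec:
    def test_basic(self):
        s = parse_pair_spec("585:CD-426:CZ")
        assert (s.resid_a, s.name_a, s.resid_b, s.name_b) == (585, "CD", 426, "CZ")
        assert s.chain_a is None

    def test_with_chains(self):
        s = parse_pair_spec("A/554:CA-B/554:CA")
        assert s.chain_a == "A" and s.chain_b == "B"

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            parse_pair_spec("585CD-426:CZ")


class TestDistanceSeries:
    def test_constant_pair(self):
        traj, _ = make_water_system(np.zeros((5, 1, 3)) + [1, 1, 1])
        series = distance_series(traj, "A/554:CA-B/554:CA", stride_ps=10.0)
        assert len(series) == 1
        assert np.allclose(series[0].distances, 1.0)  # scaffold chains 1 nm apart

    def test_gaussian_separation_recovered(self):
        traj, _ = generate_distance_pair_system([(1.0, 1.0, 0.05)], 5000, seed=8)
        (s,) = distance_series(traj, "1:CA-2:CA", stride_ps=1000.0)
        assert len(s) == 5000
        assert s.distances.mean() == pytest.approx(1.0, abs=0.01)

    def test_one_series_per_chain(self):
        traj, _ = make_water_system(np.zeros((4, 1, 3)) + [1, 1, 1])
        series = distance_series(traj, "554:CA-555:CA", stride_ps=10.0)
        assert [s.chain for s in series] == ["A", "B"]

    def test_mutated_atom_fails_loudly(self):
        traj, _ = make_water_system(np.zeros((2, 1, 3)) + [1, 1, 1])
        with pytest.raises(ValueError, match="residue 554"):
            distance_series(traj, "A/554:CZ-B/554:CZ", stride_ps=10.0)

    def test_replicate_point_count_bookkeeping(self):
        # 3 replicates x 2 halves x 150 samples = 900 points per construct
        traj, _ = make_water_system(
            np.zeros((150, 1, 3)) + [1, 1, 1], frame_spacing=1000.0
        )
        points = sum(
            len(s)
            for _ in range(3)
            for s in distance_series(traj, "554:CA-555:CA", stride_ps=1000.0)
        )
        assert points == 900


class TestBoxplotStats:
    def test_closed_form_five_values(self):
        b = boxplot_stats([1, 2, 3, 4, 5])
        assert (b.mean, b.q1, b.q3, b.minimum, b.maximum) == (3, 2, 4, 1, 5)

    def test_constant_series(self):
        b = boxplot_stats([2.5] * 7)
        assert b.mean == b.q1 == b.q3 == b.minimum == b.maximum == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_stats([])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0.1, 10, allow_nan=False), min_size=1, max_size=50))
    def test_against_sort_based_oracle(self, values):
        b = boxplot_stats(values)
        v = np.sort(np.asarray(values))
        n = len(v)
        # inclusive linear interpolation quartiles, computed by hand
        def quantile(q):
            h = (n - 1) * q
            lo = int(np.floor(h))
            return v[lo] + (h - lo) * (v[min(lo + 1, n - 1)] - v[lo])

        assert b.q1 == pytest.approx(quantile(0.25))
        assert b.q3 == pytest.approx(quantile(0.75))
        assert b.mean == pytest.approx(v.mean())   # centre is the mean, not median
        assert b.minimum == v[0] and b.maximum == v[-1]


class TestDistanceProbability:
    def test_unimodal_inward_like_valve(self):
        traj, _ = generate_distance_pair_system([(1.0, 1.05, 0.02)], 3000, seed=9)
        (s,) = distance_series(traj, "1:CA-2:CA", stride_ps=1000.0)
        dist = distance_probability([s], bin_width=0.1)
        modes = dist.mode_centers(min_probability=0.05)
        assert len(modes) == 1
        assert 1.0 <= modes[0] <= 1.1

    def test_bimodal_outward_like_valve(self):
        traj, _ = generate_distance_pair_system(
            [(0.5, 1.1, 0.03), (0.5, 1.5, 0.03)], 4000, seed=10
        )
        (s,) = distance_series(traj, "1:CA-2:CA", stride_ps=1000.0)
        dist = distance_probability([s], bin_width=0.05)
        centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        order = np.argsort(dist.probability)[::-1]
        first = centers[order[0]]
        second = next(centers[i] for i in order if abs(centers[i] - first) > 0.2)
        assert min(first, second) == pytest.approx(1.1, abs=0.075)
        assert max(first, second) == pytest.approx(1.5, abs=0.075)
        assert dist.bin_edges[0] >= 0.9 and dist.bin_edges[-1] <= 1.75

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        dist = distance_probability([rng.uniform(0.5, 2.0, 500)], bin_width=0.07)
        assert dist.probability.sum() == pytest.approx(1.0)

    def test_invariant_to_series_order(self):
        rng = np.random.default_rng(2)
        a, b, c = (rng.uniform(0.5, 2.0, 300) for _ in range(3))
        d1 = distance_probability([a, b, c], bin_width=0.05)
        d2 = distance_probability([c, a, b], bin_width=0.05)
        assert np.array_equal(d1.probability, d2.probability)


def _salt_bridge_system(min_distances):
    """ARG/GLU pair whose charged-group min distance follows a schedule."""
    top = Topology(
        names=np.array(["NE", "NH1", "NH2", "CZ", "OE1", "OE2", "CD"]),
        elements=np.array(["N", "N", "N", "C", "O", "O", "C"]),
        resids=np.array([426, 426, 426, 426, 585, 585, 585]),
        resnames=np.array(["ARG"] * 4 + ["GLU"] * 3),
        chainids=np.array(["A"] * 7),
    )
    n = len(min_distances)
    pos = np.zeros((n, 7, 3))
    pos[:, 0] = [5.0, 5.0, 5.0]            # NE: the closest approach atom
    pos[:, 1] = [5.0, 5.3, 5.0]
    pos[:, 2] = [5.0, 4.7, 5.0]
    pos[:, 3] = [4.8, 5.0, 5.0]
    for t, d in enumerate(min_distances):
        pos[t, 4] = [5.0 + d, 5.0, 5.0]    # OE1 at scheduled distance from NE
        pos[t, 5] = [5.0 + d + 0.22, 5.0, 5.0]
        pos[t, 6] = [5.0 + d + 0.13, 5.0, 5.0]
    boxes = np.tile([10.0, 10.0, 10.0], (n, 1))
    return Trajectory(top, pos, boxes, np.arange(n) * 10.0)


class TestSaltBridge:
    def test_close_pair_bridged(self):
        traj = _salt_bridge_system([0.30])
        fraction, mins = detect_salt_bridge(traj, 426, 585)
        assert fraction == 1.0
        assert mins[0] == pytest.approx(0.30)

    def test_far_pair_not_bridged(self):
        traj = _salt_bridge_system([0.80])
        fraction, _ = detect_salt_bridge(traj, 426, 585)
        assert fraction == 0.0

    def test_dwell_fraction_recovered_exactly(self):
        # 3 of 10 frames below the 0.4 nm cutoff
        schedule = [0.3, 0.8, 0.3, 0.8, 0.8, 0.3, 0.8, 0.8, 0.8, 0.8]
        traj = _salt_bridge_system(schedule)
        fraction, _ = detect_salt_bridge(traj, 426, 585)
        assert fraction == pytest.approx(0.3)

    def test_symmetric_in_residue_order(self):
        traj = _salt_bridge_system([0.3, 0.8, 0.5])
        fa, ma = detect_salt_bridge(traj, 426, 585)
        fb, mb = detect_salt_bridge(traj, 585, 426)
        assert fa == fb
        assert np.allclose(ma, mb)

    def test_uncharged_residue_rejected(self):
        traj, _ = make_water_system(np.zeros((2, 1, 3)) + 1.0)
        with pytest.raises(ValueError, match="554"):
            detect_salt_bridge(traj, 554, 555)


class TestValveAxialShift:
    @pytest.fixture(scope="class")
    def base(self):
        # several non-collinear waters double as a usable fit reference
        waters = np.array([
            [1.0, 1.0, 1.0], [2.0, 1.5, 1.2], [1.5, 2.5, 2.0],
            [0.8, 1.8, 2.6], [2.4, 2.2, 0.9],
        ])
        traj, ns = make_water_system(waters, n_frames=2)
        valve = select(traj.topology, "resid 554-555 and name CA")
        return traj.frame(0), valve

    def test_identical_structures_zero(self, base):
        frame, valve = base
        assert valve_axial_shift(frame, frame, valve) == pytest.approx(0.0)

    def test_pure_axial_shift_recovered(self, base):
        frame, valve = base
        a, b, _ = generate_shifted_pair(frame, (0, 0, 0.3))
        assert valve_axial_shift(a, b, valve) == pytest.approx(0.30)

    def test_axial_projection_of_oblique_shift(self, base):
        frame, valve = base
        a, b, _ = generate_shifted_pair(frame, (0.1, 0.0, 0.3))
        assert valve_axial_shift(a, b, valve) == pytest.approx(0.30)

    def test_alignment_on_static_reference(self, base):
        # valve moves up 0.3 nm while the reference stays put; aligning on
        # the reference must still report the valve shift
        frame, valve = base
        moved = frame.positions.copy()
        moved[valve.indices] += [0.0, 0.0, 0.3]
        from valvewatch.core import Frame

        b = Frame(moved, frame.box.copy())
        ref = AtomSelection(
            indices=np.setdiff1d(np.arange(frame.positions.shape[0]), valve.indices),
            expression="reference",
        )
        shift = valve_axial_shift(frame, b, valve, fit_selection=ref)
        assert shift == pytest.approx(0.30, abs=1e-9)


class TestStaticValveMeasures:
    def test_cross_dimer_distances(self):
        traj, _ = make_water_system(np.zeros((1, 1, 3)) + 1.0)
        d = valve_cross_distances(traj.topology, traj.frame(0))
        # scaffold chains sit 1.0 nm apart laterally
        assert d[554] == pytest.approx(1.0)
        assert d[555] == pytest.approx(1.0)

    def test_backbone_gap(self):
        traj, _ = make_water_system(np.zeros((1, 1, 3)) + 1.0)
        gap = valve_backbone_gap(
            traj.topology, traj.frame(0), backbone_names=("CA",)
        )
        assert gap == pytest.approx(1.0)
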