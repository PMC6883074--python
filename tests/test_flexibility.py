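"""RMSF, polarity classes, Shrake-Rupley SASA and running averages."""

import numpy as np
import pytest

from valvewatch import (
    classify_polarity,
    generate_tethered_system,
    rmsf_profile,
    running_average,
    shrake_rupley,
)
from valvewatch.core import Topology, Trajectory
from valvewatch.flexibility import (
    average_rmsf_profiles,
    sasa_series,
    sphere_points,
)


def mc_sasa(positions, radii, probe, n_samples=40_000, seed=0):
    """Monte-Carlo surface-point oracle: random points on each solvent
    sphere, accessible if strictly outside every other solvent sphere."""
    rng = np.random.default_rng(seed)
    solv = np.asarray(radii) + probe
    areas = np.empty(len(positions))
    for i, (c, r) in enumerate(zip(positions, solv)):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = c + r * v
        ok = np.ones(n_samples, dtype=bool)
        for j, (cj, rj) in enumerate(zip(positions, solv)):
            if j == i:
                continue
            ok &= np.sum((pts - cj) ** 2, axis=1) >= rj ** 2
        areas[i] = 4 * np.pi * r ** 2 * ok.mean()
    return areas


class TestRMSF:
    def test_rigid_trajectory_zero(self):
        traj, _ = generate_tethered_system([0.0, 0.0, 0.0], 100, seed=1)
        prof = rmsf_profile(traj, None, "name CA")
        assert np.all(prof.rmsf <= 1e-6)

    def test_tethered_recovery_sqrt3_sigma(self):
        sigmas = [0.02, 0.05, 0.10]
        traj, _ = generate_tethered_system(sigmas, 5000, seed=2)
        prof = rmsf_profile(traj, None, "name CA")
        assert prof.rmsf == pytest.approx(np.sqrt(3) * np.asarray(sigmas), rel=0.05)

    def test_sigma_ordering_preserved(self):
        sigmas = [0.03, 0.06, 0.12]
        traj, _ = generate_tethered_system(sigmas, 2000, seed=3)
        prof = rmsf_profile(traj, "name CA", "name CA")
        assert np.all(np.diff(prof.rmsf) > 0)

    def test_invariant_to_rigid_body_motion(self):
        # adding a per-frame rigid rotation+translation changes nothing
        # once the fit removes it
        from scipy.spatial.transform import Rotation

        sigmas = np.repeat([0.02, 0.05, 0.10], 10)
        traj, _ = generate_tethered_system(sigmas, 300, seed=4)
        rng = np.random.default_rng(5)
        pos = np.empty_like(traj.positions)
        for t in range(traj.n_frames):
            r = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
            pos[t] = traj.positions[t] @ r.T + rng.uniform(-1, 1, 3)
        moved = Trajectory(traj.topology, pos, traj.boxes, traj.times)
        a = rmsf_profile(traj, "name CA", "name CA")
        b = rmsf_profile(moved, "name CA", "name CA")
        assert np.allclose(a.rmsf, b.rmsf, atol=1e-9)

    def test_replicate_averaging(self):
        profs = [
            rmsf_profile(generate_tethered_system([0.05, 0.08], 500, seed=s)[0],
                         None, "name CA")
            for s in (6, 7, 8)
        ]
        avg = average_rmsf_profiles(profs)
        assert avg.n_replicates == 3
        assert avg.rmsf == pytest.approx(np.mean([p.rmsf for p in profs], axis=0))

    def test_too_few_frames_rejected(self):
        traj, _ = generate_tethered_system([0.05], 1, seed=1)
        with pytest.raises(ValueError):
            rmsf_profile(traj, None, "name CA")


class TestPolarity:
    @pytest.mark.parametrize("resname,expected", [
        ("LEU", "hydrophobic"), ("ALA", "hydrophobic"), ("TRP", "hydrophobic"),
        ("SER", "polar"), ("GLY", "polar"), ("CYS", "polar"),
        ("ARG", "positive"), ("LYS", "positive"),
        ("GLU", "negative"), ("ASP", "negative"),
    ])
    def test_standard_table(self, resname, expected):
        assert classify_polarity(resname) == expected

    def test_all_twenty_covered(self):
        from valvewatch.flexibility import POLARITY_CLASSES

        assert len(POLARITY_CLASSES) == 20

    def test_nonstandard_rejected(self):
        with pytest.raises(ValueError):
            classify_polarity("XYZ")


class TestShrakeRupley:
    def test_isolated_sphere_closed_form(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([0.19]), probe_radius=0.14)
        exact = 4 * np.pi * (0.19 + 0.14) ** 2
        assert area[0] == pytest.approx(exact, rel=0.02)

    def test_coincident_spheres_fully_occlude(self):
        areas = shrake_rupley(np.zeros((2, 3)), np.array([0.19, 0.19]), 0.14)
        single = 4 * np.pi * 0.33 ** 2
        assert areas.sum() == pytest.approx(single, rel=0.02)

    def test_two_spheres_match_monte_carlo(self):
        pos = np.array([[0.0, 0.0, 0.0], [0.35, 0.0, 0.0]])
        radii = np.array([0.17, 0.17])
        got = shrake_rupley(pos, radii, 0.14)
        ref = mc_sasa(pos, radii, 0.14, seed=1)
        assert got.sum() == pytest.approx(ref.sum(), rel=0.03)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_toys_match_monte_carlo(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 6)
        pos = rng.uniform(0, 0.5, (n, 3))
        radii = rng.uniform(0.12, 0.2, n)
        got = shrake_rupley(pos, radii, 0.14)
        ref = mc_sasa(pos, radii, 0.14, seed=seed + 100)
        assert got.sum() == pytest.approx(ref.sum(), rel=0.03)

    def test_sphere_points_unit_norm(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.abs(pts.mean(axis=0)).max() < 0.01  # quasi-uniform


def _ring_system(radii_per_frame, n_ring=8):
    """A hydrophobic ring of LEU side-chain carbons expanding over time."""
    frames = len(radii_per_frame)
    theta = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    pos = np.empty((frames, n_ring, 3))
    for t, r in enumerate(radii_per_frame):
        pos[t, :, 0] = 5.0 + r * np.cos(theta)
        pos[t, :, 1] = 5.0 + r * np.sin(theta)
        pos[t, :, 2] = 5.0
    top = Topology(
        names=np.array(["CD1"] * n_ring),
        elements=np.array(["C"] * n_ring),
        resids=np.arange(1, n_ring + 1),
        resnames=np.array(["LEU"] * n_ring),
        chainids=np.array(["A"] * n_ring),
    )
    boxes = np.tile([10.0, 10.0, 10.0], (frames, 1))
    return Trajectory(top, pos, boxes, np.arange(frames) * 10.0)


class TestSASASeries:
    def test_cavity_opening_doubles_hydrophobic_sasa(self):
        # scripted radial expansion of a hydrophobic ring: the smoothed
        # hydrophobic surface area must rise monotonically and at least 2x
        radii = np.linspace(0.22, 0.9, 40)
        traj = _ring_system(radii)
        s = sasa_series(traj, list(range(1, 9)), stride_ps=10.0, window_ps=50.0)
        assert np.all(np.diff(s.smoothed) >= -1e-9)
        assert s.smoothed[-1] >= 2.0 * s.smoothed[0]

    def test_class_filter_subset_monotone(self):
        radii = np.linspace(0.3, 0.5, 5)
        traj = _ring_system(radii)
        hydrophobic = sasa_series(traj, list(range(1, 9)), class_filter="hydrophobic",
                                  stride_ps=10.0, window_ps=10.0)
        total = sasa_series(traj, list(range(1, 9)), class_filter=None,
                            stride_ps=10.0, window_ps=10.0)
        assert np.all(total.raw >= hydrophobic.raw - 1e-12)

    def test_empty_cavity_list_rejected(self):
        traj = _ring_system([0.3])
        with pytest.raises(ValueError):
            sasa_series(traj, [])


class TestRunningAverage:
    def test_constant_unchanged(self):
        out = running_average(np.full(50, 3.3), window_ps=1000.0, sample_ps=10.0)
        assert np.allclose(out, 3.3)

    def test_alternating_with_even_window_cancels(self):
        v = np.tile([1.0, -1.0], 20)
        out = running_average(v, window_ps=40.0, sample_ps=10.0)  # 4 samples
        interior = out[2:-2]
        assert np.allclose(interior, 0.0)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=4000)
        out = running_average(v, window_ps=210.0, sample_ps=10.0)  # 21 samples
        assert out[30:-30].var() == pytest.approx(v.var() / 21, rel=0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            running_average([], window_ps=100.0)

    def test_window_below_sampling_rejected(self):
        with pytest.raises(ValueError):
            running_average([1.0, 2.0], window_ps=5.0, sample_ps=10.0)
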