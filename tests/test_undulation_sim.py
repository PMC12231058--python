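"""Monte Carlo restricted diffusion in undulating tubes.

Analytic oracles: free 1D diffusion (axial MSD), uniform-disc confinement
(transverse MSD plateau), the Gaussian-phase (van Gelderen) cylinder signal,
and a brute-force nearest-centerline distance search for the geometry.
"""

import numpy as np
import pytest
from scipy.special import jnp_zeros
from scipy.stats import kstest

from alpsim.io_formats import GradientScheme
from alpsim.undulation_sim import (
    MICRO_SUBSTRATE,
    PGSEProtocol,
    WalkerParams,
    build_substrate,
    simulate_walk,
    synthesize_pgse_signal,
    undulation_asymmetry,
)


def brute_force_distance(sub, points, n_grid=200_001):
    """Dense scan of the centerline parameter (independent of the package's
    Newton-refined search)."""
    out = []
    for p in points:
        half = abs(p[0]) + sub.A + 2.0
        t = np.linspace(p[2] - half, p[2] + half, n_grid)
        d2 = (p[0] - sub.A * np.sin(sub.omega * t)) ** 2 + p[1] ** 2 + (p[2] - t) ** 2
        out.append(np.sqrt(d2.min()))
    return np.array(out)


class TestSubstrateGeometry:
    def test_straight_cylinder_membership(self):
        sub = build_substrate(d=1.0, L=24.0, A=0.0)
        assert sub.inside(np.array([[0.4, 0.0, 3.0]]))[0]
        assert not sub.inside(np.array([[0.6, 0.0, 3.0]]))[0]

    def test_centerline_point_inside_micro(self):
        sub = build_substrate(**MICRO_SUBSTRATE)
        # centerline at z = L/4: x = A
        assert sub.inside(np.array([[4.0, 0.0, 6.0]]))[0]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            build_substrate(d=-1.0, L=24.0, A=4.0)
        with pytest.raises(ValueError, match="self-intersect"):
            build_substrate(d=10.0, L=24.0, A=4.0)

    def test_distance_matches_brute_force(self, rng):
        sub = build_substrate(**MICRO_SUBSTRATE)
        pts = np.column_stack(
            [
                rng.uniform(-6, 6, 40),
                rng.uniform(-1.5, 1.5, 40),
                rng.uniform(0, 24, 40),
            ]
        )
        fast = sub.distance_to_centerline(pts)
        slow = brute_force_distance(sub, pts)
        np.testing.assert_allclose(fast, slow, atol=1e-6)
        np.testing.assert_array_equal(sub.inside(pts), slow <= sub.radius + 1e-12)


class TestWalk:
    def test_free_axial_msd(self):
        sub = build_substrate(d=1.0, L=24.0, A=0.0)
        params = WalkerParams(n_walkers=100_000, d0=2.0, seed=3)
        T = 5.0
        walk = simulate_walk(sub, params, total_time=T, record_msd=True)
        msd_z = walk.msd[-1, 0]
        assert msd_z == pytest.approx(2.0 * params.d0 * T, rel=0.02)

    def test_transverse_confinement_plateau(self):
        d = 4.0
        sub = build_substrate(d=d, L=24.0, A=0.0)
        params = WalkerParams(n_walkers=30_000, d0=2.0, seed=4)
        T = 10 * d**2 / params.d0
        walk = simulate_walk(sub, params, total_time=T, record_msd=True)
        # two independent uniform-disc coordinates per axis: plateau d^2 / 8
        # per transverse axis, i.e. d^2 / 4 for x + y jointly
        msd_xy = walk.msd[-1, 1]
        assert msd_xy == pytest.approx(d**2 / 4.0, rel=0.03)

    def test_equilibrium_positions_uniform(self):
        d = 4.0
        sub = build_substrate(d=d, L=24.0, A=0.0)
        params = WalkerParams(n_walkers=8_000, d0=2.0, seed=5)
        walk = simulate_walk(sub, params, total_time=40.0)
        r2 = walk.positions[:, 0] ** 2 + walk.positions[:, 1] ** 2
        # r^2 of a uniform disc is uniform on [0, radius^2]
        stat = kstest(r2 / sub.radius**2, "uniform")
        assert stat.pvalue > 0.01
        assert walk.n_rejected <= 0.001 * params.n_walkers * walk.n_steps

    def test_step_length_invariant_enforced(self):
        sub = build_substrate(d=1.0, L=24.0, A=0.0)
        with pytest.raises(ValueError, match="RMS step"):
            WalkerParams(n_walkers=10, d0=2.0, dt=1.0).resolve_dt(sub)


def gpd_cylinder_perpendicular(radius, d0, delta, Delta, b_ms):
    """van Gelderen Gaussian-phase attenuation, gradient perpendicular to an
    infinite cylinder; independent closed-form oracle."""
    q2 = b_ms / (Delta - delta / 3.0)  # (gamma G delta)^2
    g2 = q2 / delta**2  # (gamma G)^2
    roots = jnp_zeros(1, 60)
    am = roots / radius
    s = 0.0
    for a in am:
        a2 = a * a
        da2 = d0 * a2
        num = (
            2.0 * da2 * delta
            - 2.0
            + 2.0 * np.exp(-da2 * delta)
            + 2.0 * np.exp(-da2 * Delta)
            - np.exp(-da2 * (Delta - delta))
            - np.exp(-da2 * (Delta + delta))
        )
        s += num / (d0**2 * a2**3 * (a2 * radius**2 - 1.0))
    return np.exp(-2.0 * g2 * s)


class TestPGSESignal:
    @pytest.fixture(scope="class")
    def cylinder_walk(self):
        sub = build_substrate(d=4.0, L=24.0, A=0.0)
        scheme = GradientScheme(
            [0.0, 1000.0, 2000.0, 500.0, 1000.0],
            [[0, 0, 0], [1.0, 0, 0], [1.0, 0, 0], [0, 0, 1.0], [0, 0, 1.0]],
        )
        protocol = PGSEProtocol(scheme, delta=10.6, Delta=43.1)
        params = WalkerParams(n_walkers=150_000, d0=2.0, seed=6)
        walk = simulate_walk(sub, params, protocol=protocol)
        return sub, protocol, walk

    def test_zero_gradient_unity(self, cylinder_walk):
        _, protocol, walk = cylinder_walk
        e = synthesize_pgse_signal(walk, protocol)
        assert e[0] == pytest.approx(1.0, abs=1e-12)

    def test_perpendicular_matches_gpd(self, cylinder_walk):
        sub, protocol, walk = cylinder_walk
        e = synthesize_pgse_signal(walk, protocol)
        for idx, b_si in ((1, 1000.0), (2, 2000.0)):
            expected = gpd_cylinder_perpendicular(
                sub.radius, 2.0, walk.delta_eff, walk.Delta_eff, b_si / 1000.0
            )
            assert e[idx] == pytest.approx(expected, rel=0.05)

    def test_parallel_is_free_diffusion(self, cylinder_walk):
        _, protocol, walk = cylinder_walk
        e = synthesize_pgse_signal(walk, protocol)
        for idx, b_si in ((3, 500.0), (4, 1000.0)):
            assert e[idx] == pytest.approx(np.exp(-b_si / 1000.0 * 2.0), rel=0.03)

    def test_protocol_b_q_consistency(self):
        protocol = PGSEProtocol.hcp_ya()
        q = protocol.q_per_um
        b = q**2 * (protocol.Delta - protocol.delta / 3.0)
        np.testing.assert_allclose(b, protocol.b_ms_um2, rtol=1e-12)


class TestUndulationAsymmetry:
    @pytest.fixture(scope="class")
    def short_protocol(self):
        # HCP-YA directions, one shell per b to keep fits cheap
        from alpsim.io_formats import make_scheme

        return PGSEProtocol(make_scheme({1000.0: 45, 3000.0: 45}, n_b0=4))

    def test_straight_tube_is_symmetric(self, short_protocol):
        sub = build_substrate(d=6.0, L=24.0, A=0.0)
        table = undulation_asymmetry(
            sub, short_protocol, WalkerParams(n_walkers=20_000, seed=7)
        )
        assert np.all(np.abs(table["asymmetry"] - 1.0) < 0.2)

    def test_asymmetry_increases_with_amplitude(self, short_protocol):
        vals = []
        for A in (1.0, 3.0):
            sub = build_substrate(d=1.0, L=24.0, A=A)
            table = undulation_asymmetry(
                sub, short_protocol, WalkerParams(n_walkers=10_000, seed=8)
            )
            vals.append(table["asymmetry"].mean())
        assert vals[1] > vals[0]

    def test_undulation_plane_attenuates_more_than_through_plane(self):
        sub = build_substrate(**MICRO_SUBSTRATE)
        scheme = GradientScheme(
            [0.0, 1000.0, 1000.0, 3000.0, 3000.0],
            [[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [1.0, 0, 0], [0, 1.0, 0]],
        )
        protocol = PGSEProtocol(scheme)
        walk = simulate_walk(sub, WalkerParams(n_walkers=15_000, seed=9), protocol=protocol)
        e = synthesize_pgse_signal(walk, protocol)
        assert e[1] < e[2]  # b=1000: x attenuates more than y
        assert e[3] < e[4]  # b=3000 likewise

    def test_same_seed_reproducible(self, short_protocol):
        sub = build_substrate(d=2.0, L=24.0, A=2.0)
        runs = [
            simulate_walk(sub, WalkerParams(n_walkers=500, seed=11), protocol=short_protocol)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].positions, runs[1].positions)
        np.testing.assert_array_equal(runs[0].s1, runs[1].s1)
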