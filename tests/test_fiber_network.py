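import math

import numpy as np
import pytest

from percaf import (
    InfeasibleProfileError,
    LatticeSpec,
    Lesion,
    apply_lesion,
    assign_block_susceptible,
    build_network,
    build_profile,
    find_isolated_segments,
    layer_couplings,
    load_network,
    percolates,
    save_network,
)
from conftest import bfs_reachable, reentry_fixture


class TestLayerCouplings:
    @pytest.mark.parametrize(
        "nu_bar,theta,expected",
        [
            (0.30, 45.0, (0.30, 0.30)),  # tan 45 = 1 forces nu_perp = nu_par
            (0.33, 24.0, (0.5236827951729215, 0.23315860241353928)),
            (0.33, 42.0, (0.3534694162127988, 0.31826529189360053)),
        ],
    )
    def test_examples(self, nu_bar, theta, expected):
        nu_par, nu_perp = layer_couplings(nu_bar, theta)
        assert nu_par == pytest.approx(expected[0], abs=1e-10)
        assert nu_perp == pytest.approx(expected[1], abs=1e-10)

    @pytest.mark.parametrize("nu_bar", [0.1, 0.25, 0.33, 0.5])
    @pytest.mark.parametrize("theta", [10.0, 24.0, 42.0, 60.0, 89.0])
    def test_defining_identities(self, nu_bar, theta):
        """The returned pair must satisfy both defining relations; grid
        points whose solution needs a probability above 1 must raise."""
        if 3 * nu_bar / (1 + 2 * math.tan(math.radians(theta))) > 1.0:
            with pytest.raises(InfeasibleProfileError):
                layer_couplings(nu_bar, theta)
            return
        nu_par, nu_perp = layer_couplings(nu_bar, theta)
        assert (2 * nu_par + 4 * nu_perp) / 6 == pytest.approx(nu_bar, abs=1e-10)
        assert math.degrees(math.atan2(nu_perp, nu_par)) == pytest.approx(
            theta, abs=1e-8
        )

    def test_infeasible(self):
        with pytest.raises(InfeasibleProfileError):
            layer_couplings(0.5, 0.0)  # nu_par = 3 nu_bar > 1

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            layer_couplings(1.2, 30.0)
        with pytest.raises(ValueError):
            layer_couplings(0.3, 95.0)


class TestBuildProfile:
    def test_homogeneous_full(self):
        spec = LatticeSpec(5, 5, 25)
        p = build_profile(spec, "homogeneous", nu_par=1.0, nu_perp=1.0)
        assert np.all(p.nu_par == 1.0) and np.all(p.nu_perp == 1.0)

    def test_inhomogeneous_endpoints_and_identity(self):
        spec = LatticeSpec(5, 5, 25)
        p = build_profile(
            spec, "inhomogeneous", nu_bar=0.33, theta_endo=24.0, theta_epi=42.0
        )
        lo = layer_couplings(0.33, 24.0)
        hi = layer_couplings(0.33, 42.0)
        assert p.nu_par[0] == pytest.approx(lo[0]) and p.nu_perp[0] == pytest.approx(lo[1])
        assert p.nu_par[24] == pytest.approx(hi[0]) and p.nu_perp[24] == pytest.approx(hi[1])
        # fixed mean coupling in every layer, to 1e-12
        assert np.allclose(p.mean_coupling, 0.33, atol=1e-12)
        # angle varies monotonically endo -> epi
        angles = np.degrees(np.arctan2(p.nu_perp, p.nu_par))
        assert np.all(np.diff(angles) > 0)

    def test_degenerate_angles_match_homogeneous(self):
        spec = LatticeSpec(5, 5, 10)
        p = build_profile(
            spec, "inhomogeneous", nu_bar=0.3, theta_endo=30.0, theta_epi=30.0
        )
        nu_par, nu_perp = layer_couplings(0.3, 30.0)
        assert np.allclose(p.nu_par, nu_par) and np.allclose(p.nu_perp, nu_perp)


class TestBuildNetwork:
    def test_full_and_empty(self, small_spec):
        pf = build_profile(small_spec, "homogeneous", nu_par=1.0, nu_perp=1.0)
        net = build_network(small_spec, pf, 0)
        assert net.bond_x[:-1].all() and not net.bond_x[-1].any()
        assert net.bond_y.all()
        assert net.bond_z[:, :, :-1].all() and not net.bond_z[:, :, -1].any()
        pf0 = build_profile(small_spec, "homogeneous", nu_par=0.0, nu_perp=0.0)
        net0 = build_network(small_spec, pf0, 0)
        assert not (net0.bond_x.any() or net0.bond_y.any() or net0.bond_z.any())

    def test_bond_density_binomial(self):
        spec = LatticeSpec(50, 50, 50)
        pf = build_profile(spec, "homogeneous", nu_par=0.5, nu_perp=0.25)
        net = build_network(spec, pf, 42)
        n = 49 * 50 * 50
        k = int(net.bond_x[:-1].sum())
        sigma = math.sqrt(n * 0.5 * 0.5)
        assert abs(k - 0.5 * n) < 4 * sigma
        m = 50 * 50 * 50
        ky = int(net.bond_y.sum())
        assert abs(ky - 0.25 * m) < 4 * math.sqrt(m * 0.25 * 0.75)

    def test_seed_determinism(self, small_spec):
        pf = build_profile(small_spec, "homogeneous", nu_par=0.5, nu_perp=0.3)
        a = build_network(small_spec, pf, 7)
        b = build_network(small_spec, pf, 7)
        c = build_network(small_spec, pf, 8)
        assert np.array_equal(a.bond_x, b.bond_x)
        assert np.array_equal(a.bond_y, b.bond_y)
        assert np.array_equal(a.bond_z, b.bond_z)
        assert not np.array_equal(a.bond_x, c.bond_x)

    def test_per_layer_densities_follow_profile(self):
        spec = LatticeSpec(60, 60, 25)
        pf = build_profile(spec, "inhomogeneous", nu_bar=0.33)
        net = build_network(spec, pf, 3)
        for z in (0, 12, 24):
            n = 59 * 60
            k = int(net.bond_x[:-1, :, z].sum())
            p = pf.nu_par[z]
            assert abs(k - p * n) < 4 * math.sqrt(n * p * (1 - p))


class TestBlockMask:
    def test_extremes(self, full_network):
        assert not assign_block_susceptible(full_network, 0.0, 0).susceptible.any()
        assert assign_block_susceptible(full_network, 1.0, 0).susceptible.all()

    def test_density(self):
        spec = LatticeSpec(50, 50, 40)
        pf = build_profile(spec, "homogeneous", nu_par=1.0, nu_perp=1.0)
        net = assign_block_susceptible(build_network(spec, pf, 0), 0.05, 9)
        n = spec.n_nodes
        k = int(net.susceptible.sum())
        assert abs(k - 0.05 * n) < 4 * math.sqrt(n * 0.05 * 0.95)


class TestLesion:
    def test_full_lesion_removes_all_bonds(self, full_network):
        spec = full_network.spec
        lesion = Lesion(0, spec.L_x - 1, 0, spec.L_y - 1, spec.L_z)
        out = apply_lesion(full_network, lesion)
        assert not (out.bond_x.any() or out.bond_y.any() or out.bond_z.any())
        # original untouched
        assert full_network.bond_x[:-1].all()

    def test_empty_intersection_is_noop_and_idempotent(self, full_network):
        lesion = Lesion(5, 7, 2, 4, 2)
        once = apply_lesion(full_network, lesion)
        twice = apply_lesion(once, lesion)
        for name in ("bond_x", "bond_y", "bond_z"):
            assert np.array_equal(getattr(once, name), getattr(twice, name))
        # bonds outside the lesion neighbourhood survive
        assert once.bond_x[10:, :, :].all() == full_network.bond_x[10:, :, :].all()

    def test_lesions_commute(self, full_network):
        l1 = Lesion(2, 6, 1, 3, 3)
        l2 = Lesion(4, 9, 2, 6, 5)
        a = apply_lesion(apply_lesion(full_network, l1), l2)
        b = apply_lesion(apply_lesion(full_network, l2), l1)
        for name in ("bond_x", "bond_y", "bond_z"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_wrapping_footprint(self, full_network):
        spec = full_network.spec
        lesion = Lesion(0, 2, spec.L_y - 2, spec.L_y + 1, spec.L_z)
        mask = lesion.node_mask(spec)
        assert mask[0, spec.L_y - 1, 0] and mask[0, 0, 0] and mask[0, 1, 0]
        assert not mask[0, 2, 0]

    def test_out_of_bounds(self, full_network):
        with pytest.raises(ValueError):
            apply_lesion(full_network, Lesion(-1, 2, 0, 1, 1))
        with pytest.raises(ValueError):
            apply_lesion(full_network, Lesion(0, 2, 0, 1, 99))


class TestPercolation:
    def test_trivial(self, full_network, small_spec):
        assert percolates(full_network)
        pf0 = build_profile(small_spec, "homogeneous", nu_par=0.0, nu_perp=0.0)
        assert not percolates(build_network(small_spec, pf0, 0))

    @pytest.mark.parametrize("seed", range(20))
    def test_against_flood_fill_oracle(self, seed):
        spec = LatticeSpec(5, 5, 5)
        p = 0.15 + 0.5 * (seed % 5) / 4
        pf = build_profile(spec, "homogeneous", nu_par=p, nu_perp=p)
        net = build_network(spec, pf, seed)
        sources = [(0, y, z) for y in range(5) for z in range(5)]
        reach = bfs_reachable(net, sources)
        expected = any((4, y, z) in reach for y in range(5) for z in range(5))
        assert percolates(net) == expected

    def test_monotone_in_coupling(self):
        """With common random numbers, bond sets are nested in the coupling,
        so percolation can only switch off -> on as nu_par grows."""
        spec = LatticeSpec(12, 12, 12)
        for seed in range(10):
            last = False
            for p in (0.1, 0.2, 0.3, 0.5, 0.8):
                pf = build_profile(spec, "homogeneous", nu_par=p, nu_perp=0.2)
                now = percolates(build_network(spec, pf, seed))
                assert now or not last
                last = now


class TestIsolatedSegments:
    def test_full_lattice_has_none(self, full_network):
        report = find_isolated_segments(full_network, tau=50)
        assert report.segments == ()
        assert report.percolates

    @pytest.mark.parametrize("length,flagged", [(30, True), (20, False)])
    def test_engineered_fiber(self, length, flagged):
        fx = reentry_fixture(length)
        report = find_isolated_segments(fx.network, tau=50)
        assert len(report.segments) == 1
        seg = report.segments[0]
        assert (seg.x0, seg.y, seg.z, seg.length) == (20, 6, 0, length)
        assert (seg in report.reentry_capable) == flagged
        assert report.n_reentry_capable == (1 if flagged else 0)

    def test_lesion_removes_segment_from_census(self):
        fx = reentry_fixture(30)
        before = find_isolated_segments(fx.network, tau=50)
        assert len(before.segments) == 1
        lesion = Lesion(18, 52, 4, 8, fx.network.spec.L_z)
        after = find_isolated_segments(apply_lesion(fx.network, lesion), tau=50)
        assert all(s.z != 0 or not (18 <= s.x0 <= 52) for s in after.segments)
        assert len(after.segments) < len(before.segments) + 1


class TestSerialization:
    def test_roundtrip(self, tmp_path, small_spec):
        pf = build_profile(small_spec, "inhomogeneous", nu_bar=0.3)
        net = assign_block_susceptible(build_network(small_spec, pf, 5), 0.1, 6)
        net = apply_lesion(net, Lesion(1, 3, 0, 2, 2))
        path = tmp_path / "net.npz"
        save_network(net, path)
        back = load_network(path)
        assert np.array_equal(back.bond_x, net.bond_x)
        assert np.array_equal(back.bond_y, net.bond_y)
        assert np.array_equal(back.bond_z, net.bond_z)
        assert np.array_equal(back.susceptible, net.susceptible)
        assert back.structure_seed == 5 and back.block_seed == 6
        assert back.lesions == net.lesions
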