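"""Screened electrostatics: grids, fits, energies, forces, exclusion."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import lhdock as L
from lhdock.electrostatics import (
    charged_group_sites,
    coulomb_constant_kT,
    debye_huckel_potential,
    inverse_debye_length,
    trilinear_interpolate,
)
from lhdock.geometry import RigidTransform, random_quaternion
from lhdock.structures import AtomRecord, Solute


def point_charge(q=1.0, radius=0.0, pos=(0.0, 0.0, 0.0)):
    return Solute([AtomRecord(1, "NZ", "LYS", 1, "A", np.array(pos, float), q, radius)])


@pytest.fixture(scope="module")
def unit_grid():
    return L.debye_huckel_grid(
        point_charge(), spacing=1.0, origin=np.array([-12.0, -12, -12]),
        dims=(25, 25, 25),
    )


class TestDebyeHuckelGrid:
    def test_unit_charge_matches_closed_form(self, unit_grid):
        pts = unit_grid.grid_points()
        r = np.linalg.norm(pts, axis=1)
        mask = r >= 2.0 * unit_grid.spacing
        kappa = inverse_debye_length()
        exact = coulomb_constant_kT() / 78.54 * np.exp(-kappa * r[mask]) / r[mask]
        rel = np.abs(unit_grid.values.ravel()[mask] - exact) / np.abs(exact)
        assert rel.max() < 0.005

    def test_zero_ionic_strength_is_plain_coulomb(self):
        g = L.debye_huckel_grid(
            point_charge(), spacing=1.0, origin=np.array([-5.0, -5, -5]),
            dims=(11, 11, 11), ionic_strength=0.0,
        )
        pts = g.grid_points()
        r = np.linalg.norm(pts, axis=1)
        mask = r >= 2.0
        exact = coulomb_constant_kT() / 78.54 / r[mask]
        np.testing.assert_allclose(g.values.ravel()[mask], exact, rtol=1e-12)

    def test_opposite_charges_superpose_to_zero(self):
        atoms = [
            AtomRecord(1, "NZ", "LYS", 1, "A", np.zeros(3), 1.0, 0.0),
            AtomRecord(2, "OD1", "ASP", 2, "A", np.zeros(3), -1.0, 0.0),
        ]
        g = L.debye_huckel_grid(
            Solute(atoms), spacing=1.0, origin=np.array([-4.0, -4, -4]),
            dims=(9, 9, 9),
        )
        np.testing.assert_allclose(g.values, 0.0, atol=1e-12)

    def test_debye_length_at_100mm(self):
        # 1/kappa ~ 9.6 Å at 100 mM, 298.15 K
        assert 1.0 / inverse_debye_length(0.1) == pytest.approx(9.63, abs=0.05)


class TestOpenDx:
    def test_round_trip(self, unit_grid, tmp_path):
        path = tmp_path / "g.dx"
        L.write_dx_grid(unit_grid, path)
        back = L.read_dx_grid(path)
        assert back.dims == unit_grid.dims
        np.testing.assert_allclose(back.origin, unit_grid.origin, atol=1e-6)
        np.testing.assert_allclose(back.values, unit_grid.values, rtol=1e-6)

    def test_hand_written_2x2x2(self, tmp_path):
        text = (
            "# comment line APBS style\n"
            "object 1 class gridpositions counts 2 2 2\n"
            "origin 0.0 0.0 0.0\n"
            "delta 1.0 0.0 0.0\n"
            "delta 0.0 1.0 0.0\n"
            "delta 0.0 0.0 1.0\n"
            "object 2 class gridconnections counts 2 2 2\n"
            "object 3 class array type double rank 0 items 8 data follows\n"
            "0.0 1.0 2.0\n"
            "3.0 4.0 5.0\n"
            "6.0 7.0\n"
            'attribute "dep" string "positions"\n'
            'object "regular positions regular connections" class field\n'
        )
        path = tmp_path / "h.dx"
        path.write_text(text)
        g = L.read_dx_grid(path)
        assert g.dims == (2, 2, 2)
        np.testing.assert_allclose(g.values.ravel(), np.arange(8.0))


class TestEffectiveCharges:
    def test_identity_fit_recovers_input_charges(self, lh):
        sol = lh.solute
        grid = L.debye_huckel_grid(sol, spacing=2.0, padding=12.0)
        mask = np.abs(sol.charges) > 1e-6
        fit = L.fit_effective_charges(
            sol, grid,
            sites=sol.reference_positions[mask],
            site_radii=sol.radii[mask],
        )
        np.testing.assert_allclose(fit.charges, sol.charges[mask], atol=1e-6)
        assert fit.fit_residual < 1e-6

    def test_net_fitted_charge_near_formal(self, lh):
        sol = lh.solute
        grid = L.debye_huckel_grid(sol, spacing=2.0, padding=12.0)
        fit = L.fit_effective_charges(sol, grid)
        formal = L.net_formal_charge(sol)
        assert abs(fit.net_charge - formal) <= 0.05 * abs(formal)

    def test_default_sites_are_charged_groups(self, lh, nuc):
        sites, _ = charged_group_sites(lh.solute)
        assert len(sites) == int(np.sum(np.abs(lh.solute.charges) > 0.5))
        dna_sites, _ = charged_group_sites(nuc.solute)
        assert len(dna_sites) == int(np.sum(nuc.solute.atom_names == "P"))

    def test_empty_shell_errors(self):
        sol = point_charge(radius=1.0)
        grid = L.debye_huckel_grid(
            sol, spacing=1.0, origin=np.array([-1.0, -1, -1]), dims=(3, 3, 3)
        )
        with pytest.raises(ValueError, match="shell"):
            L.fit_effective_charges(sol, grid, shell=(3.0, 6.0))

    def test_residual_decreases_with_more_sites(self, lh):
        sol = lh.solute
        grid = L.debye_huckel_grid(sol, spacing=2.0, padding=12.0)
        mask = np.abs(sol.charges) > 1e-6
        pos = sol.reference_positions[mask]
        rad = sol.radii[mask]
        few = L.fit_effective_charges(sol, grid, sites=pos[:4], site_radii=rad[:4])
        full = L.fit_effective_charges(sol, grid, sites=pos, site_radii=rad)
        assert full.fit_residual <= few.fit_residual


class TestInteractionEnergy:
    def test_matches_closed_form_far_from_source(self, unit_grid):
        probe = L.EffectiveChargeSet(np.zeros((1, 3)), np.array([1.0]), np.array([0.0]))
        kappa = inverse_debye_length()
        pref = coulomb_constant_kT() / 78.54
        rng = np.random.default_rng(7)
        for _ in range(20):
            d = rng.uniform(6.0, 10.0)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pose = RigidTransform(translation=d * direction)
            e = L.interaction_energy(unit_grid, probe, pose)
            exact = pref * np.exp(-kappa * d) / d
            assert abs(e - exact) / exact < 0.01

    def test_zero_charge_probe(self, unit_grid):
        probe = L.EffectiveChargeSet(np.zeros((1, 3)), np.array([0.0]), np.array([0.0]))
        assert L.interaction_energy(unit_grid, probe, RigidTransform(
            translation=np.array([5.0, 0, 0]))) == 0.0

    def test_invariant_under_global_rotation(self, rng):
        # grid-free DH superposition: rotating source and probe together
        # leaves the energy unchanged to machine precision
        src = rng.normal(size=(5, 3)) * 4
        qsrc = rng.uniform(-1, 1, 5)
        probe = rng.normal(size=(3, 3)) * 2 + np.array([15.0, 0, 0])
        qprobe = rng.uniform(-1, 1, 3)
        R = RigidTransform(random_quaternion(rng)).matrix

        def energy(a, b):
            return float(qprobe @ debye_huckel_potential(b, a, qsrc))

        e1 = energy(src, probe)
        e2 = energy(src @ R.T, probe @ R.T)
        assert abs(e1 - e2) < 1e-9 * abs(e1)

    def test_symmetrized_equals_mean_of_one_sided(self, unit_grid):
        probe = L.EffectiveChargeSet(np.zeros((1, 3)), np.array([1.0]), np.array([0.0]))
        pose = RigidTransform(translation=np.array([6.3, 1.0, 0.5]))
        e_sym = L.symmetrized_interaction_energy(
            unit_grid, probe, unit_grid, probe, pose
        )
        e_ab = L.interaction_energy(unit_grid, probe, pose)
        e_ba = L.interaction_energy(unit_grid, probe, pose.inverse())
        assert e_sym == pytest.approx(0.5 * (e_ab + e_ba))

    def test_out_of_grid_uses_monopole_tail(self, unit_grid):
        probe = L.EffectiveChargeSet(np.zeros((1, 3)), np.array([1.0]), np.array([0.0]))
        d = 40.0  # far outside the 25-node box
        pose = RigidTransform(translation=np.array([d, 0, 0]))
        e = L.interaction_energy(unit_grid, probe, pose)
        kappa = inverse_debye_length()
        exact = coulomb_constant_kT() / 78.54 * np.exp(-kappa * d) / d
        assert e == pytest.approx(exact, rel=1e-6)


class TestForceAndTorque:
    def test_central_difference_agreement(self, unit_grid):
        probe = L.EffectiveChargeSet(
            np.array([[0.0, 0, 0], [1.2, 0.4, -0.3]]),
            np.array([1.0, -0.5]),
            np.zeros(2),
        )
        pose = RigidTransform(translation=np.array([5.3, 1.2, -2.1]))
        force, torque = L.force_and_torque(unit_grid, probe, pose)
        eps = 1e-6
        for ax in range(3):
            dp = np.zeros(3)
            dp[ax] = eps
            ep = L.interaction_energy(
                unit_grid, probe, RigidTransform(translation=pose.translation + dp)
            )
            em = L.interaction_energy(
                unit_grid, probe, RigidTransform(translation=pose.translation - dp)
            )
            assert force[ax] == pytest.approx(-(ep - em) / (2 * eps), rel=1e-4)

    def test_zero_charges_no_force(self, unit_grid):
        probe = L.EffectiveChargeSet(np.zeros((1, 3)), np.array([0.0]), np.array([0.0]))
        f, t = L.force_and_torque(
            unit_grid, probe, RigidTransform(translation=np.array([4.0, 0, 0]))
        )
        assert np.all(f == 0) and np.all(t == 0)

    def test_opposite_charges_attract(self, unit_grid):
        probe = L.EffectiveChargeSet(np.zeros((1, 3)), np.array([-1.0]), np.array([0.0]))
        pose = RigidTransform(translation=np.array([6.0, 0, 0]))
        f, _ = L.force_and_torque(unit_grid, probe, pose)
        assert f[0] < 0  # pulled toward the positive source at the origin


class TestExclusion:
    def test_far_pose_never_overlaps(self, exclusion, lh):
        pose = RigidTransform(translation=np.array([500.0, 0, 0]))
        assert not L.check_overlap(exclusion, lh, pose)

    def test_pose_on_core_overlaps(self, exclusion, lh, nuc):
        pose = RigidTransform(
            translation=np.zeros(3) - lh.solute.reference_center
        )
        assert L.check_overlap(exclusion, lh, pose)

    def test_agrees_with_pairwise_distances(self, exclusion, lh, nuc, rng):
        tree = cKDTree(nuc.solute.positions)
        cell_diag = exclusion.spacing * np.sqrt(3.0)
        mismatches = 0
        for _ in range(1000):
            pose = RigidTransform(
                random_quaternion(rng),
                nuc.dyad_point + rng.uniform(-60, 60, 3),
            )
            w = pose.apply(lh.solute.reference_positions)
            d, j = tree.query(w)
            slack = d - (nuc.solute.radii[j] + exclusion.probe_margin)
            brute = bool(np.any(slack < 0))
            grid = L.check_overlap(exclusion, lh, pose)
            if brute and not grid:
                pytest.fail("grid missed a true overlap (false negative)")
            if grid and not brute:
                # allowed false positive: within one cell diagonal of contact
                assert slack.min() <= cell_diag
                mismatches += 1
        assert mismatches < 200
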