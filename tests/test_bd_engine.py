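"""Brownian propagator physics, encounter logic, and the recorded set."""

import numpy as np
import pytest
from scipy import stats

import lhdock as L
from lhdock import _kernels
from lhdock.bd import EncounterRecord, RecordedSet, StepTooLarge, bd_step
from lhdock.geometry import RigidTransform, quat_to_matrix, random_quaternion


def _free_diffusion_kernel(n_replicas, n_steps, D_t, dt, seed):
    """Propagate non-interacting particles with the production kernel."""
    phi = np.zeros((2, 2, 2))
    origin = np.array([1e8, 1e8, 1e8])  # everything falls in the (zero) tail
    site_ref = np.zeros((1, 3))
    site_q = np.zeros(1)
    occ = np.zeros((1, 1, 1), dtype=np.uint8)
    probe = np.zeros((1, 3))
    far = np.array([1e7, 0.0, 0.0])
    out = np.empty((n_replicas, 3))
    rng = np.random.default_rng(seed)
    for r in range(n_replicas):
        pos = np.zeros(3)
        quat = np.array([1.0, 0.0, 0.0, 0.0])
        noise = rng.standard_normal((n_steps, 6))
        ev = np.empty(n_steps, dtype=np.int64)
        evE = np.empty(n_steps)
        evP = np.empty((n_steps, 3))
        evQ = np.empty((n_steps, 4))
        status, step, n_ev, used = _kernels.propagate_segment(
            pos, quat, site_ref, site_q, phi, origin, 1.0,
            0.0, 0.1, far, occ, origin, 1.0, probe,
            D_t, 1e-6, dt,
            1e30, 0.0, 0.0, 0.0, far, far,
            noise, 1e9, 50, 0, n_steps,
            ev, evE, evP, evQ,
        )
        assert status == _kernels.MAX_STEPS and step == n_steps
        out[r] = pos
    return out


class TestPropagator:
    def test_zero_force_zero_noise_leaves_pose_unchanged(self):
        cfg = L.SimulationConfig(D_trans=0.01, D_rot=1e-5)
        pose = RigidTransform(translation=np.array([1.0, 2.0, 3.0]))
        out = bd_step(pose, np.zeros(3), np.zeros(3), cfg,
                      np.random.default_rng(0), noise=np.zeros(6))
        assert out == pose

    def test_large_displacement_aborts(self):
        cfg = L.SimulationConfig(D_trans=1.0, D_rot=1e-5)
        with pytest.raises(StepTooLarge):
            bd_step(RigidTransform(), np.array([1e4, 0, 0]), np.zeros(3), cfg,
                    np.random.default_rng(0), noise=np.zeros(6))

    def test_free_diffusion_recovers_d_trans(self):
        # Einstein relation: MSD(T) = 6 D T, checked within 3 standard errors
        D, dt, n_steps, n_rep = 0.02, 1.0, 10_000, 1000
        final = _free_diffusion_kernel(n_rep, n_steps, D, dt, seed=42)
        msd = (final**2).sum(axis=1)
        est = msd.mean() / (6.0 * n_steps * dt)
        se = msd.std(ddof=1) / np.sqrt(n_rep) / (6.0 * n_steps * dt)
        assert abs(est - D) < 3.0 * se

    def test_python_step_matches_kernel_statistics(self):
        # the pure-Python propagator obeys the same variance law
        cfg = L.SimulationConfig(D_trans=0.05, D_rot=1e-4, timestep=1.0)
        rng = np.random.default_rng(3)
        n = 4000
        disp = np.empty((n, 3))
        for i in range(n):
            out = bd_step(RigidTransform(), np.zeros(3), np.zeros(3), cfg, rng)
            disp[i] = out.translation
        var = disp.var(axis=0)
        expect = 2 * cfg.D_trans * cfg.timestep
        assert np.all(np.abs(var - expect) < 5 * expect / np.sqrt(n / 2))

    def test_harmonic_field_samples_boltzmann(self):
        # U(r) = q * phi(r) with phi = 0.5 k |r|^2 on a grid; the sampled
        # marginal must match the Gaussian stationary density (KS test)
        k = 0.02  # kT/Å²
        half = 30
        ax = np.arange(-half, half + 1, 1.0)
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        grid = L.PotentialGrid(
            origin=np.array([-half, -half, -half], float), spacing=1.0,
            values=0.5 * k * (xx**2 + yy**2 + zz**2),
        )
        probe = L.EffectiveChargeSet(np.zeros((1, 3)), np.array([1.0]), np.zeros(1))
        cfg = L.SimulationConfig(D_trans=1.0, D_rot=1e-6, timestep=0.5)
        rng = np.random.default_rng(11)
        pose = RigidTransform()
        n_steps, burn, thin = 100_000, 5_000, 300
        samples = []
        for i in range(n_steps):
            force, torque = L.force_and_torque(grid, probe, pose)
            pose = bd_step(pose, force, torque, cfg, rng)
            if i >= burn and i % thin == 0:
                samples.append(pose.translation[0])
        sigma = np.sqrt(1.0 / k)
        _, p = stats.kstest(np.array(samples) / sigma, "norm")
        assert p > 0.01


class TestIsEncounter:
    def test_center_at_dyad_is_encounter(self, lh, nuc):
        cfg = L.SimulationConfig()
        mu = lh.solute.reference_center
        pose = RigidTransform(translation=nuc.dyad_point - mu)
        assert L.is_encounter(pose, lh, nuc, cfg)

    def test_both_criteria_required(self, lh, nuc):
        cfg = L.SimulationConfig()
        mu = lh.solute.reference_center
        center = nuc.solute.geometric_center
        # c2c = 97 < 98 but far from the dyad -> not an encounter
        target = center - 97.0 * nuc.dyad_axis
        pose = RigidTransform(translation=target - mu)
        assert np.linalg.norm(target - nuc.dyad_point) > 40
        assert not L.is_encounter(pose, lh, nuc, cfg)
        # close to the dyad direction but c2c = 99 > 98 -> not an encounter
        target = center + 99.0 * nuc.dyad_axis
        pose = RigidTransform(translation=target - mu)
        assert not L.is_encounter(pose, lh, nuc, cfg)


class BruteRecorder:
    """Literal implementation of the recording/substitution/counting rules,
    with RMSDs computed from explicit atom coordinates."""

    def __init__(self, capacity, dedup, coords):
        self.capacity = capacity
        self.dedup = dedup
        self.coords = np.asarray(coords, float)
        self.records = []  # [pose, energy, count, traj, step]
        self.total_seen = 0

    def _world(self, pose):
        return pose.apply(self.coords)

    def update(self, pose, energy, traj=0, step=0):
        self.total_seen += 1
        w = self._world(pose)
        best_i, best_key = -1, None
        for i, rec in enumerate(self.records):
            r = np.sqrt(np.mean(((w - self._world(rec[0])) ** 2).sum(axis=1)))
            if r <= self.dedup:
                key = (r, rec[1], i)
                if best_key is None or key < best_key:
                    best_key, best_i = key, i
        if best_i == -1:
            if len(self.records) < self.capacity:
                self.records.append([pose, energy, 1, traj, step])
            else:
                energies = [r[1] for r in self.records]
                worst = energies.index(max(energies))
                if energy < energies[worst]:
                    self.records[worst] = [pose, energy, 1, traj, step]
        else:
            rec = self.records[best_i]
            if energy < rec[1]:
                self.records[best_i] = [pose, energy, rec[2] + 1, traj, step]
            else:
                rec[2] += 1


def _feed_all(events, capacity, dedup, coords, bounded=True):
    """Run an event stream through all three recorder implementations."""
    brute = BruteRecorder(capacity, dedup, coords)
    seq = RecordedSet(capacity, dedup, coords)
    batch = RecordedSet(capacity, dedup, coords)
    pos = np.array(
        [quat_to_matrix(p.quaternion) @ seq.mu + p.translation for p, _ in events]
    )
    if bounded:
        batch.set_bounds(pos.min(axis=0) - 3, pos.max(axis=0) + 3)
    quats = np.array([p.quaternion for p, _ in events])
    energies = np.array([e for _, e in events])
    steps = np.arange(len(events), dtype=np.int64)
    for i, (p, e) in enumerate(events):
        brute.update(p, e, 0, i)
        seq.update(EncounterRecord(p, e, 1, 0, i))
    batch.update_batch(pos, quats, energies, np.zeros(len(events), np.int64), steps)
    return brute, seq, batch


def _assert_recorders_equal(brute, seq, batch):
    n = len(brute.records)
    assert seq.n == n and batch.n == n
    assert seq.total_encounters_seen == brute.total_seen
    assert batch.total_encounters_seen == brute.total_seen
    b_energy = np.array([r[1] for r in brute.records])
    b_count = np.array([r[2] for r in brute.records])
    b_step = np.array([r[4] for r in brute.records])
    np.testing.assert_array_equal(seq.r_energy[:n], b_energy)
    np.testing.assert_array_equal(batch.r_energy[:n], b_energy)
    np.testing.assert_array_equal(seq.r_count[:n], b_count)
    np.testing.assert_array_equal(batch.r_count[:n], b_count)
    np.testing.assert_array_equal(seq.r_step[:n], b_step)
    np.testing.assert_array_equal(batch.r_step[:n], b_step)
    np.testing.assert_allclose(seq.r_pos[:n], batch.r_pos[:n])


class TestRecordedSet:
    def test_first_candidate_recorded(self, lh):
        rs = RecordedSet(10, 1.0, lh.solute.reference_positions)
        out = L.update_recorded_set(rs, EncounterRecord(RigidTransform(), -1.0))
        assert out is rs
        assert rs.n == 1 and rs.r_count[0] == 1
        assert rs.total_encounters_seen == 1

    def test_substitution_inherits_count(self, lh):
        rs = RecordedSet(10, 1.0, lh.solute.reference_positions)
        rs.update(EncounterRecord(RigidTransform(), -1.0))
        near = RigidTransform(translation=np.array([0.5, 0, 0]))
        rs.update(EncounterRecord(near, -2.0))  # lower energy: substitute
        assert rs.n == 1
        assert rs.r_count[0] == 2
        assert rs.r_energy[0] == -2.0
        np.testing.assert_allclose(rs.r_pos[0] - rs.mu, [0.5, 0, 0], atol=1e-12)

    def test_higher_energy_neighbor_increments_count(self, lh):
        rs = RecordedSet(10, 1.0, lh.solute.reference_positions)
        rs.update(EncounterRecord(RigidTransform(), -2.0))
        rs.update(EncounterRecord(
            RigidTransform(translation=np.array([0.5, 0, 0])), -1.0))
        assert rs.n == 1 and rs.r_count[0] == 2 and rs.r_energy[0] == -2.0

    def test_capacity_eviction_keeps_most_favorable(self, lh):
        rs = RecordedSet(2, 0.1, lh.solute.reference_positions)
        for i, e in enumerate([-1.0, -3.0, -2.0]):
            rs.update(EncounterRecord(
                RigidTransform(translation=np.array([5.0 * i, 0, 0])), e))
        assert rs.n == 2
        assert sorted(rs.r_energy[:2]) == [-3.0, -2.0]

    @pytest.mark.parametrize("seed,k,spread", [(0, 3, 0.8), (1, 5, 1.5), (2, 2, 0.4)])
    def test_three_implementations_agree(self, lh, seed, k, spread):
        events = L.synthetic_event_stream(2000, seed=seed, planted_clusters=k,
                                          spread=spread)
        brute, seq, batch = _feed_all(events, 30, 1.0,
                                      lh.solute.reference_positions)
        _assert_recorders_equal(brute, seq, batch)

    def test_invariants_after_every_event(self, lh):
        events = L.synthetic_event_stream(500, seed=9, planted_clusters=4,
                                          spread=1.0)
        rs = RecordedSet(20, 1.0, lh.solute.reference_positions)
        for i, (p, e) in enumerate(events):
            rs.update(EncounterRecord(p, e, 1, 0, i))
            assert rs.n <= rs.capacity
            assert np.all(rs.r_count[: rs.n] >= 1)
            assert rs.total_encounters_seen == i + 1


class TestTrajectories:
    def test_fixed_seed_is_bit_identical(self, lh, nuc, field):
        cfg = L.SimulationConfig(auto_scale=True, max_steps=20_000)
        ev1, r1, s1 = L.run_trajectory(lh, nuc, field, cfg, seed=5, trajectory_id=3)
        ev2, r2, s2 = L.run_trajectory(lh, nuc, field, cfg, seed=5, trajectory_id=3)
        assert r1 == r2 and s1 == s2
        np.testing.assert_array_equal(ev1["step"], ev2["step"])
        np.testing.assert_array_equal(ev1["pos"], ev2["pos"])
        np.testing.assert_array_equal(ev1["energy"], ev2["energy"])

    def test_bad_radii_config_rejected(self):
        with pytest.raises(ValueError, match="stop_radius"):
            L.SimulationConfig(start_radius=200.0, stop_radius=150.0)

    def test_zero_trajectories_empty_set(self, lh, nuc, field):
        cfg = L.SimulationConfig(auto_scale=True, n_trajectories=0)
        rs = L.run_docking(lh, nuc, field, cfg)
        assert rs.n == 0 and rs.total_encounters_seen == 0

    def test_zero_charge_hit_fraction_matches_diffusion_theory(self, lh, nuc):
        # with no forces, the chance of reaching c2c < a before escaping at R,
        # starting from r0, is the classic (1/r0 - 1/R) / (1/a - 1/R)
        a, r0, R = 60.0, 100.0, 119.0
        grid = L.PotentialGrid(
            origin=np.array([-1.0, -1, -1]), spacing=1.0, values=np.zeros((3, 3, 3)),
            source_center=nuc.solute.geometric_center, source_net_charge=0.0,
        )
        charges = L.EffectiveChargeSet(np.zeros((1, 3)), np.array([0.0]), np.zeros(1))
        field = L.DockingField(grid, charges, None)
        cfg = L.SimulationConfig(
            start_radius=r0, stop_radius=R, encounter_c2c_max=a,
            encounter_dyad_max=1e6, D_trans=0.05, D_rot=1e-6,
            n_trajectories=300, max_steps=400_000, rng_seed=17,
        )
        hits = 0
        for t in range(cfg.n_trajectories):
            ev, reason, _ = L.run_trajectory(lh, nuc, field, cfg, cfg.rng_seed, t)
            hits += bool(len(ev["step"]))
        p = (1 / r0 - 1 / R) / (1 / a - 1 / R)
        se = np.sqrt(p * (1 - p) / cfg.n_trajectories)
        assert abs(hits / cfg.n_trajectories - p) < 3.5 * se
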