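"""Rigid-body Brownian-dynamics docking engine.

The linker-histone GD diffuses as a rigid body around a fixed nucleosome
under forces interpolated from the nucleosome's electrostatic potential
grid acting on the LH's effective charges.  Trajectories start with the LH
center placed uniformly on a sphere around the nucleosome (185 Å by
default) with a uniform random orientation, and stop when the
center-to-center distance exceeds the stop radius (204 Å).  The propagator
is the Ermak–McCammon scheme with isotropic translational and rotational
diffusion (Δt = 1 ps by default); excluded volume is enforced by rejecting
and redrawing overlapping trial moves.

A diffusional *encounter complex* is any state with (1) LH–nucleosome
center-to-center distance < 98 Å and (2) LH center within 40 Å of the
nucleosome dyad point.  Encounter states feed the :class:`RecordedSet`, a
capacity-limited (5000), energy-ranked archive deduplicated at 1 Å pose
RMSD: a candidate within 1 Å of a record substitutes it when lower in
energy (inheriting the count), otherwise increments the closest such
record's occurrence count; new poses evict the least favorable record once
the archive is full.  Pose RMSD is computed over all LH atoms in the fixed
nucleosome frame, without re-superposition, using the closed form for
rigid bodies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import Boltzmann

from . import _kernels
from .electrostatics import (
    EffectiveChargeSet,
    ExclusionGrid,
    PotentialGrid,
    coulomb_constant_kT,
)
from .geometry import RigidTransform, quat_from_rotvec, quat_multiply, quat_to_matrix, random_quaternion
from .structures import LHModel, NucleosomeModel

__all__ = [
    "SimulationConfig",
    "DockingField",
    "EncounterRecord",
    "RecordedSet",
    "StepTooLarge",
    "stokes_einstein_translation",
    "stokes_einstein_rotation",
    "bd_step",
    "is_encounter",
    "update_recorded_set",
    "run_trajectory",
    "run_docking",
]

logger = logging.getLogger(__name__)

WATER_VISCOSITY = 0.891e-3  # Pa s at 25 °C
HYDRO_RADIUS_FACTOR = 1.29  # R_h as a multiple of the radius of gyration


class StepTooLarge(RuntimeError):
    """A single BD displacement exceeded the sanity bound (field too steep
    for the timestep)."""


def stokes_einstein_translation(r_h: float, temperature: float = 298.15) -> float:
    """Translational diffusion coefficient in Å²/ps for R_h in Å."""
    d_m2s = Boltzmann * temperature / (6.0 * np.pi * WATER_VISCOSITY * r_h * 1e-10)
    return float(d_m2s * 1e8)  # m²/s -> Å²/ps


def stokes_einstein_rotation(r_h: float, temperature: float = 298.15) -> float:
    """Rotational diffusion coefficient in rad²/ps for R_h in Å."""
    d_s = Boltzmann * temperature / (8.0 * np.pi * WATER_VISCOSITY * (r_h * 1e-10) ** 3)
    return float(d_s * 1e-12)


def _bounding_radius(coords: np.ndarray, radii: np.ndarray) -> float:
    center = coords.mean(axis=0)
    return float((np.linalg.norm(coords - center, axis=1) + radii).max())


@dataclass
class SimulationConfig:
    """Parameters of one docking simulation (defaults follow the protocol:
    1 ps timestep, 185/204 Å start/stop spheres, 98/40 Å encounter criteria,
    1 Å deduplication RMSD, 5000-record archive, 10 clusters, 20000
    trajectories)."""

    timestep: float = 1.0  # ps
    start_radius: float = 185.0  # Å
    stop_radius: float = 204.0  # Å
    n_trajectories: int = 20000
    encounter_c2c_max: float = 98.0  # Å
    encounter_dyad_max: float = 40.0  # Å
    dedup_rmsd: float = 1.0  # Å
    capacity: int = 5000
    n_clusters: int = 10
    D_trans: float | None = None  # Å²/ps; Stokes–Einstein if None
    D_rot: float | None = None  # rad²/ps
    rng_seed: int = 1
    temperature: float = 298.15  # K
    max_steps: int = 100_000_000  # per-trajectory hard ceiling
    max_displacement: float = 10.0  # Å, single-step abort threshold
    max_retries: int = 50  # redraws of an overlapping trial move
    segment_steps: int = 16384  # noise buffer length
    auto_scale: bool = False  # start = b-radius + 30 Å, stop = start + 19 Å

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")
        if self.n_trajectories < 0:
            raise ValueError("n_trajectories must be >= 0")
        if not self.auto_scale:
            self._check_radii()

    def _check_radii(self) -> None:
        if not (self.stop_radius > self.start_radius > self.encounter_c2c_max):
            raise ValueError(
                "require stop_radius > start_radius > encounter_c2c_max, got "
                f"{self.stop_radius} / {self.start_radius} / {self.encounter_c2c_max}"
            )

    def resolved_for(self, lh: LHModel, nuc: NucleosomeModel) -> "SimulationConfig":
        """Fill system-dependent defaults (diffusion constants; auto-scaled
        start/stop spheres) for a concrete LH/nucleosome pair."""
        cfg = replace(self)
        coords = lh.solute.reference_positions
        if cfg.D_trans is None or cfg.D_rot is None:
            rg = float(np.sqrt(((coords - coords.mean(axis=0)) ** 2).sum(axis=1).mean()))
            r_h = HYDRO_RADIUS_FACTOR * rg
            if cfg.D_trans is None:
                cfg.D_trans = stokes_einstein_translation(r_h, cfg.temperature)
            if cfg.D_rot is None:
                cfg.D_rot = stokes_einstein_rotation(r_h, cfg.temperature)
        if cfg.auto_scale:
            b = _bounding_radius(coords, lh.solute.radii) + _bounding_radius(
                nuc.solute.positions, nuc.solute.radii
            )
            cfg.start_radius = b + 30.0
            cfg.stop_radius = cfg.start_radius + 19.0
        cfg._check_radii()
        return cfg


@dataclass
class DockingField:
    """The precomputed interaction model of one docking system."""

    grid: PotentialGrid  # nucleosome potential, kT/e
    charges: EffectiveChargeSet  # LH effective charges (LH reference frame)
    exclusion: ExclusionGrid | None = None


@dataclass
class EncounterRecord:
    """A recorded encounter pose with its energy and occurrence count."""

    pose: RigidTransform
    energy: float
    count: int = 1
    trajectory_id: int = 0
    step_index: int = 0


class RecordedSet:
    """Capacity-limited, energy-ranked, RMSD-deduplicated pose archive.

    Construction needs the LH reference coordinates so pose RMSDs can be
    evaluated in closed form: for rigid poses (R₁, t₁), (R₂, t₂) over atoms
    xᵢ with centroid μ and second-moment matrix S = Σ(xᵢ−μ)(xᵢ−μ)ᵀ,

        RMSD² = |Δc|² + (2 tr S − 2 tr(R₁ᵀ R₂ S)) / N,

    where Δc is the centroid displacement.
    """

    def __init__(self, capacity: int, dedup_rmsd: float, lh_ref_coords: np.ndarray):
        if capacity <= 0:
            raise ValueError("capacity must be positive")
        coords = np.atleast_2d(np.asarray(lh_ref_coords, dtype=float))
        self.capacity = int(capacity)
        self.dedup_rmsd = float(dedup_rmsd)
        self.mu = coords.mean(axis=0)
        centered = coords - self.mu
        self.S = centered.T @ centered
        self.trS = float(np.trace(self.S))
        self.natoms = len(coords)
        cap = self.capacity
        self.r_pos = np.zeros((cap, 3))
        self.r_quat = np.zeros((cap, 4))
        self.r_rot = np.zeros((cap, 9))
        self.r_rotS = np.zeros((cap, 9))
        self.r_energy = np.zeros(cap)
        self.r_count = np.zeros(cap, dtype=np.int64)
        self.r_traj = np.zeros(cap, dtype=np.int64)
        self.r_step = np.zeros(cap, dtype=np.int64)
        self.n = 0
        self.total_encounters_seen = 0
        self._cells = None

    # -- cell-grid acceleration (optional; used by the batch path) ---------

    def set_bounds(self, lo: np.ndarray, hi: np.ndarray) -> None:
        """Declare the region record centroids can occupy (cell hashing)."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        cell = self.dedup_rmsd
        dims = np.maximum(np.ceil((hi - lo) / cell).astype(np.int64) + 1, 1)
        if int(np.prod(dims)) > 20_000_000:
            raise ValueError("recorded-set cell grid would be too large")
        self._cells = {
            "lo": lo,
            "inv": 1.0 / cell,
            "dims": dims,
            "head": np.full(int(np.prod(dims)), -1, dtype=np.int64),
            "next": np.full(self.capacity, -1, dtype=np.int64),
            "of": np.zeros(self.capacity, dtype=np.int64),
        }

    def update_batch(
        self,
        ev_pos: np.ndarray,
        ev_quat: np.ndarray,
        ev_energy: np.ndarray,
        ev_traj: np.ndarray,
        ev_step: np.ndarray,
    ) -> None:
        """Feed a batch of encounter events (centroid, quaternion, energy)
        through the numba recorder kernel."""
        if self._cells is None:
            lo = ev_pos.min(axis=0) - 2 * self.dedup_rmsd if len(ev_pos) else np.zeros(3)
            hi = ev_pos.max(axis=0) + 2 * self.dedup_rmsd if len(ev_pos) else np.ones(3)
            self.set_bounds(lo, hi)
        if len(ev_pos) == 0:
            return
        c = self._cells
        state = np.array([self.n, self.total_encounters_seen], dtype=np.int64)
        _kernels.process_events(
            np.ascontiguousarray(ev_pos, dtype=np.float64),
            np.ascontiguousarray(ev_quat, dtype=np.float64),
            np.ascontiguousarray(ev_energy, dtype=np.float64),
            np.ascontiguousarray(ev_traj, dtype=np.int64),
            np.ascontiguousarray(ev_step, dtype=np.int64),
            self.r_pos, self.r_quat, self.r_rot, self.r_rotS,
            self.r_energy, self.r_count, self.r_traj, self.r_step,
            c["head"], c["next"], c["of"],
            c["lo"], c["inv"], c["dims"],
            self.S, self.trS, self.natoms,
            self.dedup_rmsd**2, self.capacity,
            state,
        )
        self.n = int(state[0])
        self.total_encounters_seen = int(state[1])

    # -- sequential (pure-Python) path --------------------------------------

    def update(self, candidate: EncounterRecord) -> None:
        """Apply the recording rules to a single candidate (Python path).

        Mirrors the batch kernel exactly; useful for unit tests and small
        event streams.
        """
        self.total_encounters_seen += 1
        R = quat_to_matrix(candidate.pose.quaternion)
        centroid = R @ self.mu + candidate.pose.translation
        n = self.n
        d2 = self.dedup_rmsd**2
        best_i = -1
        if n > 0:
            dp2 = ((self.r_pos[:n] - centroid) ** 2).sum(axis=1)
            pre = np.nonzero(dp2 <= d2)[0]
            if len(pre):
                rot = self.r_rotS[pre] @ R.ravel()
                r2 = dp2[pre] + (2.0 * self.trS - 2.0 * rot) / self.natoms
                close = pre[r2 <= d2]
                if len(close):
                    key = np.lexsort(
                        (close, self.r_energy[close], r2[r2 <= d2])
                    )
                    best_i = int(close[key[0]])
        if best_i == -1:
            slot = -1
            if n < self.capacity:
                slot = n
                self.n = n + 1
            else:
                worst = int(np.argmax(self.r_energy[:n]))
                if candidate.energy < self.r_energy[worst]:
                    slot = worst
            if slot >= 0:
                self._write_slot(slot, centroid, candidate, R, count=1)
        else:
            if candidate.energy < self.r_energy[best_i]:
                self._write_slot(
                    best_i, centroid, candidate, R, count=int(self.r_count[best_i]) + 1
                )
            else:
                self.r_count[best_i] += 1

    def _write_slot(self, slot, centroid, candidate, R, count):
        self.r_pos[slot] = centroid
        self.r_quat[slot] = candidate.pose.quaternion
        self.r_rot[slot] = R.ravel()
        self.r_rotS[slot] = (R @ self.S).ravel()
        self.r_energy[slot] = candidate.energy
        self.r_count[slot] = count
        self.r_traj[slot] = candidate.trajectory_id
        self.r_step[slot] = candidate.step_index

    # -- views ---------------------------------------------------------------

    def __len__(self) -> int:
        return self.n

    def pose_of(self, slot: int) -> RigidTransform:
        R = self.r_rot[slot].reshape(3, 3)
        t = self.r_pos[slot] - R @ self.mu
        return RigidTransform(self.r_quat[slot].copy(), t)

    @property
    def order_by_energy(self) -> np.ndarray:
        return np.argsort(self.r_energy[: self.n], kind="stable")

    @property
    def records(self) -> list[EncounterRecord]:
        """Records sorted by energy (most favorable first)."""
        return [
            EncounterRecord(
                self.pose_of(i),
                float(self.r_energy[i]),
                int(self.r_count[i]),
                int(self.r_traj[i]),
                int(self.r_step[i]),
            )
            for i in self.order_by_energy
        ]

    def to_dataframe(self):
        import pandas as pd

        rows: list[dict] = []
        for i in self.order_by_energy:
            pose = self.pose_of(i)
            rows.append(
                {
                    "qw": pose.quaternion[0], "qx": pose.quaternion[1],
                    "qy": pose.quaternion[2], "qz": pose.quaternion[3],
                    "tx": pose.translation[0], "ty": pose.translation[1],
                    "tz": pose.translation[2],
                    "energy_kT": float(self.r_energy[i]),
                    "count": int(self.r_count[i]),
                    "trajectory": int(self.r_traj[i]),
                    "step": int(self.r_step[i]),
                }
            )
        cols = ["qw", "qx", "qy", "qz", "tx", "ty", "tz", "energy_kT",
                "count", "trajectory", "step"]
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_dataframe(cls, df, capacity, dedup_rmsd, lh_ref_coords) -> "RecordedSet":
        rs = cls(capacity, dedup_rmsd, lh_ref_coords)
        for _, row in df.iterrows():
            pose = RigidTransform(
                np.array([row["qw"], row["qx"], row["qy"], row["qz"]]),
                np.array([row["tx"], row["ty"], row["tz"]]),
            )
            R = pose.matrix
            rec = EncounterRecord(
                pose, float(row["energy_kT"]), int(row["count"]),
                int(row["trajectory"]), int(row["step"]),
            )
            rs._write_slot(rs.n, R @ rs.mu + pose.translation, rec, R, int(row["count"]))
            rs.n += 1
            rs.total_encounters_seen += int(row["count"])
        return rs


def update_recorded_set(
    rs: RecordedSet, candidate: EncounterRecord, config: SimulationConfig | None = None
) -> RecordedSet:
    """Functional wrapper around :meth:`RecordedSet.update`."""
    rs.update(candidate)
    return rs


# ---------------------------------------------------------------------------
# Propagator


def bd_step(
    pose: RigidTransform,
    force: np.ndarray,
    torque: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    noise: np.ndarray | None = None,
) -> RigidTransform:
    """One Ermak–McCammon step: Δr = D_t F Δt + ξ, Δφ = D_r T Δt + ξ_r,
    with ⟨ξ_α²⟩ = 2 D Δt per axis; the rotation is applied as a quaternion
    increment and renormalized.  Raises :class:`StepTooLarge` when the
    displacement exceeds ``config.max_displacement``."""
    if config.D_trans is None or config.D_rot is None:
        raise ValueError("config diffusion constants are unresolved")
    dt = config.timestep
    if noise is None:
        noise = rng.standard_normal(6)
    dr = config.D_trans * np.asarray(force, dtype=float) * dt + np.sqrt(
        2.0 * config.D_trans * dt
    ) * noise[:3]
    if np.linalg.norm(dr) > config.max_displacement:
        raise StepTooLarge(
            f"step displacement {np.linalg.norm(dr):.2f} Å > "
            f"{config.max_displacement} Å; timestep too large for the field"
        )
    dphi = config.D_rot * np.asarray(torque, dtype=float) * dt + np.sqrt(
        2.0 * config.D_rot * dt
    ) * noise[3:]
    dq = quat_from_rotvec(dphi)
    q = quat_multiply(dq, pose.quaternion)
    q /= np.linalg.norm(q)
    return RigidTransform(q, pose.translation + dr)


def is_encounter(
    pose: RigidTransform,
    lh: LHModel,
    nuc: NucleosomeModel,
    config: SimulationConfig,
) -> bool:
    """True iff the pose satisfies both encounter criteria (c2c and dyad)."""
    mu = lh.solute.reference_center
    center = pose.matrix @ mu + pose.translation
    c2c = np.linalg.norm(center - nuc.solute.geometric_center)
    dyad = np.linalg.norm(center - nuc.dyad_point)
    return bool(c2c < config.encounter_c2c_max and dyad < config.encounter_dyad_max)


# ---------------------------------------------------------------------------
# Trajectories


def _engine_arrays(lh: LHModel, nuc: NucleosomeModel, field: DockingField):
    mu = lh.solute.reference_center
    site_ref = np.ascontiguousarray(field.charges.positions - mu)
    site_q = np.ascontiguousarray(field.charges.charges)
    probe_ref = np.ascontiguousarray(lh.solute.reference_positions - mu)
    grid = field.grid
    tail_pref = (
        coulomb_constant_kT(grid.temperature) / grid.eps_solvent
    ) * grid.source_net_charge
    src_center = (
        grid.source_center if grid.source_center is not None
        else nuc.solute.geometric_center
    )
    if field.exclusion is not None:
        occ = np.ascontiguousarray(field.exclusion.occupancy, dtype=np.uint8)
        e_origin = field.exclusion.origin
        e_h = field.exclusion.spacing
    else:
        occ = np.zeros((1, 1, 1), dtype=np.uint8)
        e_origin = np.array([1e9, 1e9, 1e9])
        e_h = 1.0
    b_lh = _bounding_radius(lh.solute.reference_positions, lh.solute.radii)
    b_nuc = _bounding_radius(nuc.solute.positions, nuc.solute.radii)
    return {
        "skip2": (b_lh + b_nuc + 2.0) ** 2,
        "site_ref": site_ref,
        "site_q": site_q,
        "probe_ref": probe_ref,
        "phi": np.ascontiguousarray(grid.values),
        "g_origin": np.ascontiguousarray(grid.origin),
        "g_h": grid.spacing,
        "tail_pref": tail_pref,
        "kappa": grid.kappa,
        "src_center": np.ascontiguousarray(src_center),
        "occ": occ,
        "e_origin": np.ascontiguousarray(e_origin),
        "e_h": e_h,
        "nuc_center": np.ascontiguousarray(nuc.solute.geometric_center),
        "dyad_point": np.ascontiguousarray(nuc.dyad_point),
        "mu": mu,
    }


def run_trajectory(
    lh: LHModel,
    nuc: NucleosomeModel,
    field: DockingField,
    config: SimulationConfig,
    seed,
    trajectory_id: int = 0,
    _arrays: dict | None = None,
):
    """Run one trajectory; returns (events, exit_reason, n_steps).

    ``events`` is a dict of arrays (step, energy, pos, quat) of every
    encounter state, in step order; ``pos`` is the LH geometric center and
    ``quat`` the pose quaternion.  The exit reason is "escaped",
    "max_steps" or "aborted_large_step".
    """
    cfg = config.resolved_for(lh, nuc)
    arr = _arrays if _arrays is not None else _engine_arrays(lh, nuc, field)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(trajectory_id)]))
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    pos = arr["nuc_center"] + cfg.start_radius * direction
    quat = random_quaternion(rng)
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    quat = np.ascontiguousarray(quat, dtype=np.float64)

    seg = cfg.segment_steps
    ev_step_l, ev_energy_l, ev_pos_l, ev_quat_l = [], [], [], []
    step = 0
    status = _kernels.NOISE_EXHAUSTED
    while True:
        noise = rng.standard_normal((seg, 6))
        ev_step = np.empty(seg, dtype=np.int64)
        ev_energy = np.empty(seg)
        ev_pos = np.empty((seg, 3))
        ev_quat = np.empty((seg, 4))
        status, step, n_ev, _ = _kernels.propagate_segment(
            pos, quat,
            arr["site_ref"], arr["site_q"],
            arr["phi"], arr["g_origin"], arr["g_h"],
            arr["tail_pref"], arr["kappa"], arr["src_center"],
            arr["occ"], arr["e_origin"], arr["e_h"],
            arr["probe_ref"],
            cfg.D_trans, cfg.D_rot, cfg.timestep,
            cfg.stop_radius**2, cfg.encounter_c2c_max**2,
            cfg.encounter_dyad_max**2, arr["skip2"],
            arr["nuc_center"], arr["dyad_point"],
            noise,
            cfg.max_displacement, cfg.max_retries,
            step, cfg.max_steps,
            ev_step, ev_energy, ev_pos, ev_quat,
        )
        if n_ev:
            ev_step_l.append(ev_step[:n_ev].copy())
            ev_energy_l.append(ev_energy[:n_ev].copy())
            ev_pos_l.append(ev_pos[:n_ev].copy())
            ev_quat_l.append(ev_quat[:n_ev].copy())
        if status != _kernels.NOISE_EXHAUSTED:
            break
    reason = {
        _kernels.ESCAPED: "escaped",
        _kernels.MAX_STEPS: "max_steps",
        _kernels.ABORTED_LARGE_STEP: "aborted_large_step",
    }[status]
    events = {
        "step": np.concatenate(ev_step_l) if ev_step_l else np.empty(0, dtype=np.int64),
        "energy": np.concatenate(ev_energy_l) if ev_energy_l else np.empty(0),
        "pos": np.concatenate(ev_pos_l) if ev_pos_l else np.empty((0, 3)),
        "quat": np.concatenate(ev_quat_l) if ev_quat_l else np.empty((0, 4)),
    }
    return events, reason, step


def run_docking(
    lh: LHModel,
    nuc: NucleosomeModel,
    field: DockingField,
    config: SimulationConfig,
) -> RecordedSet:
    """Run all trajectories and maintain the recorded set.

    Trajectories are independent given per-trajectory seeds derived from
    the master seed; their events are merged in (trajectory, step) order,
    which makes the recorded set deterministic.  Run statistics are left
    on ``RecordedSet.stats``.
    """
    cfg = config.resolved_for(lh, nuc)
    arr = _engine_arrays(lh, nuc, field)
    rs = RecordedSet(cfg.capacity, cfg.dedup_rmsd, lh.solute.reference_positions)
    pad = 4.0 * cfg.dedup_rmsd + 1.0
    rs.set_bounds(
        arr["dyad_point"] - (cfg.encounter_dyad_max + pad),
        arr["dyad_point"] + (cfg.encounter_dyad_max + pad),
    )
    stats = {"escaped": 0, "max_steps": 0, "aborted_large_step": 0,
             "steps_total": 0, "events_total": 0}
    for traj in range(cfg.n_trajectories):
        events, reason, n_steps = run_trajectory(
            lh, nuc, field, cfg, cfg.rng_seed, trajectory_id=traj, _arrays=arr
        )
        stats[reason] += 1
        stats["steps_total"] += n_steps
        n_ev = len(events["step"])
        stats["events_total"] += n_ev
        if n_ev:
            rs.update_batch(
                events["pos"], events["quat"], events["energy"],
                np.full(n_ev, traj, dtype=np.int64), events["step"],
            )
    rs.stats = stats
    logger.info(
        "docking: %d trajectories, %d encounters, %d records kept",
        cfg.n_trajectories, rs.total_encounters_seen, rs.n,
    )
    return rs
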