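"""Idealized nucleosome and linker-histone fixtures.

The generator stands in for experimental structures so that every docking,
recording, clustering, classification and H-bond stage can run with no
download:

* :func:`build_ideal_nucleosome` — a nucleosome-shaped polyanion: one P
  pseudo-atom per strand per base pair (charge −1 e, radius 2.1 Å) wound as
  a double helix (10.4 bp/turn) along a left-handed superhelix of standard
  nucleosome geometry (radius 41.9 Å, pitch 25.9 Å, 1.65 turns for 147 bp),
  extended by straight B-DNA linker arms with tunable opening angles, plus
  a neutral bead ball standing in for the histone-core excluded volume.
  The core DNA is built exactly two-fold symmetric about the dyad axis.
* :func:`build_toy_lh` — a one-bead-per-residue winged-helix-like cationic
  domain (80 residues, net +11 e by default) whose three DNA-binding
  elements are pre-placed against the nucleosome so that its native pose
  classifies as the on-dyad configuration "(−3↑, 0, +3)"; β1-region
  mutable sites (V80/K82/K85/V87) and PTM sites (K58/S66/S67/K72) mimic
  the classic gH5/gH1 positions.
* :func:`place_reference_pose` — on-dyad and off-dyad reference poses
  (off-dyad poses exploit the superhelical symmetry of the core DNA).
* :func:`synthetic_event_stream` — planted-cluster pose/energy streams for
  recorder and clustering oracles.

All fixtures are deterministic given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import RigidTransform, quat_from_axis_angle, random_quaternion
from .structures import (
    AtomRecord,
    LHModel,
    NucleosomeModel,
    Solute,
    annotate_lh_elements,
    annotate_nucleosome,
)
from .variants import RESIDUE_PARAMS

__all__ = [
    "FixtureSpec",
    "build_ideal_nucleosome",
    "build_toy_lh",
    "place_reference_pose",
    "synthetic_event_stream",
    "write_fixture_files",
    "load_fixture_files",
]

# standard nucleosome geometry (textbook values, not fitted here)
SUPERHELIX_RADIUS = 41.9  # Å
SUPERHELIX_PITCH = 25.9  # Å per superhelical turn
SUPERHELIX_TURNS = 1.65  # for the 147 bp core
HELICAL_REPEAT = 10.4  # bp per DNA double-helix turn
PHOSPHATE_RING_RADIUS = 9.3  # Å, P distance from the duplex axis
STRAND_HALF_PHASE = np.radians(70.0)  # half the minor-groove phase width
ARM_BP_RISE = 3.4  # Å per bp on straight linker arms
PHOSPHATE_RADIUS = 2.1  # Å
CORE_SPHERE_RADIUS = 21.0  # Å, histone-core bead ball
CORE_BEAD_RADIUS = 4.0  # Å
CORE_BEAD_SPACING = 5.5  # Å
STEM_OFFSET = 15.0  # Å, stem convergence point ahead of the dyad (closed arms)

_MIRROR = np.diag([1.0, -1.0, -1.0])  # the dyad two-fold operation (about x)

# toy-LH residue layout (residues are numbered 30..109 like a typical GD
# construct): alpha3 carries the site −3 contact, beta1 dips to the dyad,
# l1 reaches site +3; alpha1/alpha2 scaffold the fold above the DNA.  The
# numbering hosts both classic mutation quartets (V80/K82/K85/V87 in the
# β1 wing, K102/I104/K107/K109 on the l1 tail) and the PTM sites
# K58/S66/S67/K72.
LH_FIRST_RESIDUE = 30
LH_ELEMENT_RANGES = {
    "alpha3": (30, 54),
    "alpha1": (55, 63),
    "alpha2": (64, 75),
    "beta1": (76, 87),
    "l1": (88, 109),
}
LH_POSITIVE_SITES = {42, 58, 69, 72, 74, 82, 85, 91, 92, 95, 102, 107, 109}
LH_NEGATIVE_SITES = {35, 49}
_LH_RESIDUE_NAMES = {
    **{i: "LYS" for i in LH_POSITIVE_SITES},
    74: "ARG",
    **{i: "GLU" for i in LH_NEGATIVE_SITES},
    66: "SER", 67: "SER", 80: "VAL", 87: "VAL", 104: "ILE",
}
_LH_CHARGE_POOL = (97, 99, 44, 31, 63, 78, 94, 100, 56, 60, 65, 75, 89, 98)


@dataclass
class FixtureSpec:
    """Study conditions of the synthetic system."""

    core_bp: int = 147
    l_dna_bp: int = 10  # per arm
    opening_angle_1: float = 0.0  # deg, L-DNA1 splay from the closed reference
    opening_angle_2: float = 0.0  # deg
    lh_size: int = 80  # residues
    lh_net_charge: int = 11  # e
    dna_phosphate_charge: float = -1.0  # e
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_bp < 31 or self.core_bp % 2 == 0:
            raise ValueError("core_bp must be odd and at least 31")
        if self.l_dna_bp < 0:
            raise ValueError("l_dna_bp must be >= 0")
        for a in (self.opening_angle_1, self.opening_angle_2):
            if not (0.0 <= a <= 90.0):
                raise ValueError("opening angles must be within [0°, 90°]")
        if self.lh_size < 80:
            raise ValueError("lh_size must be at least 80 residues")


# ---------------------------------------------------------------------------
# Nucleosome


def _core_frame(j: float, spec: FixtureSpec):
    """Path point and local (t̂, û, v̂) frame of the superhelix at bp j ≥ 0."""
    dtheta = 2.0 * np.pi * SUPERHELIX_TURNS / spec.core_bp
    dz = SUPERHELIX_PITCH * SUPERHELIX_TURNS / spec.core_bp
    th = j * dtheta
    c = np.array([SUPERHELIX_RADIUS * np.cos(th), SUPERHELIX_RADIUS * np.sin(th), -j * dz])
    tangent = np.array(
        [-SUPERHELIX_RADIUS * np.sin(th) * dtheta, SUPERHELIX_RADIUS * np.cos(th) * dtheta, -dz]
    )
    t_hat = tangent / np.linalg.norm(tangent)
    radial = np.array([np.cos(th), np.sin(th), 0.0])
    u = radial - np.dot(radial, t_hat) * t_hat
    u /= np.linalg.norm(u)
    v = np.cross(t_hat, u)
    return c, t_hat, u, v


def _strand_points(j: float, c, u, v) -> tuple[np.ndarray, np.ndarray]:
    """P positions of strands I/II at bp j given the local frame."""
    omega = 2.0 * np.pi / HELICAL_REPEAT
    out = []
    for sgn in (+1.0, -1.0):
        psi = omega * j + sgn * STRAND_HALF_PHASE
        out.append(c + PHOSPHATE_RING_RADIUS * (np.cos(psi) * u + np.sin(psi) * v))
    return out[0], out[1]


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _positive_arm(spec: FixtureSpec, opening_deg: float):
    """Phosphates of a straight linker arm leaving the positive-bp end.

    In the closed (0°) reference the arm points toward a stem point ahead
    of the dyad (``STEM_OFFSET`` Å outward along the dyad axis), so the two
    closed arms converge near the dyad the way linker DNA does in a
    chromatosome.  Opening rotates the arm toward the direction pointing
    away from the dyad axis, so larger angles strictly move the arm end
    away from it.
    """
    half = (spec.core_bp - 1) // 2
    J, t_hat, u, v = _core_frame(half, spec)
    dyad_x = SUPERHELIX_RADIUS + PHOSPHATE_RING_RADIUS * np.cos(STRAND_HALF_PHASE)
    stem = np.array([dyad_x + STEM_OFFSET, 0.0, 0.0])
    d_closed = stem - J
    d_closed /= np.linalg.norm(d_closed)
    R = _rodrigues(np.cross(t_hat, d_closed),
                   float(np.arccos(np.clip(np.dot(t_hat, d_closed), -1, 1))))
    if opening_deg > 0:
        w = np.array([0.0, J[1], J[2]])
        w /= np.linalg.norm(w)
        R = _rodrigues(np.cross(d_closed, w),
                       np.radians(opening_deg)) @ R
    d = R @ t_hat
    ua = R @ u
    va = R @ v
    omega = 2.0 * np.pi / HELICAL_REPEAT
    rows = []
    for j in range(half + 1, half + spec.l_dna_bp + 1):
        c = J + (j - half) * ARM_BP_RISE * d
        p1 = c + PHOSPHATE_RING_RADIUS * (
            np.cos(omega * j + STRAND_HALF_PHASE) * ua
            + np.sin(omega * j + STRAND_HALF_PHASE) * va
        )
        p2 = c + PHOSPHATE_RING_RADIUS * (
            np.cos(omega * j - STRAND_HALF_PHASE) * ua
            + np.sin(omega * j - STRAND_HALF_PHASE) * va
        )
        rows.append((j, p1, p2))
    return rows


def build_ideal_nucleosome(spec: FixtureSpec) -> NucleosomeModel:
    """Construct the idealized nucleosome model (see module docstring).

    Total DNA charge is ``dna_phosphate_charge × 2 × (core_bp + 2·l_dna_bp)``;
    with equal opening angles the whole DNA is exactly two-fold symmetric
    about the dyad (x) axis.
    """
    half = (spec.core_bp - 1) // 2
    # core: build bp >= 0 from the formula, reflect for bp < 0 (exact C2)
    strand1: dict[int, np.ndarray] = {}
    strand2: dict[int, np.ndarray] = {}
    for j in range(0, half + 1):
        c, _, u, v = _core_frame(j, spec)
        p1, p2 = _strand_points(j, c, u, v)
        strand1[j] = p1
        strand2[j] = p2
        if j > 0:
            strand1[-j] = _MIRROR @ p2
            strand2[-j] = _MIRROR @ p1
    strand2[0] = _MIRROR @ strand1[0]
    # arms: positive side from the formula, negative side as its mirror
    for j, p1, p2 in _positive_arm(spec, spec.opening_angle_2):
        strand1[j] = p1
        strand2[j] = p2
    for j, p1, p2 in _positive_arm(spec, spec.opening_angle_1):
        strand1[-j] = _MIRROR @ p2
        strand2[-j] = _MIRROR @ p1

    bps = sorted(strand1)
    n_bp = len(bps)
    atoms: list[AtomRecord] = []
    table = []
    for res, j in enumerate(bps, start=1):
        atoms.append(
            AtomRecord(res, "P", "DG", res, "I", strand1[j],
                       spec.dna_phosphate_charge, PHOSPHATE_RADIUS)
        )
    for res, j in enumerate(bps, start=1):
        atoms.append(
            AtomRecord(n_bp + res, "P", "DG", n_bp + res, "J", strand2[j],
                       spec.dna_phosphate_charge, PHOSPHATE_RADIUS)
        )
    for res, j in enumerate(bps, start=1):
        if abs(j) <= half:
            seg = "N-DNA"
        elif j < 0:
            seg = "L-DNA1"
        else:
            seg = "L-DNA2"
        table.append({"bp": j, "segment": seg, "p1": res, "p2": n_bp + res})

    core_ids = []
    next_id = 2 * n_bp + 1
    grid = np.arange(-CORE_SPHERE_RADIUS, CORE_SPHERE_RADIUS + 1e-6, CORE_BEAD_SPACING)
    res_index = 2 * n_bp
    for x in grid:
        for y in grid:
            for z in grid:
                p = np.array([x, y, z])
                if np.linalg.norm(p) <= CORE_SPHERE_RADIUS:
                    res_index += 1
                    atoms.append(
                        AtomRecord(next_id, "C", "COR", res_index, "C", p, 0.0,
                                   CORE_BEAD_RADIUS)
                    )
                    core_ids.append(next_id)
                    next_id += 1

    solute = Solute(atoms, label="ideal-nucleosome")
    return annotate_nucleosome(solute, pd.DataFrame(table), dyad_bp=0,
                               core_atom_ids=core_ids)


# ---------------------------------------------------------------------------
# Toy linker histone


def _local_dna_frame(nuc: NucleosomeModel, bp: int):
    """Estimated duplex frame at a base pair: (midpoint, t̂, minor-groove
    bisector b̂, duplex-axis point)."""
    sol = nuc.solute
    idx = {int(a): i for i, a in enumerate(sol.atom_ids)}
    pos = sol.positions

    def mid(b):
        row = nuc.bp_table.loc[nuc.bp_table["bp"] == b].iloc[0]
        return 0.5 * (pos[idx[int(row["p1"])]] + pos[idx[int(row["p2"])]])

    row = nuc.bp_table.loc[nuc.bp_table["bp"] == bp].iloc[0]
    p1 = pos[idx[int(row["p1"])]]
    p2 = pos[idx[int(row["p2"])]]
    m = 0.5 * (p1 + p2)
    t = mid(bp + 1) - mid(bp - 1)
    t /= np.linalg.norm(t)
    b = np.cross(p1 - p2, t)
    b /= np.linalg.norm(b)
    axis_point = m - PHOSPHATE_RING_RADIUS * np.cos(STRAND_HALF_PHASE) * b
    return m, t, b, axis_point, p1, p2


def _anchor(nuc: NucleosomeModel, bp: int):
    """A phosphate at this bp and the outward direction away from the duplex
    axis there; picks the strand whose P lies farther from the nucleosome
    center (the solvent-exposed one)."""
    _, _, _, axis_point, p1, p2 = _local_dna_frame(nuc, bp)
    center = nuc.solute.geometric_center
    p = p1 if np.linalg.norm(p1 - center) >= np.linalg.norm(p2 - center) else p2
    out = p - axis_point
    out /= np.linalg.norm(out)
    return p, out


def build_toy_lh(spec: FixtureSpec, nuc: NucleosomeModel | None = None) -> LHModel:
    """Construct the toy LH pre-placed in its on-dyad reference geometry.

    Reference coordinates are centered on the bead centroid; the world
    placement producing the on-dyad configuration is stored on
    ``solute.frame`` (and returned by :func:`place_reference_pose`).
    """
    from .classify import viewing_frame

    if nuc is None:
        nuc = build_ideal_nucleosome(spec)
    if spec.l_dna_bp < 5:
        raise ValueError("the toy LH needs linker arms of at least 5 bp")
    half = (spec.core_bp - 1) // 2
    arm_bp = half + min(9, spec.l_dna_bp - 1)  # a site ±3 base pair (outer arm)
    e1, e2, _ = viewing_frame(nuc)

    p_a3, out_a3 = _anchor(nuc, -arm_bp)
    a3_anchor = p_a3 + 3.4 * out_a3
    p_b1, out_b1 = _anchor(nuc, 0)
    b1_anchor = p_b1 + 3.4 * out_b1
    p_l1, out_l1 = _anchor(nuc, arm_bp)
    l1_anchor = p_l1 + 3.4 * out_l1

    coords: dict[int, np.ndarray] = {}

    def lerp(i0, i1, p0, p1):
        for i in range(i0, i1 + 1):
            f = (i - i0) / max(i1 - i0, 1)
            coords[i] = p0 + f * (np.asarray(p1) - np.asarray(p0))

    # alpha3: 25 beads through the site −3 anchor along the in-plane "up"
    # direction; away from the contact bead the helix lifts off the DNA
    # (the even lift keeps the N→C vector exactly along e2)
    for i in range(30, 55):
        delta = (i - 42) * 0.9
        lift = 0.5 * abs(delta) + 0.03 * delta * delta
        coords[i] = a3_anchor + delta * e2 + lift * out_a3
    # beta1: a hairpin retreating radially from the dyad contact — only the
    # apex bead touches the DNA
    t_dyad = _local_dna_frame(nuc, 0)[1]
    rad_b1 = np.array([b1_anchor[0], b1_anchor[1], 0.0])
    rad_b1 /= np.linalg.norm(rad_b1)
    for i in range(76, 82):
        k = 82 - i
        coords[i] = b1_anchor + 2.2 * k * rad_b1 + 0.8 * k * t_dyad
    coords[82] = b1_anchor
    for i in range(83, 88):
        k = i - 82
        coords[i] = b1_anchor + 2.2 * k * rad_b1 - 0.8 * k * t_dyad
    # scaffold helices: from the alpha3 top over the stem region to beta1
    mid = nuc.dyad_point + (STEM_OFFSET + 12.0) * nuc.dyad_axis + np.array([0.0, 2.0, 4.0])
    lerp(55, 63, coords[54] + 4.0 * out_a3, mid)  # alpha1
    lerp(64, 75, mid, coords[76] + 2.0 * rad_b1)  # alpha2
    # l1: from the beta1 hairpin down to the site +3 contact on L-DNA2,
    # approaching along the anchor's outward ray, then a short tail
    t_l1 = _local_dna_frame(nuc, arm_bp)[1]
    lerp(88, 89, coords[87] + 1.5 * rad_b1, l1_anchor + 9.0 * out_l1 - 2.0 * t_l1)
    coords[90] = l1_anchor + 6.0 * out_l1
    coords[91] = l1_anchor + 3.0 * out_l1
    coords[92] = l1_anchor
    coords[93] = l1_anchor + 3.0 * out_l1 + 1.6 * t_l1
    coords[94] = l1_anchor + 6.0 * out_l1 + 2.8 * t_l1
    last = LH_FIRST_RESIDUE + spec.lh_size - 1  # l1 end residue
    lerp(95, last, l1_anchor + 8.5 * out_l1 + 3.5 * t_l1,
         l1_anchor + 14.0 * out_l1 + 9.0 * t_l1)

    # residue identities and charges
    names = {i: _LH_RESIDUE_NAMES.get(i, "GLY") for i in coords}
    delta = spec.lh_net_charge - 11
    pool = [i for i in _LH_CHARGE_POOL if i in coords and names[i] == "GLY"]
    if abs(delta) > len(pool):
        raise ValueError(
            f"net charge {spec.lh_net_charge:+d} e unrealizable with ±1 e sites"
        )
    for i in pool[: abs(delta)]:
        names[i] = "LYS" if delta > 0 else "GLU"

    order = sorted(coords)
    world = np.array([coords[i] for i in order])
    centroid = world.mean(axis=0)
    atoms = []
    for k, i in enumerate(order, start=1):
        rname = names[i]
        q, radius, polar = RESIDUE_PARAMS[rname]
        atoms.append(
            AtomRecord(k, polar, rname, i, "A", world[k - 1] - centroid, float(q),
                       radius)
        )
    solute = Solute(atoms, label="toy-lh",
                    frame=RigidTransform(np.array([1.0, 0, 0, 0]), centroid))
    ranges = dict(LH_ELEMENT_RANGES)
    ranges["l1"] = (88, max(order))
    return annotate_lh_elements(solute, ranges, alpha3_n_terminus=30,
                                alpha3_c_terminus=54)


# ---------------------------------------------------------------------------
# Reference poses


_MODES = ("on-dyad", "off-dyad-L1", "off-dyad-L2")


def _arm_direction(nuc: NucleosomeModel, arm: str) -> np.ndarray:
    """Unit vector from the arm's junction toward its free end."""
    tab = nuc.bp_table
    rows = tab.loc[tab["segment"] == arm]
    sol = nuc.solute
    idx = {int(a): i for i, a in enumerate(sol.atom_ids)}
    pos = sol.positions

    def mid(row):
        return 0.5 * (pos[idx[int(row["p1"])]] + pos[idx[int(row["p2"])]])

    first = rows.loc[rows["bp"].abs().idxmin()]
    lastr = rows.loc[rows["bp"].abs().idxmax()]
    d = mid(lastr) - mid(first)
    return d / np.linalg.norm(d)


def place_reference_pose(
    lh: LHModel, nuc: NucleosomeModel, mode: str = "on-dyad"
) -> RigidTransform:
    """A non-overlapping pose whose classification matches ``mode``.

    The on-dyad pose is the toy LH's native placement.  Off-dyad poses
    slide it along the requested linker arm until only that arm's grooves
    remain in contact; the slide distance is searched deterministically
    and the result is verified (classification and excluded volume) before
    being returned.
    """
    from .classify import classify

    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    want = {
        "on-dyad": "on-dyad",
        "off-dyad-L1": "off-dyad-L-DNA1",
        "off-dyad-L2": "off-dyad-L-DNA2",
    }[mode]
    base = lh.solute.frame.copy()
    sol = nuc.solute
    from scipy.spatial import cKDTree

    tree = cKDTree(sol.positions)

    def clear_of_dna(pose: RigidTransform) -> bool:
        w = pose.apply(lh.solute.reference_positions)
        d, j = tree.query(w)
        return bool(np.all(d - (sol.radii[j] + 1.0) > 0.0))

    if mode == "on-dyad":
        cfg = classify(lh, base, nuc)
        if cfg.dyad_mode == want and clear_of_dna(base):
            return base
    else:
        candidates = []
        arm = "L-DNA1" if mode == "off-dyad-L1" else "L-DNA2"
        for d in (_arm_direction(nuc, "L-DNA1"), _arm_direction(nuc, "L-DNA2")):
            for slide in np.arange(1.0, 20.0, 0.25):
                candidates.append(
                    RigidTransform(base.quaternion.copy(),
                                   base.translation + slide * d)
                )
        if mode == "off-dyad-L2":
            # the dyad two-fold image of L-DNA1 poses lands on L-DNA2
            c2 = RigidTransform(
                quat_from_axis_angle(np.array([1.0, 0.0, 0.0]), np.pi),
                np.zeros(3),
            )
            candidates = [c2.compose(p) for p in candidates] + candidates
        for pose in candidates:
            cfg = classify(lh, pose, nuc)
            if cfg.dyad_mode == want and clear_of_dna(pose):
                return pose
    raise ValueError(f"unreachable geometry: no valid pose found for {mode}")


# ---------------------------------------------------------------------------
# Event streams


def synthetic_event_stream(
    n: int,
    seed: int,
    planted_clusters: int = 2,
    spread: float = 0.3,
    center_separation: float = 25.0,
) -> list[tuple[RigidTransform, float]]:
    """Poses drawn around k planted centers with energies lower near them.

    Deterministic per seed.  With ``spread = 0`` every event duplicates its
    cluster center exactly.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    k = planted_clusters
    centers_t = [
        np.array([center_separation * (i - (k - 1) / 2.0), 0.0, 0.0])
        + rng.uniform(-1.0, 1.0, 3)
        for i in range(k)
    ]
    centers_q = [random_quaternion(rng) for _ in range(k)]
    base_e = rng.uniform(-25.0, -15.0, k)
    events = []
    for _ in range(n):
        c = int(rng.integers(k))
        dt_vec = rng.normal(scale=max(spread, 0.0) / np.sqrt(3.0), size=3) if spread > 0 else np.zeros(3)
        if spread > 0:
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            ang = rng.normal(scale=spread / 60.0)
            dq = quat_from_axis_angle(axis, ang)
            q = RigidTransform(dq).compose(RigidTransform(centers_q[c])).quaternion
        else:
            q = centers_q[c]
        pose = RigidTransform(q, centers_t[c] + dt_vec)
        energy = float(base_e[c] + 3.0 * np.linalg.norm(dt_vec) + abs(rng.normal(scale=0.2)))
        events.append((pose, energy))
    return events


# ---------------------------------------------------------------------------
# Fixture files (PQR + annotation sidecars)


def write_fixture_files(lh: LHModel, nuc: NucleosomeModel, outdir) -> dict:
    """Write fixtures as PQR plus plain-text annotation sidecars."""
    from pathlib import Path

    from .structures import write_pqr

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "lh_pqr": out / "lh.pqr",
        "nuc_pqr": out / "nucleosome.pqr",
        "lh_elements": out / "lh_elements.csv",
        "nuc_bp": out / "nucleosome_bp.csv",
        "lh_frame": out / "lh_reference_pose.csv",
    }
    lh_ref = lh.solute.copy()
    lh_ref.frame = RigidTransform.identity()  # write reference coordinates
    write_pqr(lh_ref, paths["lh_pqr"])
    write_pqr(nuc.solute, paths["nuc_pqr"])
    rows = [
        {"element": name, "first": lo, "last": hi}
        for name, (lo, hi) in lh.elements.items()
    ]
    rows.append({"element": "alpha3_n_terminus", "first": lh.alpha3_n_terminus,
                 "last": lh.alpha3_n_terminus})
    rows.append({"element": "alpha3_c_terminus", "first": lh.alpha3_c_terminus,
                 "last": lh.alpha3_c_terminus})
    pd.DataFrame(rows).to_csv(paths["lh_elements"], index=False)
    tab = nuc.bp_table.copy()
    tab["core"] = ""
    pd.DataFrame(tab).to_csv(paths["nuc_bp"], index=False)
    with open(paths["lh_frame"], "w") as fh:
        q = lh.solute.frame.quaternion
        t = lh.solute.frame.translation
        fh.write("qw,qx,qy,qz,tx,ty,tz\n")
        fh.write(",".join(f"{x:.10f}" for x in (*q, *t)) + "\n")
    with open(out / "nucleosome_core_ids.csv", "w") as fh:
        fh.write("atom_id\n")
        for a in nuc.core_atom_ids:
            fh.write(f"{int(a)}\n")
    paths["core_ids"] = out / "nucleosome_core_ids.csv"
    return paths


def load_fixture_files(outdir) -> tuple[LHModel, NucleosomeModel]:
    """Rebuild the annotated models from fixture files (the same path real
    structures take)."""
    from pathlib import Path

    from .structures import read_pqr

    out = Path(outdir)
    lh_sol = read_pqr(out / "lh.pqr")
    elem = pd.read_csv(out / "lh_elements.csv")
    ranges = {}
    termini = {}
    for _, row in elem.iterrows():
        if str(row["element"]).startswith("alpha3_"):
            termini[str(row["element"])] = int(row["first"])
        else:
            ranges[str(row["element"])] = (int(row["first"]), int(row["last"]))
    frame = pd.read_csv(out / "lh_reference_pose.csv").iloc[0]
    lh_sol.frame = RigidTransform(
        np.array([frame["qw"], frame["qx"], frame["qy"], frame["qz"]]),
        np.array([frame["tx"], frame["ty"], frame["tz"]]),
    )
    lh = annotate_lh_elements(
        lh_sol, ranges,
        alpha3_n_terminus=termini.get("alpha3_n_terminus"),
        alpha3_c_terminus=termini.get("alpha3_c_terminus"),
    )
    nuc_sol = read_pqr(out / "nucleosome.pqr")
    tab = pd.read_csv(out / "nucleosome_bp.csv")
    core = pd.read_csv(out / "nucleosome_core_ids.csv")["atom_id"].astype(int).tolist()
    nuc = annotate_nucleosome(nuc_sol, tab[["bp", "segment", "p1", "p2"]],
                              dyad_bp=0, core_atom_ids=core)
    return lh, nuc
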