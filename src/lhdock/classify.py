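"""Groove-indexed classification of docked LH–nucleosome configurations.

DNA grooves are labeled by a signed index: 0 is the minor groove at the
dyad and ±k the k-th outward-facing major groove walking from the dyad
toward L-DNA2 (+) or L-DNA1 (−), one site per helical turn (10.4 bp by
default, so centers sit at ±(10.4·k − 5.2) bp).  A docked pose is reduced
to the groove contacts of the three DNA-binding elements of the LH
(α3, β1, l1), an eight-point compass arrow for the α3 N→C direction
projected on the dyad viewing plane (X when the helix points along the
dyad axis), and an on-dyad/off-dyad call.  Rendered strings follow the
"(−3↑, 0, +3)" style, with "no" for an element without DNA contacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import RigidTransform
from .structures import CONTACT_ELEMENTS, LHModel, NucleosomeModel

__all__ = [
    "GrooveSite",
    "Configuration",
    "ARROWS",
    "enumerate_groove_sites",
    "viewing_frame",
    "element_contacts",
    "alpha3_symbol",
    "classify",
    "compare_configurations",
    "build_match_matrix",
]

#: Eight compass arrows at azimuths 0°, 45°, … 315° in the viewing plane
#: (0° points from the dyad toward the L-DNA2 arm, counterclockwise viewed
#: down the dyad axis).
ARROWS = ("→", "↗", "↑", "↖", "←", "↙", "↓", "↘")

DEFAULT_CONTACT_CUTOFF = 5.0  # Å, element atom to groove phosphate
DEFAULT_HELICAL_REPEAT = 10.4  # bp per turn
DEFAULT_THETA_X = 30.0  # deg; X symbol when the helix is this close to the axis


@dataclass
class GrooveSite:
    """One labeled DNA groove: index, center and member phosphates."""

    index: int
    center: np.ndarray
    member_atom_ids: np.ndarray
    segment: str


@dataclass
class Configuration:
    """Per-element groove contacts plus α3 arrow and dyad-mode call."""

    contacts: dict[str, list[int]]
    alpha3_symbol: str
    dyad_mode: str

    @property
    def contacted(self) -> set[int]:
        out: set[int] = set()
        for lst in self.contacts.values():
            out.update(lst)
        return out

    def render(self) -> str:
        def fmt(indices: list[int]) -> str:
            if not indices:
                return "no"
            return " ".join(f"+{i}" if i > 0 else str(i) for i in indices)

        a3 = fmt(self.contacts["alpha3"]) + self.alpha3_symbol
        return f"({a3}, {fmt(self.contacts['beta1'])}, {fmt(self.contacts['l1'])})"

    def __str__(self) -> str:
        return self.render()


def enumerate_groove_sites(
    nuc: NucleosomeModel,
    helical_repeat: float = DEFAULT_HELICAL_REPEAT,
) -> list[GrooveSite]:
    """Label the groove sites used for configuration calls.

    Site 0 is the dyad minor groove (base pairs within a quarter turn of the
    dyad); sites ±1 are the neighboring N-DNA major grooves (out to ~3/4
    turn); sites ±2, ±3, … walk the linker arms in half-turn (5.2 bp) steps
    to the arm ends — the grooves visible along each arm.  N-DNA beyond ±1
    carries no label.  A site's member phosphates are the P atoms of its
    base pairs on both strands; its center is their centroid.  For the
    147+10+10 bp fixture this yields sites 0, ±1, ±2, ±3.
    """
    half_turn = helical_repeat / 2.0
    tab = nuc.bp_table
    ndna = tab.loc[tab["segment"] == "N-DNA", "bp"]
    if ndna.empty:
        raise ValueError("no N-DNA base pairs in the table")
    ndna_max = int(ndna.abs().max())
    arm_per_side = int((tab["segment"] == "L-DNA2").sum())
    if ndna_max < helical_repeat or arm_per_side < half_turn:
        warnings.warn("DNA shorter than one helical turn per side; few groove sites")

    def site_of(bp: int, segment: str) -> int | None:
        a = abs(bp)
        sign = 1 if bp > 0 else -1
        if segment == "N-DNA":
            if a <= half_turn / 2:
                return 0
            if a <= 1.5 * half_turn:
                return sign
            return None
        j = int((a - ndna_max - 0.5) // half_turn)
        return sign * (2 + j)

    assign = [site_of(int(b), str(s)) for b, s in zip(tab["bp"], tab["segment"])]
    pos = nuc.solute.positions
    id_to_idx = {int(a): i for i, a in enumerate(nuc.solute.atom_ids)}
    sites: list[GrooveSite] = []
    for k in sorted({a for a in assign if a is not None}):
        rows = tab.loc[[a == k for a in assign]]
        ids = np.concatenate([rows["p1"].to_numpy(), rows["p2"].to_numpy()]).astype(int)
        coords = pos[[id_to_idx[i] for i in ids]]
        seg = rows["segment"].mode().iloc[0]
        sites.append(GrooveSite(int(k), coords.mean(axis=0), ids, str(seg)))
    return sites


def viewing_frame(nuc: NucleosomeModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (e1, e2, n) of the dyad viewing plane.

    ``n`` is the dyad axis; ``e1`` (azimuth 0°) points from the dyad toward
    the L-DNA2 arm, projected on the plane; ``e2 = n × e1`` so azimuth grows
    counterclockwise when viewed down the dyad axis.
    """
    n = nuc.dyad_axis / np.linalg.norm(nuc.dyad_axis)
    arm = nuc.bp_table.loc[nuc.bp_table["segment"] == "L-DNA2"]
    if arm.empty:  # fall back to the positive-bp end of the core DNA
        arm = nuc.bp_table.loc[nuc.bp_table["bp"] == nuc.bp_table["bp"].max()]
    idx = nuc.phosphate_atom_indices(arm)
    target = nuc.solute.positions[idx].mean(axis=0)
    v = target - nuc.dyad_point
    v -= np.dot(v, n) * n
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("L-DNA2 arm projects onto the dyad point; frame undefined")
    e1 = v / norm
    e2 = np.cross(n, e1)
    return e1, e2, n


def element_contacts(
    lh: LHModel,
    pose: RigidTransform,
    sites: list[GrooveSite],
    nuc: NucleosomeModel,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> dict[str, list[int]]:
    """Groove indices contacted by each of α3, β1 and l1.

    An element contacts site k when any of its atoms lies within ``cutoff``
    of any member phosphate of that site.
    """
    pos = nuc.solute.positions
    id_to_idx = {int(a): i for i, a in enumerate(nuc.solute.atom_ids)}
    ph_coords = []
    ph_site = []
    for s in sites:
        ph_coords.append(pos[[id_to_idx[i] for i in s.member_atom_ids]])
        ph_site.extend([s.index] * len(s.member_atom_ids))
    tree = cKDTree(np.concatenate(ph_coords))
    ph_site = np.array(ph_site)
    world = pose.apply(lh.solute.reference_positions)
    out: dict[str, list[int]] = {}
    for element in CONTACT_ELEMENTS:
        mask = lh.element_atom_mask(element)
        hits = tree.query_ball_point(world[mask], r=cutoff)
        found = sorted({int(ph_site[j]) for row in hits for j in row})
        out[element] = found
    return out


def alpha3_symbol(
    lh: LHModel,
    pose: RigidTransform,
    nuc: NucleosomeModel,
    theta_x: float = DEFAULT_THETA_X,
) -> str:
    """Compass arrow of the α3 N→C direction in the viewing plane, or X.

    X is returned when the helix vector leans out of the viewing plane by
    more than 90° − ``theta_x``, i.e. lies within ``theta_x`` of the dyad
    axis.
    """
    world = pose.apply(lh.solute.reference_positions)
    n_pos = world[lh.residue_mask(lh.alpha3_n_terminus)].mean(axis=0)
    c_pos = world[lh.residue_mask(lh.alpha3_c_terminus)].mean(axis=0)
    vec = c_pos - n_pos
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        raise ValueError("zero-length alpha3 helix vector")
    vec /= norm
    e1, e2, n = viewing_frame(nuc)
    out_of_plane = np.degrees(np.arcsin(np.clip(abs(np.dot(vec, n)), 0.0, 1.0)))
    if out_of_plane > 90.0 - theta_x:
        return "X"
    azimuth = np.degrees(np.arctan2(np.dot(vec, e2), np.dot(vec, e1))) % 360.0
    return ARROWS[int(np.floor((azimuth + 22.5) / 45.0)) % 8]


def classify(
    lh: LHModel,
    pose: RigidTransform,
    nuc: NucleosomeModel,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    sites: list[GrooveSite] | None = None,
    helical_repeat: float = DEFAULT_HELICAL_REPEAT,
    theta_x: float = DEFAULT_THETA_X,
) -> Configuration:
    """Full configuration call for one docked pose."""
    if sites is None:
        sites = enumerate_groove_sites(nuc, helical_repeat)
    contacts = element_contacts(lh, pose, sites, nuc, cutoff)
    symbol = alpha3_symbol(lh, pose, nuc, theta_x)
    touched = set()
    for lst in contacts.values():
        touched.update(lst)
    if not touched:
        mode = "no-contact"
    elif 0 in touched:
        mode = "on-dyad"
    elif all(k < 0 for k in touched):
        mode = "off-dyad-L-DNA1"
    elif all(k > 0 for k in touched):
        mode = "off-dyad-L-DNA2"
    else:
        mode = "mixed"
    return Configuration(contacts, symbol, mode)


def compare_configurations(variant: Configuration, reference: Configuration) -> str:
    """Match category of a variant configuration against a reference.

    ``identical`` — all three element contact lists equal; ``partial`` —
    one or two equal; ``different`` — none equal.
    """
    same = sum(
        variant.contacts[e] == reference.contacts[e] for e in CONTACT_ELEMENTS
    )
    return {3: "identical", 0: "different"}.get(same, "partial")


def build_match_matrix(
    runs: dict[tuple[str, str], Configuration],
    reference_variant: str = "WT",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Tabulate variant configurations against the wild type per conformer.

    ``runs`` maps (variant label, nucleosome-conformer label) to the top
    cluster's configuration.  Returns a long-form table (variant, conformer,
    configuration string, category vs the WT on the same conformer) and the
    per-variant count of shifted configurations (category not identical).
    """
    rows = []
    variants = sorted({v for v, _ in runs}, key=lambda v: (v != reference_variant, v))
    conformers = sorted({c for _, c in runs})
    shift_counts: dict[str, int] = {}
    for v in variants:
        shifts = 0
        for c in conformers:
            cfg = runs.get((v, c))
            if cfg is None:
                continue
            ref = runs.get((reference_variant, c))
            if ref is None:
                category = "undefined"
            elif v == reference_variant:
                category = "identical"
            else:
                category = compare_configurations(cfg, ref)
            if category in ("partial", "different"):
                shifts += 1
            rows.append(
                {
                    "variant": v,
                    "conformer": c,
                    "configuration": cfg.render(),
                    "dyad_mode": cfg.dyad_mode,
                    "category": category,
                }
            )
        shift_counts[v] = shifts
    return pd.DataFrame(rows), shift_counts
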