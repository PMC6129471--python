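"""Hydrogen-bond counting between docked LH poses and the DNA backbone.

A hydrogen bond is called on heavy-atom distance alone: an LH polar atom
(side-chain or backbone N/O) paired with a DNA phosphate-backbone acceptor
(OP1/OP2, O3', O5'; the bare P pseudo-atom stands in for the whole
phosphate group on coarse bead models) at a donor–acceptor distance inside
a closed window, 3.2–3.6 Å by default.  A conventional mode with no lower
bound (0–3.6 Å) is available behind ``enforce_lower_bound=False`` since
the two-sided window is unusual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import RigidTransform
from .structures import LHModel, NucleosomeModel

__all__ = [
    "HBond",
    "DNA_ACCEPTOR_NAMES",
    "find_hbonds",
    "hbond_count_table",
    "aggregate_hbonds",
]

DEFAULT_D_MIN = 3.2  # Å
DEFAULT_D_MAX = 3.6  # Å

#: DNA phosphate-backbone acceptor atom names (both APBS/PDB oxygen naming
#: conventions, plus the bare P pseudo-atom of coarse bead models).
DNA_ACCEPTOR_NAMES = ("OP1", "OP2", "O1P", "O2P", "O3'", "O5'", "P")


@dataclass(frozen=True)
class HBond:
    """One LH–DNA hydrogen bond (heavy-atom distance criterion)."""

    lh_residue_index: int
    lh_residue_name: str
    lh_atom_name: str
    dna_atom_id: int
    distance: float


def _polar_mask(lh: LHModel) -> np.ndarray:
    names = lh.solute.atom_names
    return np.array(
        [str(n).startswith(("N", "O")) for n in names], dtype=bool
    )


def find_hbonds(
    lh: LHModel,
    pose: RigidTransform,
    nuc: NucleosomeModel,
    d_min: float = DEFAULT_D_MIN,
    d_max: float = DEFAULT_D_MAX,
    enforce_lower_bound: bool = True,
    acceptor_names: Sequence[str] = DNA_ACCEPTOR_NAMES,
) -> list[HBond]:
    """All qualifying LH-polar / DNA-acceptor pairs, deterministically ordered.

    Each (LH atom, DNA atom) pair is counted once; ordering is by LH
    residue, LH atom, DNA atom id.
    """
    if not (0 <= d_min <= d_max):
        raise ValueError(f"invalid distance window [{d_min}, {d_max}]")
    lo = d_min if enforce_lower_bound else 0.0
    lh_mask = _polar_mask(lh)
    lh_idx = np.nonzero(lh_mask)[0]
    if len(lh_idx) == 0:
        return []
    acc_mask = np.isin(nuc.solute.atom_names, list(acceptor_names))
    acc_idx = np.nonzero(acc_mask)[0]
    if len(acc_idx) == 0:
        return []
    lh_pos = pose.apply(lh.solute.reference_positions[lh_idx])
    acc_pos = nuc.solute.positions[acc_idx]
    tree = cKDTree(acc_pos)
    hits = tree.query_ball_point(lh_pos, r=d_max)
    bonds: list[HBond] = []
    sol = lh.solute
    for k, (a, row) in enumerate(zip(lh_idx, hits)):
        for j in row:
            d = float(np.linalg.norm(lh_pos[k] - acc_pos[j]))
            if lo <= d <= d_max:
                bonds.append(
                    HBond(
                        int(sol.residue_indices[a]),
                        str(sol.residue_names[a]),
                        str(sol.atom_names[a]),
                        int(nuc.solute.atom_ids[acc_idx[j]]),
                        d,
                    )
                )
    bonds.sort(key=lambda b: (b.lh_residue_index, b.lh_atom_name, b.dna_atom_id))
    return bonds


def hbond_count_table(bonds: Iterable[HBond]) -> pd.DataFrame:
    """Per-residue bond counts of one docked pose."""
    rows = [
        {"residue_index": b.lh_residue_index, "residue_name": b.lh_residue_name}
        for b in bonds
    ]
    if not rows:
        return pd.DataFrame(columns=["residue_index", "residue_name", "count"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["residue_index", "residue_name"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return out.sort_values("residue_index").reset_index(drop=True)


def aggregate_hbonds(
    tables: Mapping[tuple, Iterable[HBond]],
) -> pd.DataFrame:
    """Aggregate per-pose H-bond lists over runs and cluster ranks.

    ``tables`` maps (run label, cluster rank) — or any hashable key — to the
    H-bond list of that docked representative.  Returns per-residue totals
    plus a ``multi_bond`` flag marking residues that make more than one
    H-bond within a single docked position.  Raises on inconsistent residue
    naming across runs.
    """
    per_pose: list[pd.DataFrame] = []
    for key, bonds in tables.items():
        tab = hbond_count_table(bonds)
        tab["source"] = [key] * len(tab)
        per_pose.append(tab)
    if not per_pose:
        return pd.DataFrame(
            columns=["residue_index", "residue_name", "count", "multi_bond"]
        )
    allb = pd.concat(per_pose, ignore_index=True)
    names = allb.groupby("residue_index")["residue_name"].nunique()
    clashes = names[names > 1].index.tolist()
    if clashes:
        raise ValueError(f"inconsistent residue names across runs at {clashes}")
    agg = (
        allb.groupby(["residue_index", "residue_name"], as_index=False)["count"]
        .sum()
    )
    multi = allb.groupby("residue_index")["count"].max() > 1
    agg["multi_bond"] = agg["residue_index"].map(multi).fillna(False).astype(bool)
    return agg.sort_values("residue_index").reset_index(drop=True)
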