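"""Annotated rigid-body structure model for the linker histone and nucleosome.

Solutes are ordered atom lists (positions in Å, partial charges in e, radii
in Å) carried around with a rigid-body frame, the way Brownian-dynamics
docking codes treat their species.  Two annotated views sit on top:

* :class:`LHModel` — a linker-histone globular domain with its structural
  elements (three α-helices, the β1 wing, the l1 loop) mapped to residue
  ranges, plus the α3 helix termini used for orientation arrows.
* :class:`NucleosomeModel` — the nucleosome with a base-pair table (signed
  bp index, 0 at the dyad), segment labels (N-DNA and the two linker arms
  L-DNA1/L-DNA2), phosphate atom ids per strand, and the dyad point/axis.

Structures are read and written as PQR (whitespace-delimited; the chain
column is optional and extra columns are ignored).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import RigidTransform

__all__ = [
    "AtomRecord",
    "Solute",
    "LHModel",
    "NucleosomeModel",
    "ELEMENT_NAMES",
    "read_pqr",
    "write_pqr",
    "read_pdb_atoms",
    "net_formal_charge",
    "annotate_lh_elements",
    "annotate_nucleosome",
]

#: Canonical (ASCII) names of the LH structural elements.
ELEMENT_NAMES = ("alpha1", "alpha2", "alpha3", "beta1", "l1")

_ELEMENT_ALIASES = {
    "α1": "alpha1",
    "α2": "alpha2",
    "α3": "alpha3",
    "β1": "beta1",
    "a1": "alpha1",
    "a2": "alpha2",
    "a3": "alpha3",
    "b1": "beta1",
}

#: Elements whose DNA-groove contacts are classified downstream.
CONTACT_ELEMENTS = ("alpha3", "beta1", "l1")

_FORMAL_CHARGES = {
    "LYS": 1,
    "ARG": 1,
    "HIS": 0,
    "ASP": -1,
    "GLU": -1,
    "SEP": -2,  # phosphoserine
    "MLZ": 1,  # methylated lysine variants keep the +1
    "MLY": 1,
    "M2L": 1,
}


def canonical_element(name: str) -> str:
    key = _ELEMENT_ALIASES.get(name, name).lower()
    key = _ELEMENT_ALIASES.get(key, key)
    if key not in ELEMENT_NAMES:
        raise ValueError(f"unknown LH element {name!r}; expected one of {ELEMENT_NAMES}")
    return key


@dataclass
class AtomRecord:
    """One atom of a solute: identity, position (Å), charge (e), radius (Å)."""

    atom_id: int
    atom_name: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    partial_charge: float
    radius: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_id}: position must be a finite 3-vector")
        if self.radius < 0:
            raise ValueError(f"atom {self.atom_id}: negative radius {self.radius}")


class Solute:
    """An ordered atom list with a rigid-body frame.

    Reference coordinates are immutable once constructed; the solute's
    current coordinates are ``frame.apply(reference)``.  Column arrays are
    used internally so that docking stages can work on plain numpy data.
    """

    def __init__(self, atoms: Iterable[AtomRecord], label: str = "",
                 frame: RigidTransform | None = None):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a solute needs at least one atom")
        self.label = label
        self.frame = frame if frame is not None else RigidTransform.identity()
        self.atom_ids = np.array([a.atom_id for a in atoms], dtype=int)
        self.atom_names = np.array([a.atom_name for a in atoms], dtype=object)
        self.residue_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.residue_indices = np.array([a.residue_index for a in atoms], dtype=int)
        self.chain_ids = np.array([a.chain_id for a in atoms], dtype=object)
        self.reference_positions = np.array([a.position for a in atoms], dtype=float)
        self.charges = np.array([a.partial_charge for a in atoms], dtype=float)
        self.radii = np.array([a.radius for a in atoms], dtype=float)
        if np.any(self.radii < 0) or not np.all(np.isfinite(self.reference_positions)):
            raise ValueError("invalid atom data (negative radius or non-finite position)")

    def __len__(self) -> int:
        return len(self.atom_ids)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                int(self.atom_ids[i]),
                str(self.atom_names[i]),
                str(self.residue_names[i]),
                int(self.residue_indices[i]),
                str(self.chain_ids[i]),
                self.reference_positions[i].copy(),
                float(self.charges[i]),
                float(self.radii[i]),
            )
            for i in range(len(self))
        ]

    @property
    def positions(self) -> np.ndarray:
        """Current coordinates (frame applied to the reference)."""
        return self.frame.apply(self.reference_positions)

    @property
    def geometric_center(self) -> np.ndarray:
        """Unweighted mean of the current atom positions."""
        return self.positions.mean(axis=0)

    @property
    def reference_center(self) -> np.ndarray:
        return self.reference_positions.mean(axis=0)

    @property
    def total_charge(self) -> float:
        """Unrounded sum of partial charges, in e."""
        return float(self.charges.sum())

    def with_frame(self, frame: RigidTransform) -> "Solute":
        out = self.copy()
        out.frame = frame.copy()
        return out

    def copy(self) -> "Solute":
        out = object.__new__(Solute)
        out.label = self.label
        out.frame = self.frame.copy()
        for name in ("atom_ids", "atom_names", "residue_names", "residue_indices",
                     "chain_ids", "reference_positions", "charges", "radii"):
            setattr(out, name, getattr(self, name).copy())
        return out

    def atom_index_of(self, atom_id: int) -> int:
        idx = np.nonzero(self.atom_ids == atom_id)[0]
        if len(idx) == 0:
            raise KeyError(f"no atom with id {atom_id}")
        return int(idx[0])


def net_formal_charge(solute: Solute) -> int:
    """Net charge of the solute, in e, as the rounded sum of partial charges."""
    return int(round(solute.total_charge))


# ---------------------------------------------------------------------------
# PQR / PDB I/O


def read_pqr(path) -> Solute:
    """Read a whitespace-delimited PQR file into a :class:`Solute`.

    The chain-id column is optional (PDB2PQR emits both dialects); columns
    beyond the radius are ignored.  Raises :class:`ValueError` naming the
    offending line on malformed input.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
        name = getattr(path, "name", "<stream>")
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
        name = str(path)
    atoms: list[AtomRecord] = []
    for lineno, line in enumerate(lines, start=1):
        tok = line.split()
        if not tok or tok[0] not in ("ATOM", "HETATM"):
            continue
        try:
            if len(tok) >= 11:
                chain = tok[4]
                serial, aname, rname, rid = tok[1], tok[2], tok[3], tok[5]
                x, y, z, q, r = tok[6:11]
            elif len(tok) == 10:
                chain = ""
                serial, aname, rname, rid = tok[1], tok[2], tok[3], tok[4]
                x, y, z, q, r = tok[5:10]
            else:
                raise ValueError("expected 10 or 11 whitespace-separated fields")
            atoms.append(
                AtomRecord(
                    atom_id=int(serial),
                    atom_name=aname,
                    residue_name=rname,
                    residue_index=int(rid),
                    chain_id=chain,
                    position=np.array([float(x), float(y), float(z)]),
                    partial_charge=float(q),
                    radius=float(r),
                )
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{name}: malformed PQR line {lineno}: {exc}") from exc
    if not atoms:
        raise ValueError(f"{name}: no ATOM/HETATM records found")
    return Solute(atoms, label=name)


def write_pqr(solute: Solute, path) -> None:
    """Write the solute's *current* (frame-transformed) coordinates as PQR."""
    if len(solute) == 0:
        raise ValueError("refusing to write an empty solute")
    pos = solute.positions
    buf = io.StringIO()
    for i in range(len(solute)):
        chain = str(solute.chain_ids[i]) or ""
        chain_field = f" {chain:>1s}" if chain else ""
        buf.write(
            f"ATOM  {int(solute.atom_ids[i]):>5d} {str(solute.atom_names[i]):<4s} "
            f"{str(solute.residue_names[i]):<4s}{chain_field} "
            f"{int(solute.residue_indices[i]):>4d} "
            f"{pos[i, 0]:>10.4f} {pos[i, 1]:>10.4f} {pos[i, 2]:>10.4f} "
            f"{solute.charges[i]:>8.4f} {solute.radii[i]:>7.4f}\n"
        )
    buf.write("END\n")
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def read_pdb_atoms(path, label: str = "") -> Solute:
    """Read ATOM records of a PDB file (annotation convenience; no charges).

    Charges and radii are zero; uses Biopython's parser.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(label or "pdb", path)
    atoms = []
    serial = 0
    for atom in structure.get_atoms():
        res = atom.get_parent()
        het, resseq, _ = res.get_id()
        if het.strip():
            continue
        serial += 1
        atoms.append(
            AtomRecord(
                atom_id=serial,
                atom_name=atom.get_name(),
                residue_name=res.get_resname(),
                residue_index=int(resseq),
                chain_id=res.get_parent().id,
                position=np.asarray(atom.get_coord(), dtype=float),
                partial_charge=0.0,
                radius=0.0,
            )
        )
    if not atoms:
        raise ValueError(f"{path}: no ATOM records")
    return Solute(atoms, label=label or str(path))


# ---------------------------------------------------------------------------
# Annotated models


@dataclass
class LHModel:
    """Linker-histone GD: solute plus structural-element annotation."""

    solute: Solute
    elements: dict[str, tuple[int, int]]
    alpha3_n_terminus: int
    alpha3_c_terminus: int
    ptm_labels: list[str] = field(default_factory=list)

    def element_atom_mask(self, element: str) -> np.ndarray:
        lo, hi = self.elements[canonical_element(element)]
        rid = self.solute.residue_indices
        return (rid >= lo) & (rid <= hi)

    def residue_mask(self, residue_index: int) -> np.ndarray:
        return self.solute.residue_indices == residue_index

    @property
    def net_formal_charge(self) -> int:
        return net_formal_charge(self.solute)

    def copy(self) -> "LHModel":
        return LHModel(
            self.solute.copy(),
            dict(self.elements),
            self.alpha3_n_terminus,
            self.alpha3_c_terminus,
            list(self.ptm_labels),
        )


def annotate_lh_elements(
    solute: Solute,
    ranges: Mapping[str, tuple[int, int]],
    alpha3_n_terminus: int | None = None,
    alpha3_c_terminus: int | None = None,
) -> LHModel:
    """Attach element annotation (residue-index ranges) to an LH solute.

    Ranges are inclusive and must be non-overlapping and within the solute's
    residue span; the α3 termini default to the ends of the α3 range.
    """
    norm: dict[str, tuple[int, int]] = {}
    for name, (lo, hi) in ranges.items():
        key = canonical_element(name)
        if hi < lo:
            raise ValueError(f"element {key}: empty range ({lo}, {hi})")
        norm[key] = (int(lo), int(hi))
    rid = solute.residue_indices
    rmin, rmax = int(rid.min()), int(rid.max())
    spans = sorted(norm.items(), key=lambda kv: kv[1])
    for (n1, (a1, b1)), (n2, (a2, b2)) in zip(spans, spans[1:]):
        if a2 <= b1:
            raise ValueError(f"element ranges overlap: {n1} {a1}-{b1} vs {n2} {a2}-{b2}")
    for name, (lo, hi) in norm.items():
        if lo < rmin or hi > rmax:
            raise ValueError(
                f"element {name} range {lo}-{hi} outside residue span {rmin}-{rmax}"
            )
    if "alpha3" not in norm:
        raise ValueError("an alpha3 range is required")
    a3lo, a3hi = norm["alpha3"]
    n_t = a3lo if alpha3_n_terminus is None else int(alpha3_n_terminus)
    c_t = a3hi if alpha3_c_terminus is None else int(alpha3_c_terminus)
    for t in (n_t, c_t):
        if not (a3lo <= t <= a3hi):
            raise ValueError(f"alpha3 terminus {t} outside the alpha3 range {a3lo}-{a3hi}")
    return LHModel(solute, norm, n_t, c_t)


@dataclass
class NucleosomeModel:
    """Nucleosome: solute plus dyad frame and base-pair bookkeeping.

    ``bp_table`` has one row per base pair with columns ``bp`` (signed index,
    0 at the dyad), ``segment`` (N-DNA / L-DNA1 / L-DNA2) and ``p1`` / ``p2``
    (phosphate atom ids of the two strands).
    """

    solute: Solute
    dyad_point: np.ndarray
    dyad_axis: np.ndarray
    bp_table: pd.DataFrame
    core_atom_ids: np.ndarray

    def phosphate_atom_indices(self, bp_rows: pd.DataFrame | None = None) -> np.ndarray:
        rows = self.bp_table if bp_rows is None else bp_rows
        ids = np.concatenate([rows["p1"].to_numpy(), rows["p2"].to_numpy()])
        lookup = {int(a): i for i, a in enumerate(self.solute.atom_ids)}
        return np.array([lookup[int(a)] for a in ids], dtype=int)

    def segment_of_bp(self, bp: int) -> str:
        row = self.bp_table.loc[self.bp_table["bp"] == bp]
        if row.empty:
            raise KeyError(f"no base pair {bp}")
        return str(row["segment"].iloc[0])

    def swap_arm_labels(self) -> "NucleosomeModel":
        """Relabel L-DNA1 <-> L-DNA2 and renumber bp indices accordingly."""
        tab = self.bp_table.copy()
        tab["segment"] = tab["segment"].map(
            {"N-DNA": "N-DNA", "L-DNA1": "L-DNA2", "L-DNA2": "L-DNA1"}
        )
        tab["bp"] = -tab["bp"].to_numpy()
        tab = tab.sort_values("bp").reset_index(drop=True)
        return NucleosomeModel(
            self.solute, self.dyad_point.copy(), self.dyad_axis.copy(), tab,
            self.core_atom_ids.copy(),
        )


_SEGMENTS = ("N-DNA", "L-DNA1", "L-DNA2")


def annotate_nucleosome(
    solute: Solute,
    bp_map: pd.DataFrame | Sequence[Mapping],
    dyad_bp: int = 0,
    core_atom_ids: Sequence[int] | None = None,
    phosphate_atom_name: str = "P",
) -> NucleosomeModel:
    """Build a :class:`NucleosomeModel` from a solute and a base-pair map.

    The dyad point is the midpoint of the dyad base pair's two phosphates;
    the dyad axis points from the superhelix center (centroid of the N-DNA
    phosphates) through the dyad point.
    """
    tab = pd.DataFrame(bp_map).copy()
    required = {"bp", "segment", "p1", "p2"}
    if not required.issubset(tab.columns):
        raise ValueError(f"bp_map needs columns {sorted(required)}")
    tab["bp"] = tab["bp"].astype(int)
    if (tab["bp"] == dyad_bp).sum() != 1:
        raise ValueError(f"bp_map must contain exactly one dyad base pair (bp={dyad_bp})")
    if tab["bp"].duplicated().any():
        raise ValueError("duplicate bp indices in bp_map")
    bad = set(tab["segment"]) - set(_SEGMENTS)
    if bad:
        raise ValueError(f"unknown segment labels {sorted(bad)}")
    known_ids = set(int(a) for a in solute.atom_ids)
    for col in ("p1", "p2"):
        missing = set(int(a) for a in tab[col]) - known_ids
        if missing:
            raise ValueError(f"bp_map references unknown atom ids {sorted(missing)[:5]}")
    # every phosphate-bearing residue must be covered
    p_ids = set(int(a) for a in solute.atom_ids[solute.atom_names == phosphate_atom_name])
    covered = set(int(a) for a in tab["p1"]) | set(int(a) for a in tab["p2"])
    omitted = p_ids - covered
    if omitted:
        raise ValueError(
            f"bp_map omits phosphate atoms {sorted(omitted)[:5]} "
            "(every DNA residue must appear)"
        )
    tab = tab.sort_values("bp").reset_index(drop=True)

    pos = solute.positions
    idx = {int(a): i for i, a in enumerate(solute.atom_ids)}
    dyad_row = tab.loc[tab["bp"] == dyad_bp].iloc[0]
    dyad_point = 0.5 * (pos[idx[int(dyad_row["p1"])]] + pos[idx[int(dyad_row["p2"])]])
    ndna = tab.loc[tab["segment"] == "N-DNA"]
    nd_idx = np.array(
        [idx[int(a)] for a in np.concatenate([ndna["p1"].to_numpy(), ndna["p2"].to_numpy()])]
    )
    center = pos[nd_idx].mean(axis=0)
    axis = dyad_point - center
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("degenerate dyad axis (dyad point coincides with superhelix center)")
    core = np.asarray(core_atom_ids if core_atom_ids is not None else [], dtype=int)
    return NucleosomeModel(solute, dyad_point, axis / norm, tab, core)
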