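"""Point mutations and PTMs as parameter-level edits on an LH model.

Rigid-body electrostatic docking sees a variant only through its charges,
radii and polar-site identities, so mutations are applied by swapping the
side-chain parameters of a residue for those of the target residue and
PTMs by applying a net-charge/radius delta at the modified site — no
rotamer search or structure rebuilding.  Charge bookkeeping follows formal
charges: K→V removes +1 e, V→K adds +1 e, phosphoserine is the phosphate
dianion (−2 e), dimethyl-lysine keeps its +1 e.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .structures import LHModel

__all__ = [
    "VariantSpec",
    "PtmParams",
    "PtmParameterTable",
    "DEFAULT_PTM_TABLE",
    "parse_variant",
    "apply_mutation",
    "apply_ptm",
    "apply_variant",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Coarse per-residue side-chain parameters: (formal charge e, bead radius Å,
#: representative polar-atom name used for H-bond donor/acceptor typing).
RESIDUE_PARAMS: dict[str, tuple[int, float, str]] = {
    "ALA": (0, 2.9, "CB"), "ARG": (1, 3.3, "NH1"), "ASN": (0, 3.0, "ND2"),
    "ASP": (-1, 3.0, "OD1"), "CYS": (0, 2.9, "SG"), "GLN": (0, 3.1, "NE2"),
    "GLU": (-1, 3.1, "OE1"), "GLY": (0, 2.7, "CA"), "HIS": (0, 3.1, "ND1"),
    "ILE": (0, 3.1, "CB"), "LEU": (0, 3.1, "CB"), "LYS": (1, 3.2, "NZ"),
    "MET": (0, 3.1, "CB"), "PHE": (0, 3.2, "CB"), "PRO": (0, 3.0, "CB"),
    "SER": (0, 2.8, "OG"), "THR": (0, 2.9, "OG1"), "TRP": (0, 3.4, "NE1"),
    "TYR": (0, 3.3, "OH"), "VAL": (0, 3.0, "CB"),
}

_BACKBONE_NAMES = ("N", "CA", "C", "O", "H", "HA", "OXT")


@dataclass(frozen=True)
class VariantSpec:
    """One mutation (``V80K``) or PTM (``S67ph``, ``K72me2``)."""

    kind: str  # "mutation" | "ptm"
    residue_index: int
    from_residue: str  # 3-letter code expected at the site
    to_residue: str | None = None  # 3-letter code (mutations)
    ptm_name: str | None = None  # "phosphoserine" | "dimethyl-lysine"
    label: str = ""

    def __str__(self) -> str:
        return self.label or f"{self.kind}@{self.residue_index}"


@dataclass(frozen=True)
class PtmParams:
    """Parameter deltas of one PTM at the modified site."""

    charge_delta: float  # e
    radius_delta: float  # Å
    target_residue: str  # residue type the PTM applies to
    modified_name: str  # residue name after modification
    added_site: str | None = None  # description of any added pseudo-site


PtmParameterTable = dict[str, PtmParams]

#: Implementation defaults standing in for literature charge sets: the
#: phosphoserine delta is the phosphate-dianion −2 e, dimethyl-lysine keeps
#: the lysine +1 e; radius deltas mimic the bulkier modified side chains.
#: User-overridable wherever a table argument is accepted.
DEFAULT_PTM_TABLE: PtmParameterTable = {
    "phosphoserine": PtmParams(-2.0, +0.5, "SER", "SEP"),
    "dimethyl-lysine": PtmParams(0.0, +0.4, "LYS", "MLY"),
}

_PTM_SUFFIXES = {"ph": "phosphoserine", "me2": "dimethyl-lysine"}

_VARIANT_RE = re.compile(r"^([A-Z])(\d+)([A-Z]|me2|ph)$")


def parse_variant(text: str) -> VariantSpec:
    """Parse ``"V80K"``, ``"K102V"``, ``"S67ph"`` or ``"K72me2"``."""
    m = _VARIANT_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse variant {text!r}")
    one, idx, tail = m.groups()
    if one not in _ONE_TO_THREE:
        raise ValueError(f"unknown residue letter {one!r} in {text!r}")
    if tail in _PTM_SUFFIXES:
        return VariantSpec(
            kind="ptm",
            residue_index=int(idx),
            from_residue=_ONE_TO_THREE[one],
            ptm_name=_PTM_SUFFIXES[tail],
            label=text.strip(),
        )
    if tail not in _ONE_TO_THREE:
        raise ValueError(f"unknown target residue {tail!r} in {text!r}")
    return VariantSpec(
        kind="mutation",
        residue_index=int(idx),
        from_residue=_ONE_TO_THREE[one],
        to_residue=_ONE_TO_THREE[tail],
        label=text.strip(),
    )


def _site_atoms(model: LHModel, spec: VariantSpec) -> np.ndarray:
    mask = model.residue_mask(spec.residue_index)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise ValueError(f"{spec}: no residue {spec.residue_index} in the model")
    found = str(model.solute.residue_names[idx[0]])
    if found != spec.from_residue:
        raise ValueError(
            f"{spec}: residue {spec.residue_index} is {found}, "
            f"expected {spec.from_residue}"
        )
    return idx


def apply_mutation(model: LHModel, spec: VariantSpec) -> LHModel:
    """Return a copy of the model with one side chain re-parameterized.

    The net formal charge changes by the formal-charge difference of the
    residue pair; element annotation is untouched.  Multi-atom residues
    keep their backbone and collapse the side chain to a single pseudo-site
    at the old side-chain centroid carrying the target parameters.
    """
    if spec.kind != "mutation":
        raise ValueError(f"{spec} is not a mutation")
    if spec.to_residue not in RESIDUE_PARAMS:
        raise ValueError(f"{spec}: unsupported target residue {spec.to_residue}")
    idx = _site_atoms(model, spec)
    from_q = RESIDUE_PARAMS.get(spec.from_residue, (0, 3.0, "CB"))[0]
    to_q, to_r, to_name = RESIDUE_PARAMS[spec.to_residue]
    out = model.copy()
    sol = out.solute
    if len(idx) == 1:
        i = idx[0]
        sol.residue_names[i] = spec.to_residue
        sol.atom_names[i] = to_name
        sol.charges[i] = sol.charges[i] + (to_q - from_q)
        sol.radii[i] = to_r
        return out
    # atomistic path: keep backbone, collapse the side chain
    names = sol.atom_names[idx]
    side = idx[~np.isin(names, _BACKBONE_NAMES)]
    back = idx[np.isin(names, _BACKBONE_NAMES)]
    if len(side) == 0:
        side = idx[-1:]
        back = idx[:-1]
    centroid = sol.reference_positions[side].mean(axis=0)
    side_q = float(sol.charges[side].sum())
    keep = np.ones(len(sol.atom_ids), dtype=bool)
    keep[side] = False
    keep[side[0]] = True  # reuse the first side-chain slot as the pseudo-site
    j = side[0]
    sol.reference_positions[j] = centroid
    sol.charges[j] = side_q + (to_q - from_q)
    sol.radii[j] = to_r
    sol.atom_names[j] = to_name
    for name in ("atom_ids", "atom_names", "residue_names", "residue_indices",
                 "chain_ids", "reference_positions", "charges", "radii"):
        setattr(sol, name, getattr(sol, name)[keep])
    for i in np.nonzero(sol.residue_indices == spec.residue_index)[0]:
        sol.residue_names[i] = spec.to_residue
    return out


def apply_ptm(
    model: LHModel,
    spec: VariantSpec,
    table: PtmParameterTable | None = None,
) -> LHModel:
    """Return a copy of the model with one PTM's parameter deltas applied."""
    if spec.kind != "ptm":
        raise ValueError(f"{spec} is not a PTM")
    table = DEFAULT_PTM_TABLE if table is None else table
    if spec.ptm_name not in table:
        raise ValueError(f"{spec}: unknown PTM {spec.ptm_name!r}")
    params = table[spec.ptm_name]
    if spec.from_residue != params.target_residue:
        raise ValueError(
            f"{spec}: {spec.ptm_name} applies to {params.target_residue}, "
            f"not {spec.from_residue}"
        )
    idx = _site_atoms(model, spec)
    out = model.copy()
    sol = out.solute
    # the charge delta goes on the residue's polar site; radius grows there too
    names = sol.atom_names[idx]
    polar = RESIDUE_PARAMS[spec.from_residue][2]
    j = idx[np.nonzero(names == polar)[0][0]] if polar in names else idx[-1]
    sol.charges[j] = sol.charges[j] + params.charge_delta
    sol.radii[j] = sol.radii[j] + params.radius_delta
    for i in idx:
        sol.residue_names[i] = params.modified_name
    out.ptm_labels.append(spec.label or f"{spec.ptm_name}@{spec.residue_index}")
    return out


def apply_variant(
    model: LHModel,
    spec: VariantSpec | str,
    table: PtmParameterTable | None = None,
) -> LHModel:
    """Apply a mutation or PTM given a spec or a string like ``"K85V"``."""
    if isinstance(spec, str):
        spec = parse_variant(spec)
    if spec.kind == "mutation":
        return apply_mutation(model, spec)
    return apply_ptm(model, spec, table)
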