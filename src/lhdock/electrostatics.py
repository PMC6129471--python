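"""Screened electrostatics for rigid-body docking.

The built-in potential model is uniform-dielectric Debye–Hückel (DH)
superposition: each source atom *i* with charge :math:`q_i` (e) and radius
:math:`a_i` (Å) contributes

.. math::

    \\phi_i(r) = \\frac{C}{\\varepsilon_s}\\, q_i\\,
        \\frac{e^{-\\kappa(d - a_i)}}{(1 + \\kappa a_i)\\, d},

with :math:`d = |r - r_i|`, :math:`C = e^2/(4\\pi\\varepsilon_0 k_B T)` in
kT·Å/e² units and :math:`\\kappa` the inverse Debye length for a 1:1 salt.
Potentials are tabulated on regular grids (kT/e), interaction energies and
forces are evaluated by trilinear interpolation at effective-charge sites,
and higher-fidelity grids computed externally (e.g. by a Poisson–Boltzmann
solver) can be imported in OpenDX format through the identical interface.
Sites outside a grid fall back to the analytic DH monopole tail of the
source solute.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import Avogadro, Boltzmann, elementary_charge, epsilon_0
from scipy.spatial import cKDTree
from scipy.stats import qmc

from .geometry import RigidTransform
from .structures import NucleosomeModel, Solute

__all__ = [
    "PotentialGrid",
    "EffectiveChargeSet",
    "ExclusionGrid",
    "coulomb_constant_kT",
    "inverse_debye_length",
    "debye_huckel_grid",
    "debye_huckel_potential",
    "read_dx_grid",
    "write_dx_grid",
    "charged_group_sites",
    "fit_effective_charges",
    "interaction_energy",
    "symmetrized_interaction_energy",
    "force_and_torque",
    "build_exclusion_grid",
    "check_overlap",
]

logger = logging.getLogger(__name__)

DEFAULT_TEMPERATURE = 298.15  # K
DEFAULT_IONIC_STRENGTH = 0.100  # mol/L
DEFAULT_EPS_SOLVENT = 78.54
DEFAULT_EPS_SOLUTE = 2.0


def coulomb_constant_kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """e²/(4πε₀ k_B T) in kT·Å/e² units (≈ 560.5 at 298.15 K)."""
    return elementary_charge**2 / (
        4.0 * np.pi * epsilon_0 * Boltzmann * temperature * 1e-10
    )


def inverse_debye_length(
    ionic_strength: float = DEFAULT_IONIC_STRENGTH,
    temperature: float = DEFAULT_TEMPERATURE,
    eps_solvent: float = DEFAULT_EPS_SOLVENT,
) -> float:
    """κ in Å⁻¹ for a 1:1 electrolyte (≈ 0.104 Å⁻¹ at 100 mM, 298.15 K)."""
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    n = 2.0 * ionic_strength * 1000.0 * Avogadro  # ions / m^3
    kappa_m = np.sqrt(
        n * elementary_charge**2 / (epsilon_0 * eps_solvent * Boltzmann * temperature)
    )
    return float(kappa_m * 1e-10)


@dataclass
class PotentialGrid:
    """Regular scalar grid of electrostatic potential, in kT/e."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    ionic_strength: float = DEFAULT_IONIC_STRENGTH
    eps_solvent: float = DEFAULT_EPS_SOLVENT
    eps_solute: float = DEFAULT_EPS_SOLUTE
    source_center: np.ndarray | None = None
    source_net_charge: float = 0.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.values.ndim != 3:
            raise ValueError("grid values must be a 3-d array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite values")
        if self.source_center is not None:
            self.source_center = np.asarray(self.source_center, dtype=float)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def kappa(self) -> float:
        return inverse_debye_length(self.ionic_strength, self.temperature, self.eps_solvent)

    def grid_points(self) -> np.ndarray:
        """All grid node coordinates, shape (nx*ny*nz, 3)."""
        axes = [self.origin[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points strictly inside the interpolation box."""
        frac = (np.atleast_2d(points) - self.origin) / self.spacing
        hi = np.array(self.dims) - 1
        return np.all((frac >= 0.0) & (frac <= hi - 1e-9), axis=1)


@dataclass
class EffectiveChargeSet:
    """Fitted point charges reproducing a solute's exterior potential."""

    positions: np.ndarray  # (n, 3), solute reference frame, Å
    charges: np.ndarray  # e
    radii: np.ndarray  # Å, used in the DH kernel
    fit_residual: float = 0.0  # relative RMS over the fitting shell

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.fit_residual < 0:
            raise ValueError("fit residual must be >= 0")

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def __len__(self) -> int:
        return len(self.charges)


# ---------------------------------------------------------------------------
# DH superposition


_clamp_logged = False


def debye_huckel_potential(
    points: np.ndarray,
    positions: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    ionic_strength: float = DEFAULT_IONIC_STRENGTH,
    eps_solvent: float = DEFAULT_EPS_SOLVENT,
    chunk: int = 64,
) -> np.ndarray:
    """Screened-Coulomb superposition potential at ``points``, in kT/e.

    Distances below an atom's radius (or a tenth of an Å for zero-radius
    sites) are clamped there; that only happens for evaluation points
    landing essentially on a source site.
    """
    global _clamp_logged
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    q = np.asarray(charges, dtype=float)
    a = np.zeros(len(q)) if radii is None else np.asarray(radii, dtype=float)
    kappa = inverse_debye_length(ionic_strength, temperature, eps_solvent)
    pref = coulomb_constant_kT(temperature) / eps_solvent
    out = np.zeros(len(pts))
    floor = np.maximum(a, 0.1)
    for lo in range(0, len(q), chunk):
        hi = min(lo + chunk, len(q))
        d = np.linalg.norm(pts[:, None, :] - pos[None, lo:hi, :], axis=2)
        clamped = d < floor[None, lo:hi]
        if np.any(clamped) and not _clamp_logged:
            logger.warning("evaluation point inside a source atom; distance clamped")
            _clamp_logged = True
        d = np.maximum(d, floor[None, lo:hi])
        ai = a[None, lo:hi]
        out += np.sum(
            q[None, lo:hi] * np.exp(-kappa * (d - ai)) / ((1.0 + kappa * ai) * d),
            axis=1,
        )
    return pref * out


def debye_huckel_grid(
    solute: Solute,
    spacing: float = 1.0,
    padding: float | None = None,
    origin: np.ndarray | None = None,
    dims: tuple[int, int, int] | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    ionic_strength: float = DEFAULT_IONIC_STRENGTH,
    eps_solvent: float = DEFAULT_EPS_SOLVENT,
    eps_solute: float = DEFAULT_EPS_SOLUTE,
) -> PotentialGrid:
    """Tabulate the solute's DH potential on a regular grid.

    By default the box extends three Debye lengths beyond the solute's
    bounding box; pass ``origin`` and ``dims`` for an explicit box.
    """
    pos = solute.positions
    kappa = inverse_debye_length(ionic_strength, temperature, eps_solvent)
    if origin is None or dims is None:
        if padding is None:
            padding = 3.0 / max(kappa, 1e-6) if kappa > 0 else 30.0
        lo = pos.min(axis=0) - padding
        hi = pos.max(axis=0) + padding
        dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
        origin = lo
    origin = np.asarray(origin, dtype=float)
    npts = int(np.prod(dims))
    values = np.empty(npts)
    axes = [origin[k] + spacing * np.arange(dims[k]) for k in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    block = 200_000
    for lo_i in range(0, npts, block):
        hi_i = min(lo_i + block, npts)
        values[lo_i:hi_i] = debye_huckel_potential(
            pts[lo_i:hi_i], pos, solute.charges, solute.radii,
            temperature, ionic_strength, eps_solvent,
        )
    return PotentialGrid(
        origin=origin,
        spacing=spacing,
        values=values.reshape(dims),
        temperature=temperature,
        ionic_strength=ionic_strength,
        eps_solvent=eps_solvent,
        eps_solute=eps_solute,
        source_center=solute.geometric_center,
        source_net_charge=solute.total_charge,
    )


# ---------------------------------------------------------------------------
# OpenDX import/export (APBS-compatible, via GridDataFormats)


def read_dx_grid(path, **metadata) -> PotentialGrid:
    """Read an OpenDX scalar grid (APBS dialect included).

    Keyword arguments override physical metadata (temperature, ionic
    strength, dielectrics, source center/net charge) that DX files do not
    carry.
    """
    from gridData import Grid

    g = Grid(str(path))
    delta = np.asarray(g.delta)
    if delta.ndim == 2:
        delta = np.diag(delta)
    if not np.allclose(delta, delta[0]):
        raise ValueError(f"{path}: anisotropic grid spacing {delta} is not supported")
    return PotentialGrid(
        origin=np.asarray(g.origin, dtype=float),
        spacing=float(delta[0]),
        values=np.asarray(g.grid, dtype=float),
        **metadata,
    )


def write_dx_grid(grid: PotentialGrid, path) -> None:
    from gridData import Grid

    g = Grid(grid.values, origin=grid.origin, delta=[grid.spacing] * 3)
    g.export(str(path), file_format="dx")


# ---------------------------------------------------------------------------
# Effective charges

_SIDECHAIN_CHARGE_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "CZ"),
    "SEP": ("OG", "P"),
    "MLY": ("NZ",),
}
_CHARGED_RESIDUES = tuple(_SIDECHAIN_CHARGE_ATOMS)


def charged_group_sites(solute: Solute) -> tuple[np.ndarray, np.ndarray]:
    """Default effective-charge site positions and radii (reference frame).

    DNA contributes its P atoms; proteins contribute one site per charged
    residue at the charged-group centroid.  Single-bead residues fall back
    to the bead itself.
    """
    pos = solute.reference_positions
    sites: list[np.ndarray] = []
    radii: list[float] = []
    p_mask = solute.atom_names == "P"
    for i in np.nonzero(p_mask)[0]:
        sites.append(pos[i])
        radii.append(float(solute.radii[i]))
    for rid in np.unique(solute.residue_indices):
        rmask = (solute.residue_indices == rid) & ~p_mask
        if not np.any(rmask):
            continue
        rname = str(solute.residue_names[np.nonzero(rmask)[0][0]])
        if rname not in _CHARGED_RESIDUES:
            continue
        wanted = _SIDECHAIN_CHARGE_ATOMS[rname]
        sel = rmask & np.isin(solute.atom_names, wanted)
        if not np.any(sel):
            sel = rmask  # coarse single-bead residue
        sites.append(pos[sel].mean(axis=0))
        radii.append(float(solute.radii[sel].mean()))
    if not sites:
        raise ValueError("no chargeable sites found (no P atoms or charged residues)")
    return np.array(sites), np.array(radii)


def fit_effective_charges(
    solute: Solute,
    grid: PotentialGrid,
    shell: tuple[float, float] = (3.0, 6.0),
    n_points: int = 2000,
    sites: np.ndarray | None = None,
    site_radii: np.ndarray | None = None,
    seed: int = 2017,
) -> EffectiveChargeSet:
    """Fit point charges at chemically meaningful sites to a potential grid.

    Charges minimize the RMS difference between the site-generated DH
    potential and the grid over quasi-random sample points in a shell
    ``shell[0]``–``shell[1]`` Å outside the solute surface.  The relative
    RMS residual is reported on the result.
    """
    if sites is None:
        sites, site_radii = charged_group_sites(solute)
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    if len(sites) == 0:
        raise ValueError("empty effective-charge site list")
    if site_radii is None:
        site_radii = np.zeros(len(sites))
    site_radii = np.asarray(site_radii, dtype=float)
    inner, outer = shell
    if not (0 <= inner < outer):
        raise ValueError(f"invalid shell {shell}")

    # the grid tabulates the potential of the solute's *current* coordinates;
    # fit there, store the sites in the reference frame
    sites_world = solute.frame.apply(sites)
    ref = solute.positions
    tree = cKDTree(ref)
    rmax = float(solute.radii.max())
    lo = ref.min(axis=0) - (outer + rmax)
    hi = ref.max(axis=0) + (outer + rmax)
    sampler = qmc.Halton(d=3, scramble=True, seed=seed)
    pts: list[np.ndarray] = []
    attempts = 0
    while sum(len(p) for p in pts) < n_points and attempts < 200:
        cand = qmc.scale(sampler.random(4 * n_points), lo, hi)
        # snap to grid nodes: the tabulated potential is exact there, so the
        # fit is not polluted by interpolation error
        cand = grid.origin + grid.spacing * np.rint((cand - grid.origin) / grid.spacing)
        d, idx = tree.query(cand)
        surf = d - solute.radii[idx]
        keep = (surf >= inner) & (surf <= outer)
        if np.any(keep):
            cand = cand[keep]
            cand = cand[grid.contains(cand)]
            if len(cand):
                pts.append(cand)
        attempts += 1
    if not pts:
        raise ValueError("fitting shell contains no sample points inside the grid")
    points = np.unique(np.concatenate(pts), axis=0)[:n_points]

    kappa = grid.kappa
    pref = coulomb_constant_kT(grid.temperature) / grid.eps_solvent
    d = np.linalg.norm(points[:, None, :] - sites_world[None, :, :], axis=2)
    d = np.maximum(d, 1e-6)
    A = pref * np.exp(-kappa * (d - site_radii)) / ((1.0 + kappa * site_radii) * d)
    phi = trilinear_interpolate(grid, points)
    q, residuals, rank, _ = np.linalg.lstsq(A, phi, rcond=None)
    if rank < len(sites):
        warnings.warn("singular normal equations in effective-charge fit; regularizing")
        lam = 1e-8 * np.trace(A.T @ A) / len(sites)
        q = np.linalg.solve(A.T @ A + lam * np.eye(len(sites)), A.T @ phi)
    scale = float(np.sqrt(np.mean(phi**2)))
    res = float(np.sqrt(np.mean((A @ q - phi) ** 2)) / max(scale, 1e-30))
    return EffectiveChargeSet(sites, q, site_radii, res)


# ---------------------------------------------------------------------------
# Trilinear evaluation, energies, forces


def trilinear_interpolate(grid: PotentialGrid, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of grid values at points (must be inside)."""
    vals, _ = _trilinear(grid, points, gradient=False)
    return vals


def _trilinear(grid: PotentialGrid, points: np.ndarray, gradient: bool):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    h = grid.spacing
    frac = (pts - grid.origin) / h
    dims = np.array(grid.dims)
    if np.any(frac < -1e-9) or np.any(frac > dims - 1 + 1e-9):
        raise ValueError("point outside the interpolation box")
    i0 = np.clip(np.floor(frac).astype(int), 0, dims - 2)
    f = frac - i0
    V = grid.values
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    c000 = V[ix, iy, iz]
    c100 = V[ix + 1, iy, iz]
    c010 = V[ix, iy + 1, iz]
    c110 = V[ix + 1, iy + 1, iz]
    c001 = V[ix, iy, iz + 1]
    c101 = V[ix + 1, iy, iz + 1]
    c011 = V[ix, iy + 1, iz + 1]
    c111 = V[ix + 1, iy + 1, iz + 1]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    vals = c0 * (1 - fz) + c1 * fz
    if not gradient:
        return vals, None
    dx = ((c100 - c000) * (1 - fy) + (c110 - c010) * fy) * (1 - fz) + (
        (c101 - c001) * (1 - fy) + (c111 - c011) * fy
    ) * fz
    dy = (c10 - c00) * (1 - fz) + (c11 - c01) * fz
    dz = c1 - c0
    grad = np.stack([dx, dy, dz], axis=1) / h
    return vals, grad


def _tail_potential(grid: PotentialGrid, points: np.ndarray, gradient: bool):
    """Analytic DH monopole tail of the grid's source solute."""
    if grid.source_center is None:
        z = np.zeros(len(points))
        return (z, np.zeros((len(points), 3))) if gradient else (z, None)
    kappa = grid.kappa
    pref = coulomb_constant_kT(grid.temperature) / grid.eps_solvent
    rvec = points - grid.source_center
    r = np.maximum(np.linalg.norm(rvec, axis=1), 1e-6)
    phi = pref * grid.source_net_charge * np.exp(-kappa * r) / r
    if not gradient:
        return phi, None
    dphi_dr = -phi * (kappa + 1.0 / r)
    grad = dphi_dr[:, None] * rvec / r[:, None]
    return phi, grad


def _potential_at(grid: PotentialGrid, points: np.ndarray, gradient: bool):
    pts = np.atleast_2d(points)
    inside = grid.contains(pts)
    phi = np.empty(len(pts))
    grad = np.zeros((len(pts), 3)) if gradient else None
    if np.any(inside):
        v, g = _trilinear(grid, pts[inside], gradient)
        phi[inside] = v
        if gradient:
            grad[inside] = g
    if np.any(~inside):
        v, g = _tail_potential(grid, pts[~inside], gradient)
        phi[~inside] = v
        if gradient:
            grad[~inside] = g
    return phi, grad


def interaction_energy(
    grid_A: PotentialGrid,
    charges_B: EffectiveChargeSet,
    pose: RigidTransform,
) -> float:
    """One-sided interaction energy: B's charges in A's potential, kT."""
    world = pose.apply(charges_B.positions)
    phi, _ = _potential_at(grid_A, world, gradient=False)
    return float(np.dot(charges_B.charges, phi))


def symmetrized_interaction_energy(
    grid_A: PotentialGrid,
    charges_A: EffectiveChargeSet,
    grid_B: PotentialGrid,
    charges_B: EffectiveChargeSet,
    pose: RigidTransform,
) -> float:
    """Average of the two one-sided energies (A fixed, B posed by ``pose``)."""
    e_ab = interaction_energy(grid_A, charges_B, pose)
    inv = pose.inverse()
    e_ba = interaction_energy(grid_B, charges_A, inv)
    return 0.5 * (e_ab + e_ba)


def force_and_torque(
    grid_A: PotentialGrid,
    charges_B: EffectiveChargeSet,
    pose: RigidTransform,
    center: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Force (kT/Å) and torque (kT) on B, from the gradient of the trilinear
    interpolant of A's grid.  Torque is taken about B's geometric center
    (the posed centroid of the charge sites unless ``center`` is given)."""
    world = pose.apply(charges_B.positions)
    if center is None:
        center = world.mean(axis=0)
    phi, grad = _potential_at(grid_A, world, gradient=True)
    f = -charges_B.charges[:, None] * grad
    force = f.sum(axis=0)
    torque = np.cross(world - center, f).sum(axis=0)
    return force, torque


# ---------------------------------------------------------------------------
# Excluded volume


@dataclass
class ExclusionGrid:
    """Boolean occupancy grid implementing the excluded-volume criterion.

    A probe-atom *center* is overlapping when it falls in a cell marked
    occupied; cells are marked within (atom radius + probe margin + half a
    cell diagonal) of any nucleosome atom center, so the test has no false
    negatives and false positives of at most one cell diagonal.
    """

    origin: np.ndarray
    spacing: float
    occupancy: np.ndarray
    probe_margin: float = 0.5

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=bool)


def build_exclusion_grid(
    nuc: NucleosomeModel | Solute,
    margin: float = 0.5,
    spacing: float = 0.5,
) -> ExclusionGrid:
    solute = nuc.solute if isinstance(nuc, NucleosomeModel) else nuc
    pos = solute.positions
    radii = solute.radii
    half_diag = 0.5 * spacing * np.sqrt(3.0)
    reach = radii + margin + half_diag
    lo = (pos - reach[:, None]).min(axis=0) - spacing
    hi = (pos + reach[:, None]).max(axis=0) + spacing
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    occ = np.zeros(tuple(dims), dtype=bool)
    for p, r in zip(pos, reach):
        i0 = np.floor((p - r - lo) / spacing).astype(int)
        i1 = np.ceil((p + r - lo) / spacing).astype(int) + 1
        i0 = np.maximum(i0, 0)
        i1 = np.minimum(i1, dims)
        ax = [lo[k] + spacing * np.arange(i0[k], i1[k]) for k in range(3)]
        dx2 = (ax[0] - p[0]) ** 2
        dy2 = (ax[1] - p[1]) ** 2
        dz2 = (ax[2] - p[2]) ** 2
        ball = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        ) <= r * r
        occ[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= ball
    return ExclusionGrid(lo, spacing, occ, probe_margin=margin)


def check_overlap(excl: ExclusionGrid, probe, pose: RigidTransform | None = None) -> bool:
    """True if any probe atom center falls in an occupied cell.

    ``probe`` may be an LHModel, a Solute, or an (n, 3) coordinate array
    (reference coordinates; ``pose`` is applied if given).
    """
    if hasattr(probe, "solute"):
        coords = probe.solute.reference_positions
    elif isinstance(probe, Solute):
        coords = probe.reference_positions
    else:
        coords = np.atleast_2d(np.asarray(probe, dtype=float))
    if pose is not None:
        coords = pose.apply(coords)
    idx = np.rint((coords - excl.origin) / excl.spacing).astype(int)
    dims = np.array(excl.occupancy.shape)
    inside = np.all((idx >= 0) & (idx < dims), axis=1)
    if not np.any(inside):
        return False
    ii = idx[inside]
    return bool(np.any(excl.occupancy[ii[:, 0], ii[:, 1], ii[:, 2]]))
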