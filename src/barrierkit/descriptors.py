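"""Interpretable physical-organic descriptors computed from 3D structures.

Electronic descriptors (PEOE partial charges, electrotopological-state
indices) are graph-derived; steric descriptors (Sterimol L/B1/B5, percent
buried volume, solvent-accessible surface area) are geometric and use the
Bondi vdW radii from the constants table.  All are deterministic — the SASA
point set is a golden spiral and buried volume uses a fixed grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import constants as C
from .qm_io import Structure

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Connectivity:
    """Undirected bond list with optional bond orders (default single)."""

    n_atoms: int
    pairs: tuple[tuple[int, int], ...]
    orders: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.orders and len(self.orders) != len(self.pairs):
            raise ValueError("orders length must match pairs")
        for i, j in self.pairs:
            if i == j:
                raise ValueError("self-bond")
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError("bond index out of range")

    def order(self, k: int) -> float:
        return self.orders[k] if self.orders else 1.0

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for i, j in self.pairs:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def pi_counts(self) -> list[float]:
        """Per-atom sum of (order - 1) over incident bonds."""
        pi = [0.0] * self.n_atoms
        for k, (i, j) in enumerate(self.pairs):
            extra = self.order(k) - 1.0
            pi[i] += extra
            pi[j] += extra
        return pi


def perceive_bonds(structure: Structure, tolerance: float = 1.2) -> Connectivity:
    """Distance-based bonds: d < tolerance x (covalent radius sum)."""
    pos = structure.positions()
    pairs = []
    for i in range(structure.n_atoms):
        for j in range(i + 1, structure.n_atoms):
            rsum = (
                C.COVALENT_RADII[structure.symbols[i]]
                + C.COVALENT_RADII[structure.symbols[j]]
            )
            if np.linalg.norm(pos[i] - pos[j]) < tolerance * rsum:
                pairs.append((i, j))
    return Connectivity(n_atoms=structure.n_atoms, pairs=tuple(pairs))


# ---------------------------------------------------------------------------
# PEOE (Gasteiger-Marsili) charges
# ---------------------------------------------------------------------------


def _peoe_atom_type(symbol: str, pi: float) -> str:
    if symbol in ("H", "F", "Cl", "Br", "I", "S"):
        return symbol
    if symbol == "C":
        if pi >= 2:
            return "C_sp"
        return "C_sp2" if pi >= 1 else "C_sp3"
    if symbol == "N":
        if pi >= 2:
            return "N_sp"
        return "N_sp2" if pi >= 1 else "N_sp3"
    if symbol == "O":
        return "O_sp2" if pi >= 1 else "O_sp3"
    raise ValueError(f"no PEOE parameters for element {symbol!r}")


def peoe_charges(
    structure: Structure,
    bonds: Connectivity | None = None,
    n_iterations: int = 8,
    formal_charges: list[float] | None = None,
) -> np.ndarray:
    """Partial-equalisation-of-orbital-electronegativity charges.

    Iteratively transfers charge along each bond proportional to the
    electronegativity difference, damped by (1/2)^k at iteration k; the
    net molecular charge is conserved exactly.
    """
    if bonds is None:
        bonds = perceive_bonds(structure)
    pi = bonds.pi_counts()
    types = [
        _peoe_atom_type(sym, pi[i]) for i, sym in enumerate(structure.symbols)
    ]
    params = np.array([C.PEOE_PARAMS[t] for t in types])  # (n, 3): a, b, c
    # chi+ normalisation: chi at q=+1 (a+b+c), except hydrogen's fixed value
    chi_plus = params.sum(axis=1)
    chi_plus[[s == "H" for s in structure.symbols]] = C.PEOE_H_CATION_CHI

    q = np.zeros(structure.n_atoms)
    if formal_charges is not None:
        q[:] = formal_charges
    elif structure.net_charge != 0:
        q[:] = structure.net_charge / structure.n_atoms

    for k in range(1, n_iterations + 1):
        chi = params[:, 0] + params[:, 1] * q + params[:, 2] * q * q
        damp = 0.5**k
        dq = np.zeros_like(q)
        for i, j in bonds.pairs:
            if chi[i] < chi[j]:
                transfer = (chi[j] - chi[i]) / chi_plus[i] * damp
                dq[i] += transfer
                dq[j] -= transfer
            elif chi[j] < chi[i]:
                transfer = (chi[i] - chi[j]) / chi_plus[j] * damp
                dq[j] += transfer
                dq[i] -= transfer
        q += dq
    return q


# ---------------------------------------------------------------------------
# EState (Kier-Hall electrotopological) indices
# ---------------------------------------------------------------------------


def _heavy_graph(structure: Structure, bonds: Connectivity):
    heavy = [i for i, s in enumerate(structure.symbols) if s != "H"]
    pos_of = {a: k for k, a in enumerate(heavy)}
    adj: dict[int, set[int]] = {k: set() for k in range(len(heavy))}
    h_count = {k: 0 for k in range(len(heavy))}
    for i, j in bonds.pairs:
        si, sj = structure.symbols[i], structure.symbols[j]
        if si != "H" and sj != "H":
            adj[pos_of[i]].add(pos_of[j])
            adj[pos_of[j]].add(pos_of[i])
        elif si != "H" and sj == "H":
            h_count[pos_of[i]] += 1
        elif si == "H" and sj != "H":
            h_count[pos_of[j]] += 1
    return heavy, adj, h_count


def _bfs_distances(adj: dict[int, set[int]], start: int) -> dict[int, int]:
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for node in frontier:
            for nb in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    nxt.append(nb)
        frontier = nxt
    return dist


def estate_indices(
    structure: Structure, bonds: Connectivity | None = None
) -> dict[int, float]:
    """Electrotopological-state index per heavy atom (keyed by atom index).

    Intrinsic state I = ((2/n)^2 dv + 1)/d with n the valence principal
    quantum number, dv the valence delta and d the heavy-atom degree,
    perturbed by sum_j (I_i - I_j)/(d_ij)^2 with d_ij = bonds + 1.
    """
    if bonds is None:
        bonds = perceive_bonds(structure)
    heavy, adj, h_count = _heavy_graph(structure, bonds)
    intrinsic = []
    for k, atom in enumerate(heavy):
        sym = structure.symbols[atom]
        n_q = C.PRINCIPAL_QUANTUM_NUMBER[sym]
        z = C.ATOMIC_NUMBER[sym]
        zv = C.VALENCE_ELECTRONS[sym]
        dv_num = zv - h_count[k]
        dv = dv_num if n_q == 2 else dv_num / (z - zv - 1)
        delta = len(adj[k])
        if delta == 0:
            logger.info(
                "isolated heavy atom %d (%s): using free-atom intrinsic state",
                atom,
                sym,
            )
            delta = 1
        intrinsic.append(((2.0 / n_q) ** 2 * dv + 1.0) / delta)
    out: dict[int, float] = {}
    for k, atom in enumerate(heavy):
        dist = _bfs_distances(adj, k)
        perturbation = sum(
            (intrinsic[k] - intrinsic[m]) / (d + 1) ** 2
            for m, d in dist.items()
            if m != k
        )
        out[atom] = intrinsic[k] + perturbation
    return out


# ---------------------------------------------------------------------------
# Sterimol
# ---------------------------------------------------------------------------


def _substituent_atoms(
    bonds: Connectivity, attach_atom: int, sub_atom: int
) -> list[int]:
    adj = bonds.adjacency()
    seen = {attach_atom, sub_atom}
    stack = [sub_atom]
    members = [sub_atom]
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if nb not in seen:
                seen.add(nb)
                members.append(nb)
                stack.append(nb)
    return members


def sterimol(
    structure: Structure,
    attach_atom: int,
    sub_atom: int,
    bonds: Connectivity | None = None,
    radii: dict[str, float] | None = None,
) -> tuple[float, float, float]:
    """Sterimol (L, B1, B5) of the substituent rooted at ``sub_atom``.

    L: furthest extent of substituent vdW spheres along the attach->sub
    axis, measured from the attachment atom.  B5: largest perpendicular
    extent.  B1: smallest perpendicular half-width over rotations about
    the axis (minimum of the 2D support function).
    """
    radii = radii or C.VDW_RADII
    if bonds is None:
        bonds = perceive_bonds(structure)
    pos = structure.positions()
    axis = pos[sub_atom] - pos[attach_atom]
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        raise ValueError("attachment and substituent atoms coincide")
    axis = axis / norm
    members = _substituent_atoms(bonds, attach_atom, sub_atom)
    if not members:
        raise ValueError("empty substituent")
    rel = pos[members] - pos[attach_atom]
    r = np.array([radii[structure.symbols[i]] for i in members])
    proj = rel @ axis
    l_val = float((proj + r).max())
    perp = rel - np.outer(proj, axis)
    # orthonormal frame in the perpendicular plane
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    u = perp @ e1
    v = perp @ e2
    dist_perp = np.sqrt(u**2 + v**2)
    b5 = float((dist_perp + r).max())

    def width(theta: float) -> float:
        return float(np.max(u * math.cos(theta) + v * math.sin(theta) + r))

    thetas = np.linspace(0.0, 2.0 * math.pi, 721, endpoint=False)
    widths = np.array([width(t) for t in thetas])
    k = int(widths.argmin())
    span = thetas[1] - thetas[0]
    res = minimize_scalar(
        width,
        bounds=(thetas[k] - span, thetas[k] + span),
        method="bounded",
        options={"xatol": 1e-8},
    )
    b1 = float(min(res.fun, widths[k]))
    return l_val, b1, b5


# ---------------------------------------------------------------------------
# percent buried volume
# ---------------------------------------------------------------------------


def percent_buried_volume(
    structure: Structure,
    center_atom: int,
    sphere_radius: float = 3.5,
    radii_scale: float = 1.17,
    grid_spacing: float = 0.05,
    radii: dict[str, float] | None = None,
) -> float:
    """Percentage of a probe sphere occupied by scaled atomic vdW spheres.

    Deterministic cubic-grid integration: grid points inside the probe
    sphere are tested against every (scaled) atomic sphere.
    """
    if sphere_radius <= 0:
        raise ValueError("sphere_radius must be positive")
    radii = radii or C.VDW_RADII
    pos = structure.positions()
    center = pos[center_atom]
    n_side = int(math.floor(sphere_radius / grid_spacing))
    axis = np.arange(-n_side, n_side + 1) * grid_spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    pts = pts[(pts**2).sum(axis=1) <= sphere_radius**2]
    occupied = np.zeros(len(pts), dtype=bool)
    for i in range(structure.n_atoms):
        r_at = radii[structure.symbols[i]] * radii_scale
        rel = pos[i] - center
        if np.linalg.norm(rel) > sphere_radius + r_at:
            continue
        # cheap bounding-box prefilter before the exact sphere test
        box = (
            (np.abs(pts[:, 0] - rel[0]) <= r_at)
            & (np.abs(pts[:, 1] - rel[1]) <= r_at)
            & (np.abs(pts[:, 2] - rel[2]) <= r_at)
        )
        cand = np.flatnonzero(box & ~occupied)
        if cand.size:
            inside = ((pts[cand] - rel) ** 2).sum(axis=1) <= r_at**2
            occupied[cand[inside]] = True
    return float(occupied.mean() * 100.0)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(1.0 - z**2)
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Returns (per-atom areas, total) in square Angstrom.
    """
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    if n_points < 10:
        raise ValueError("need at least 10 sphere points")
    radii = radii or C.VDW_RADII
    pos = structure.positions()
    rads = np.array([radii[s] for s in structure.symbols]) + probe
    sphere = golden_spiral_points(n_points)
    areas = np.zeros(structure.n_atoms)
    for i in range(structure.n_atoms):
        pts = pos[i] + rads[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(structure.n_atoms):
            if j == i:
                continue
            if np.linalg.norm(pos[i] - pos[j]) > rads[i] + rads[j]:
                continue
            accessible &= ((pts - pos[j]) ** 2).sum(axis=1) > rads[j] ** 2
        areas[i] = accessible.mean() * 4.0 * math.pi * rads[i] ** 2
    return areas, float(areas.sum())


# ---------------------------------------------------------------------------
# descriptor-set assembly
# ---------------------------------------------------------------------------


@dataclass
class DescriptorSet:
    """Named descriptor values for one species (used by featurize)."""

    values: dict[str, float] = field(default_factory=dict)
    level: str = ""


def compute_descriptor_set(
    structure: Structure,
    key_atom_map: dict[str, int],
    rgroup_attachments: dict[str, tuple[int, int]] | None = None,
    mulliken: tuple[float, ...] | None = None,
    dispersion: dict[int, float] | None = None,
    level: str = "",
    bonds: Connectivity | None = None,
    pbv_names: set[str] | None = None,
) -> DescriptorSet:
    """Compute the standard per-species descriptor block.

    ``key_atom_map`` maps descriptor-friendly names (e.g. ``beta_carbon``)
    to atom indices; ``rgroup_attachments`` maps R-group names to
    (attach_atom, substituent_atom) pairs for Sterimol.  ``dispersion``
    accepts externally computed per-atom dispersion values (no internal
    formula is provided) and is flagged experimental in the feature name.
    """
    if bonds is None:
        bonds = perceive_bonds(structure)
    if pbv_names is None:
        # buried volume is costly; default to the reacting carbons only
        pbv_names = {"beta_carbon", "nucleophile_carbon"}
    values: dict[str, float] = {}
    peoe = peoe_charges(structure, bonds)
    estate = estate_indices(structure, bonds)
    atom_sasa, total_sasa = sasa(structure)
    for name, idx in key_atom_map.items():
        values[f"peoe_{name}"] = float(peoe[idx])
        if idx in estate:
            values[f"estate_{name}"] = float(estate[idx])
        values[f"sasa_{name}"] = float(atom_sasa[idx])
        if name in pbv_names:
            values[f"pbv_{name}"] = percent_buried_volume(structure, idx)
        if mulliken is not None:
            values[f"mulliken_{name}"] = float(mulliken[idx])
        if dispersion is not None and idx in dispersion:
            values[f"dispersion_experimental_{name}"] = float(dispersion[idx])
    values["sasa_total"] = total_sasa
    if rgroup_attachments:
        for rg_name, (attach, sub) in rgroup_attachments.items():
            l_val, b1, b5 = sterimol(structure, attach, sub, bonds=bonds)
            values[f"sterimol_L_{rg_name}"] = l_val
            values[f"sterimol_B1_{rg_name}"] = b1
            values[f"sterimol_B5_{rg_name}"] = b5
    return DescriptorSet(values=values, level=level)
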