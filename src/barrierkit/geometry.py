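"""Geometry comparison between levels of theory.

Superposition RMSDs use the Kabsch algorithm (centroid removal, SVD of the
cross-covariance, reflection-corrected rotation).  Atom correspondence is by
index — structures compared here must share an atom ordering, which the
manifest/generator guarantees.  Stripped variants re-align on the retained
subset only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .constants import VDW_RADII
from .qm_io import ReactionRecord, Structure

STRIP_MODES = ("full", "no_nucleophile", "no_rgroups", "core_only", "ma_vs_ts")


@dataclass(frozen=True)
class RMSDReport:
    reaction_id: str
    rmsd_full: float
    rmsd_no_nucleophile: float
    rmsd_no_rgroups: float
    rmsd_core_only: float
    d_bond_a: float
    d_bond_b: float
    delta_d: float  # level B minus level A


@dataclass(frozen=True)
class Contact:
    atom_i: int
    atom_j: int
    distance: float
    vdw_sum: float
    ratio: float


@dataclass(frozen=True)
class ContactReport:
    contacts: tuple[Contact, ...]
    factor: float


def kabsch_rmsd(
    a: Structure,
    b: Structure,
    atom_subset: Sequence[int] | None = None,
) -> float:
    """Minimum RMSD between two structures over proper rigid motions."""
    idx = list(range(a.n_atoms)) if atom_subset is None else list(atom_subset)
    if len(idx) < 3:
        raise ValueError("need at least 3 atoms for a unique superposition")
    sym_a = [a.symbols[i] for i in idx]
    sym_b = [b.symbols[i] for i in idx]
    if sym_a != sym_b:
        raise ValueError("element sequences differ on the comparison subset")
    p = a.positions()[idx]
    q = b.positions()[idx]
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    # collinear subsets leave the rotation about the axis undetermined; the
    # RMSD itself is still well-defined
    if np.linalg.svd(p, compute_uv=False)[1] < 1e-10:
        warnings.warn("degenerate (collinear) atom subset in superposition")
    cov = p.T @ q
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = (rot @ p.T).T - q
    return float(np.sqrt((diff**2).sum() / len(idx)))


def _rgroup_members(structure: Structure, reaction: ReactionRecord) -> set[int]:
    """Atoms reachable from each R-group attachment without crossing the
    core or the nucleophile, attachment atoms included."""
    from .descriptors import perceive_bonds

    ka = reaction.key_atoms
    if ka is None:
        raise ValueError(f"reaction {reaction.reaction_id}: key atoms required")
    bonds = perceive_bonds(structure)
    adj: dict[int, set[int]] = {i: set() for i in range(structure.n_atoms)}
    for i, j in bonds.pairs:
        adj[i].add(j)
        adj[j].add(i)
    blocked = set(ka.core) | set(ka.nucleophile_atoms)
    members: set[int] = set()
    for start in ka.rgroup_attachments:
        stack = [start]
        while stack:
            cur = stack.pop()
            if cur in members or cur in blocked:
                continue
            members.add(cur)
            stack.extend(adj[cur] - members - blocked)
    return members


def _retained_indices(
    structure: Structure, reaction: ReactionRecord, mode: str
) -> list[int]:
    ka = reaction.key_atoms
    if ka is None:
        raise ValueError(f"reaction {reaction.reaction_id}: key atoms required")
    n = structure.n_atoms
    if mode == "full":
        return list(range(n))
    if mode == "no_nucleophile":
        drop = set(ka.nucleophile_atoms)
        return [i for i in range(n) if i not in drop]
    if mode == "no_rgroups":
        drop = _rgroup_members(structure, reaction)
        return [i for i in range(n) if i not in drop]
    if mode == "core_only":
        return [i for i in range(n) if i in set(ka.core)]
    raise ValueError(f"unknown strip mode {mode!r}")


def stripped_rmsd(
    a: Structure,
    b: Structure,
    reaction: ReactionRecord,
    mode: str = "full",
) -> float:
    """Kabsch RMSD on a retained atom subset defined by ``mode``.

    ``ma_vs_ts`` compares an MA structure (``a``) against a TS structure
    (``b``) with the TS's nucleophile atoms deleted; the MA must share the
    ordering of the TS's non-nucleophile atoms.
    """
    if mode == "ma_vs_ts":
        ka = reaction.key_atoms
        if ka is None:
            raise ValueError(f"reaction {reaction.reaction_id}: key atoms required")
        keep = [i for i in range(b.n_atoms) if i not in set(ka.nucleophile_atoms)]
        if len(keep) < 3:
            raise ValueError("retained subset smaller than 3 atoms")
        b_stripped = b.subset(keep)
        if a.n_atoms != b_stripped.n_atoms:
            raise ValueError(
                "MA structure does not match TS-minus-nucleophile atom count"
            )
        return kabsch_rmsd(a, b_stripped)
    keep = _retained_indices(a, reaction, mode)
    if len(keep) < 3:
        raise ValueError("retained subset smaller than 3 atoms")
    return kabsch_rmsd(a, b, atom_subset=keep)


def bond_forming_delta(
    reaction: ReactionRecord, level_a: str, level_b: str
) -> tuple[float, float, float]:
    """Forming C-C distances in both TSs and their signed difference B - A."""
    ka = reaction.key_atoms
    if ka is None:
        raise ValueError(f"reaction {reaction.reaction_id}: key atoms required")
    dists = []
    for level in (level_a, level_b):
        if not reaction.has(level, "TS"):
            raise ValueError(
                f"reaction {reaction.reaction_id}: missing TS at level {level}"
            )
        pos = reaction.get(level, "TS").structure.positions()
        d = float(np.linalg.norm(pos[ka.nucleophile_carbon] - pos[ka.beta_carbon]))
        dists.append(d)
    return dists[0], dists[1], dists[1] - dists[0]


def vdw_contacts(
    structure: Structure,
    elements_filter: Iterable[tuple[str, str]] = (("C", "C"),),
    factor: float = 0.9,
    bonds=None,
) -> ContactReport:
    """Non-bonded, non-geminal atom pairs closer than factor x vdW sum."""
    if not 0.0 < factor <= 1.0:
        raise ValueError("factor must lie in (0, 1]")
    from .descriptors import perceive_bonds

    if bonds is None:
        bonds = perceive_bonds(structure)
    bonded = {frozenset(p) for p in bonds.pairs}
    adj: dict[int, set[int]] = {i: set() for i in range(structure.n_atoms)}
    for i, j in bonds.pairs:
        adj[i].add(j)
        adj[j].add(i)
    allowed = {frozenset(p) for p in elements_filter}
    pos = structure.positions()
    contacts = []
    for i in range(structure.n_atoms):
        for j in range(i + 1, structure.n_atoms):
            pair = frozenset((structure.symbols[i], structure.symbols[j]))
            if allowed and pair not in allowed:
                continue
            if frozenset((i, j)) in bonded:
                continue
            if adj[i] & adj[j]:  # geminal: share a bonded neighbour
                continue
            vdw_sum = VDW_RADII[structure.symbols[i]] + VDW_RADII[structure.symbols[j]]
            dist = float(np.linalg.norm(pos[i] - pos[j]))
            if dist < factor * vdw_sum:
                contacts.append(
                    Contact(i, j, dist, vdw_sum, dist / vdw_sum)
                )
    return ContactReport(contacts=tuple(contacts), factor=factor)


def summarize_distributions(
    reports: Sequence[RMSDReport],
    rmsd_threshold: float = 2.0,
    delta_d_threshold: float = 0.3,
    n_bins: int = 20,
) -> dict:
    """Dataset-level means, below-threshold fractions, and histograms."""
    if not reports:
        raise ValueError("no reports to summarise")
    rmsds = np.array([r.rmsd_full for r in reports])
    deltas = np.array([r.delta_d for r in reports])
    rmsd_hist, rmsd_edges = np.histogram(rmsds, bins=n_bins)
    delta_hist, delta_edges = np.histogram(deltas, bins=n_bins)
    return {
        "n": len(reports),
        "mean_rmsd_full": float(rmsds.mean()),
        "mean_rmsd_no_nucleophile": float(
            np.mean([r.rmsd_no_nucleophile for r in reports])
        ),
        "mean_rmsd_no_rgroups": float(np.mean([r.rmsd_no_rgroups for r in reports])),
        "mean_rmsd_core_only": float(np.mean([r.rmsd_core_only for r in reports])),
        "mean_delta_d": float(deltas.mean()),
        "pct_rmsd_below": float((rmsds < rmsd_threshold).mean() * 100.0),
        "pct_abs_delta_d_below": float(
            (np.abs(deltas) < delta_d_threshold).mean() * 100.0
        ),
        "rmsd_threshold": rmsd_threshold,
        "delta_d_threshold": delta_d_threshold,
        "rmsd_histogram": {
            "counts": rmsd_hist.tolist(),
            "edges": rmsd_edges.tolist(),
        },
        "delta_d_histogram": {
            "counts": delta_hist.tolist(),
            "edges": delta_edges.tolist(),
        },
    }


def compare_reaction(
    reaction: ReactionRecord, level_a: str, level_b: str
) -> RMSDReport:
    """Full RMSD/bond-distance comparison of two TS levels for one reaction."""
    ts_a = reaction.get(level_a, "TS").structure
    ts_b = reaction.get(level_b, "TS").structure
    d_a, d_b, delta = bond_forming_delta(reaction, level_a, level_b)
    return RMSDReport(
        reaction_id=reaction.reaction_id,
        rmsd_full=stripped_rmsd(ts_a, ts_b, reaction, "full"),
        rmsd_no_nucleophile=stripped_rmsd(ts_a, ts_b, reaction, "no_nucleophile"),
        rmsd_no_rgroups=stripped_rmsd(ts_a, ts_b, reaction, "no_rgroups"),
        rmsd_core_only=stripped_rmsd(ts_a, ts_b, reaction, "core_only"),
        d_bond_a=d_a,
        d_bond_b=d_b,
        delta_d=delta,
    )
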