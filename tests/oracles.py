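"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately written against the underlying math (and
third-party references such as scipy.spatial.transform and networkx) rather
than against the package's own implementations, so each check is dual-route.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.constants as sc
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

# ---------------------------------------------------------------------------
# superposition RMSD via rotation-space search (no SVD/Kabsch)
# ---------------------------------------------------------------------------


def rmsd_rotation_search(p: np.ndarray, q: np.ndarray, n_grid: int = 2000, seed: int = 0) -> float:
    """Minimal RMSD over proper rotations by quaternion sampling + local
    refinement of the best starts."""
    p0 = p - p.mean(axis=0)
    q0 = q - q.mean(axis=0)

    def value(rotvec: np.ndarray) -> float:
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        d = p0 @ rot.T - q0
        return float(np.sqrt((d**2).sum() / len(p0)))

    grid = Rotation.random(n_grid, random_state=seed)
    scores = []
    for r in grid:
        d = p0 @ r.as_matrix().T - q0
        scores.append((d**2).sum())
    order = np.argsort(scores)
    best = np.inf
    for k in order[:5]:
        res = minimize(
            value,
            grid[int(k)].as_rotvec(),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000},
        )
        best = min(best, float(res.fun))
    return best


# ---------------------------------------------------------------------------
# Monte-Carlo buried volume
# ---------------------------------------------------------------------------


def buried_volume_mc(
    positions: np.ndarray,
    radii: np.ndarray,
    center: np.ndarray,
    sphere_radius: float,
    n_points: int = 10_000_000,
    seed: int = 0,
    chunk: int = 1_000_000,
) -> float:
    """Percent of the probe sphere covered by atom spheres, by uniform
    Monte-Carlo sampling inside the sphere."""
    rng = np.random.default_rng(seed)
    hit = 0
    done = 0
    rel = positions - center
    while done < n_points:
        m = min(chunk, n_points - done)
        u = rng.standard_normal((m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = sphere_radius * rng.random(m) ** (1.0 / 3.0)
        pts = u * r[:, None]
        inside = np.zeros(m, dtype=bool)
        for a in range(len(rel)):
            inside |= ((pts - rel[a]) ** 2).sum(axis=1) <= radii[a] ** 2
        hit += int(inside.sum())
        done += m
    return 100.0 * hit / n_points


# ---------------------------------------------------------------------------
# Sterimol by dense rotational scan
# ---------------------------------------------------------------------------


def sterimol_scan(
    positions: np.ndarray,
    radii: np.ndarray,
    attach: int,
    members: list[int],
    step_deg: float = 0.1,
) -> tuple[float, float, float]:
    """(L, B1, B5) with B1 from an exhaustive angular grid."""
    axis = positions[members[0]] - positions[attach]
    axis = axis / np.linalg.norm(axis)
    rel = positions[members] - positions[attach]
    r = radii[members]
    proj = rel @ axis
    l_val = float((proj + r).max())
    perp = rel - np.outer(proj, axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    u = perp @ e1
    v = perp @ e2
    b5 = float((np.sqrt(u**2 + v**2) + r).max())
    angles = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    widths = (
        u[None, :] * np.cos(angles)[:, None]
        + v[None, :] * np.sin(angles)[:, None]
        + r[None, :]
    ).max(axis=1)
    return l_val, float(widths.min()), b5


# ---------------------------------------------------------------------------
# independent RRHO / quasiharmonic free energy
# ---------------------------------------------------------------------------

_HARTREE_KCAL = 627.5094740631


def free_energy_oracle(
    symbols: list[str],
    coords: np.ndarray,
    masses: dict[str, float],
    e_hartree: float,
    freqs_cm: list[float],
    temperature: float,
    concentration: float | None,
    qh_cutoff: float = 100.0,
) -> float:
    """Quasiharmonic Gibbs free energy (kcal/mol) written from scratch.

    Imaginary modes must already be removed by the caller.
    """
    kB, h, c, NA, R, atm = sc.k, sc.h, sc.c, sc.N_A, sc.R, sc.atm
    cal = sc.calorie
    T = temperature
    m_kg = sum(masses[s] for s in symbols) * sc.atomic_mass

    # translation
    q_t = (2 * math.pi * m_kg * kB * T / h**2) ** 1.5 * kB * T / atm
    s_trans = R * (math.log(q_t) + 2.5)
    u_trans = 1.5 * R * T

    # rotation
    n = len(symbols)
    if n == 1:
        s_rot, u_rot = 0.0, 0.0
    else:
        mvec = np.array([masses[s] for s in symbols]) * sc.atomic_mass
        x = np.asarray(coords) * 1e-10
        com = (mvec[:, None] * x).sum(0) / mvec.sum()
        x = x - com
        inertia = np.zeros((3, 3))
        for a in range(n):
            ra = x[a]
            inertia += mvec[a] * ((ra @ ra) * np.eye(3) - np.outer(ra, ra))
        evals = np.sort(np.linalg.eigvalsh(inertia))
        if evals[0] < 1e-3 * evals[2]:
            q_r = 8 * math.pi**2 * evals[2] * kB * T / h**2
            s_rot = R * (math.log(q_r) + 1.0)
            u_rot = R * T
        else:
            q_r = (
                math.sqrt(math.pi)
                * math.sqrt(np.prod(8 * math.pi**2 * evals * kB * T / h**2))
            )
            s_rot = R * (math.log(q_r) + 1.5)
            u_rot = 1.5 * R * T

    # vibration (Grimme quasiharmonic entropy)
    zpe = u_vib = s_vib = 0.0
    for nu in freqs_cm:
        nu_si = nu * 100.0 * c
        theta = h * nu_si / kB
        x_ = theta / T
        zpe += 0.5 * h * nu_si * NA
        u_vib += R * theta / math.expm1(x_)
        s_ho = R * (x_ / math.expm1(x_) - math.log1p(-math.exp(-x_)))
        mu = h / (8 * math.pi**2 * nu_si)
        mu_eff = mu * 1e-44 / (mu + 1e-44)
        s_fr = R * (0.5 + math.log(math.sqrt(8 * math.pi**3 * mu_eff * kB * T / h**2)))
        w = 1.0 / (1.0 + (qh_cutoff / nu) ** 4) if qh_cutoff > 0 else 1.0
        s_vib += w * s_ho + (1.0 - w) * s_fr

    h_tot_j = zpe + u_trans + u_rot + u_vib + R * T
    g_j = h_tot_j - T * (s_trans + s_rot + s_vib)
    g_kcal = e_hartree * _HARTREE_KCAL + g_j / (cal * 1000.0)
    if concentration is not None:
        g_kcal += (
            R * T * math.log(concentration * 1000.0 * R * T / atm) / (cal * 1000.0)
        )
    return g_kcal


def estate_oracle(symbols, bonds, h_counts, principal_n, valence_e, z_number):
    """Kier-Hall EState indices on an explicit heavy-atom graph, using
    networkx shortest paths."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(symbols)))
    g.add_edges_from(bonds)
    intrinsic = []
    for i, sym in enumerate(symbols):
        nq = principal_n[sym]
        dv = valence_e[sym] - h_counts[i]
        if nq != 2:
            dv = dv / (z_number[sym] - valence_e[sym] - 1)
        delta = max(g.degree[i], 1)
        intrinsic.append(((2.0 / nq) ** 2 * dv + 1.0) / delta)
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    out = []
    for i in range(len(symbols)):
        ds = sum(
            (intrinsic[i] - intrinsic[j]) / (lengths[i][j] + 1) ** 2
            for j in lengths[i]
            if j != i
        )
        out.append(intrinsic[i] + ds)
    return out
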