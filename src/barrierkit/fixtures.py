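"""Deterministic synthetic-data generators for the whole pipeline.

Nothing here runs quantum chemistry.  Reactions are fabricated from a
planar enone template with substituent vocabulary at four positions plus a
small anionic nucleophile fragment; two pseudo-levels ("SQM" reference
geometry perturbed with Gaussian noise and biased energies, "DFT" the
reference) are emitted in the same text formats qm_io reads.  Electronic
energies are back-solved through the thermo module so that the generated
barriers hit planted targets exactly, and every ground truth (bond graph,
key atoms, active features, noise draws) is recorded in a sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import qm_io, thermo
from .featurize import FeatureTable
from .qm_io import KeyAtoms, QMRecord, ReactionRecord, Structure

# bond lengths (Angstrom) used by the geometry templates
_BOND = {"CC": 1.50, "C=C": 1.34, "C=O": 1.22, "CH": 1.09, "CF": 1.35, "CCl": 1.77,
         "CN": 1.35, "NO": 1.25}

# substituent vocabulary: name -> (atoms appended, bond length to anchor)
RGROUP_VOCAB = ("H", "Me", "F", "Cl")


@dataclass
class SyntheticReactionSpec:
    n_reactions: int = 10
    geo_noise_sd: float = 0.05     # Angstrom, SQM geometry perturbation
    bond_bias: float = -0.04       # SQM forming C-C distance shift vs DFT
    barrier_sigma: float = 0.5     # kcal/mol noise on the DFT barrier
    seed: int = 0
    levels: tuple[str, str] = ("SQM", "DFT")
    with_spe: bool = True


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotate_about(v, axis, angle):
    axis = _unit(np.asarray(axis, float))
    v = np.asarray(v, float)
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * (axis @ v) * (1.0 - math.cos(angle))
    )


def _place_rgroup(name: str, anchor: np.ndarray, direction: np.ndarray, normal):
    """Atoms for one substituent: (symbols, coords) with the attachment atom
    first."""
    direction = _unit(direction)
    if name == "H":
        return ["H"], [anchor + _BOND["CH"] * direction]
    if name == "F":
        return ["F"], [anchor + _BOND["CF"] * direction]
    if name == "Cl":
        return ["Cl"], [anchor + _BOND["CCl"] * direction]
    if name == "Me":
        c = anchor + _BOND["CC"] * direction
        syms = ["C"]
        coords = [c]
        # three tetrahedral hydrogens around the methyl carbon
        back = -direction
        for k in range(3):
            hdir = _rotate_about(
                _rotate_about(back, np.cross(back, normal), math.radians(109.5)),
                back,
                2.0 * math.pi * k / 3.0,
            )
            syms.append("H")
            coords.append(c + _BOND["CH"] * _unit(hdir))
        return syms, coords
    raise ValueError(f"unknown R group {name!r}")


def build_ma(rgroups: tuple[str, str, str, str]):
    """Planar enone core Cb=Ca-C(=O) with four substituent positions.

    Returns (Structure, key-atom info dict).  Atom order: core (Cb, Ca,
    Cc, O) then R1..R4 atoms, each R-group's attachment atom first.
    """
    z = np.array([0.0, 0.0, 1.0])
    cb = np.array([0.0, 0.0, 0.0])
    ca = cb + np.array([_BOND["C=C"], 0.0, 0.0])
    cc_dir = _rotate_about(np.array([1.0, 0.0, 0.0]), z, math.radians(-60.0))
    cc = ca + _BOND["CC"] * cc_dir
    o_dir = _rotate_about(-cc_dir, z, math.radians(-120.0))
    o = cc + _BOND["C=O"] * o_dir
    symbols = ["C", "C", "C", "O"]
    coords = [cb, ca, cc, o]
    attachments = []
    # R1, R2 on the beta carbon; R3 on the alpha carbon; R4 on the carbonyl C
    sites = [
        (cb, _rotate_about(np.array([-1.0, 0.0, 0.0]), z, math.radians(30.0))),
        (cb, _rotate_about(np.array([-1.0, 0.0, 0.0]), z, math.radians(-30.0))),
        (ca, -_unit(cc_dir + np.array([-1.0, 0.0, 0.0]))),
        (cc, -_unit(_unit(o_dir) - cc_dir)),
    ]
    for name, (anchor, direction) in zip(rgroups, sites):
        syms, pts = _place_rgroup(name, anchor, direction, z)
        attachments.append(len(symbols))
        symbols.extend(syms)
        coords.extend(pts)
    info = {
        "beta_carbon": 0,
        "alpha_carbon": 1,
        "carbonyl_carbon": 2,
        "carbonyl_oxygen": 3,
        "core": (0, 1, 2, 3),
        "rgroup_attachments": tuple(attachments),
    }
    return Structure(
        symbols=tuple(symbols),
        coords=tuple(tuple(p) for p in np.asarray(coords)),
        role="MA",
        net_charge=0,
        label="synthetic MA " + "/".join(rgroups),
    ), info


def build_nucleophile():
    """Small nitronate-like anion: C(H2)=N(O)O with the carbanion C first."""
    c = np.array([0.0, 0.0, 0.0])
    n = c + np.array([_BOND["CN"], 0.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    o1 = n + _BOND["NO"] * _rotate_about(np.array([1.0, 0.0, 0.0]), z, math.radians(120.0))
    o2 = n + _BOND["NO"] * _rotate_about(np.array([1.0, 0.0, 0.0]), z, math.radians(-120.0))
    h1 = c + _BOND["CH"] * _rotate_about(np.array([-1.0, 0.0, 0.0]), z, math.radians(25.0))
    h2 = c + _BOND["CH"] * _rotate_about(np.array([-1.0, 0.0, 0.0]), z, math.radians(-25.0))
    coords = [c, n, o1, o2, h1, h2]
    return Structure(
        symbols=("C", "N", "O", "O", "H", "H"),
        coords=tuple(tuple(p) for p in coords),
        role="nucleophile",
        net_charge=-1,
        label="synthetic nitronate",
    )


def build_ts(ma: Structure, nucleophile: Structure, forming_distance: float = 2.10):
    """TS = MA atoms followed by nucleophile atoms, nucleophile carbon above
    the beta carbon at the forming C-C distance."""
    ma_pos = ma.positions()
    nu_pos = nucleophile.positions()
    offset = ma_pos[0] + np.array([0.0, 0.0, forming_distance]) - nu_pos[0]
    nu_shifted = nu_pos + offset
    symbols = ma.symbols + nucleophile.symbols
    coords = tuple(tuple(p) for p in np.vstack([ma_pos, nu_shifted]))
    return Structure(
        symbols=symbols,
        coords=coords,
        role="TS",
        net_charge=ma.net_charge + nucleophile.net_charge,
        label=ma.label.replace("MA", "TS"),
    )


def _frequencies(n_atoms: int, rng: np.random.Generator, ts: bool) -> tuple[float, ...]:
    n_modes = 3 * n_atoms - 6
    freqs = np.sort(rng.uniform(300.0, 3200.0, n_modes - (1 if ts else 0)))
    if ts:
        return (float(-rng.uniform(400.0, 700.0)),) + tuple(freqs)
    return tuple(freqs)


def _mulliken(structure: Structure, rng: np.random.Generator) -> tuple[float, ...]:
    base = {"C": 0.05, "H": 0.08, "O": -0.35, "N": 0.1, "F": -0.2, "Cl": -0.1}
    q = np.array([base[s] for s in structure.symbols]) + rng.normal(0, 0.02, structure.n_atoms)
    q += (structure.net_charge - q.sum()) / structure.n_atoms
    return tuple(float(v) for v in q)


# per-R-group planted contribution to the SQM->DFT barrier correction
_RGROUP_EFFECT = {"H": 0.0, "Me": 1.2, "F": -0.8, "Cl": 0.5}


def _thermal_g(rec: QMRecord, temperature: float, concentration: float) -> float:
    """G_qh of a record with its electronic energy zeroed (kcal/mol)."""
    zeroed = QMRecord(
        structure=rec.structure,
        level=rec.level,
        e_elec=0.0,
        frequencies=rec.frequencies,
    )
    return thermo.rrho_thermo(
        zeroed, temperature=temperature, concentration=concentration
    ).g_qh


@dataclass
class GeneratedReaction:
    record: ReactionRecord
    rgroups: tuple[str, str, str, str]
    dg_sqm: float
    dg_dft: float
    correction: float
    noise: float


def build_reaction_records(
    spec: SyntheticReactionSpec,
    temperature: float = 298.15,
    concentration: float = 1.0,
) -> list[GeneratedReaction]:
    """Generate internally consistent ReactionRecords for both pseudo-levels.

    Electronic energies are solved so that the quasiharmonic barrier at the
    generator's thermochemistry settings equals the planted value; the DFT
    barrier is the SQM barrier plus an R-group-determined correction plus
    Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    level_sqm, level_dft = spec.levels
    out: list[GeneratedReaction] = []
    for idx in range(spec.n_reactions):
        rgroups = tuple(rng.choice(RGROUP_VOCAB, 4))
        ma, info = build_ma(rgroups)
        nu = build_nucleophile()
        ts = build_ts(ma, nu, forming_distance=2.10)
        n_ma = ma.n_atoms
        key_atoms = KeyAtoms(
            nucleophile_carbon=n_ma,
            beta_carbon=info["beta_carbon"],
            carbonyl_oxygen=info["carbonyl_oxygen"],
            core=info["core"],
            rgroup_attachments=info["rgroup_attachments"],
            nucleophile_atoms=tuple(range(n_ma, n_ma + nu.n_atoms)),
        )

        dg_sqm = float(rng.uniform(8.0, 40.0))
        correction = sum(_RGROUP_EFFECT[r] for r in rgroups)
        noise = float(rng.normal(0.0, spec.barrier_sigma))
        dg_dft = dg_sqm + correction + noise

        reaction = ReactionRecord(
            reaction_id=f"rxn{idx:04d}", key_atoms=key_atoms, split_tag="unassigned"
        )
        for level, dg_target in ((level_sqm, dg_sqm), (level_dft, dg_dft)):
            if level == level_dft:
                structures = {"MA": ma, "nucleophile": nu, "TS": ts}
            else:
                structures = {
                    "MA": _perturb(ma, rng, spec.geo_noise_sd),
                    "nucleophile": _perturb(nu, rng, spec.geo_noise_sd),
                    "TS": _perturb_ts(ts, key_atoms, rng, spec.geo_noise_sd, spec.bond_bias),
                }
            freqs = {
                role: _frequencies(s.n_atoms, rng, ts=(role == "TS"))
                for role, s in structures.items()
            }
            base_e = {"MA": -200.0, "nucleophile": -150.0}
            recs: dict[str, QMRecord] = {}
            for role in ("MA", "nucleophile"):
                s = structures[role]
                e = base_e[role] + float(rng.normal(0.0, 0.01))
                recs[role] = QMRecord(
                    structure=s,
                    level=level,
                    e_elec=e + 0.005 if spec.with_spe else e,
                    e_spe=e if spec.with_spe else None,
                    frequencies=freqs[role],
                    mulliken=_mulliken(s, rng),
                )
            # back-solve the TS composite energy for the target barrier
            g_corr = {
                role: _thermal_g(recs[role], temperature, concentration)
                for role in ("MA", "nucleophile")
            }
            ts_probe = QMRecord(
                structure=structures["TS"],
                level=level,
                e_elec=0.0,
                frequencies=freqs["TS"],
            )
            g_corr_ts = thermo.rrho_thermo(
                ts_probe, temperature=temperature, concentration=concentration
            ).g_qh
            e_ts = (
                dg_target
                - g_corr_ts
                + g_corr["MA"]
                + g_corr["nucleophile"]
                + (recs["MA"].composite_energy + recs["nucleophile"].composite_energy)
                * thermo.C.HARTREE_TO_KCAL
            ) / thermo.C.HARTREE_TO_KCAL
            recs["TS"] = QMRecord(
                structure=structures["TS"],
                level=level,
                e_elec=e_ts + 0.005 if spec.with_spe else e_ts,
                e_spe=e_ts if spec.with_spe else None,
                frequencies=freqs["TS"],
                mulliken=_mulliken(structures["TS"], rng),
            )
            reaction.records[level] = recs
        out.append(
            GeneratedReaction(
                record=reaction,
                rgroups=rgroups,
                dg_sqm=dg_sqm,
                dg_dft=dg_dft,
                correction=correction,
                noise=noise,
            )
        )
    return out


def _perturb(structure: Structure, rng: np.random.Generator, sd: float) -> Structure:
    if sd == 0.0:
        return structure
    pos = structure.positions() + rng.normal(0.0, sd, (structure.n_atoms, 3))
    return Structure(
        symbols=structure.symbols,
        coords=tuple(tuple(p) for p in pos),
        role=structure.role,
        net_charge=structure.net_charge,
        label=structure.label,
    )


def _perturb_ts(
    ts: Structure,
    key_atoms: KeyAtoms,
    rng: np.random.Generator,
    sd: float,
    bond_bias: float,
) -> Structure:
    """Noise plus a systematic shift of the forming C-C distance."""
    pos = ts.positions()
    if bond_bias != 0.0:
        nuc = list(key_atoms.nucleophile_atoms)
        axis = _unit(pos[key_atoms.nucleophile_carbon] - pos[key_atoms.beta_carbon])
        pos[nuc] += bond_bias * axis
    if sd > 0.0:
        pos = pos + rng.normal(0.0, sd, pos.shape)
    return Structure(
        symbols=ts.symbols,
        coords=tuple(tuple(p) for p in pos),
        role=ts.role,
        net_charge=ts.net_charge,
        label=ts.label,
    )


def generate_reactions(
    spec: SyntheticReactionSpec, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write native logs, XYZ files, a manifest CSV and a ground-truth
    sidecar; returns (manifest path, sidecar path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    generated = build_reaction_records(spec)
    rows = []
    truth = []
    for gen in generated:
        reaction = gen.record
        rid = reaction.reaction_id
        for level in spec.levels:
            for role in ("MA", "nucleophile", "TS"):
                rec = reaction.get(level, role)
                fname = f"{rid}_{level}_{role}.log"
                qm_io.write_native_log(rec, out_dir / fname)
                qm_io.write_xyz(rec.structure, out_dir / f"{rid}_{level}_{role}.xyz")
                rows.append(
                    {
                        "reaction_id": rid,
                        "level": level,
                        "role": role,
                        "path": fname,
                        "key_atoms": reaction.key_atoms.to_compact(),
                        "split_tag": reaction.split_tag,
                    }
                )
        truth.append(
            {
                "reaction_id": rid,
                "rgroups": list(gen.rgroups),
                "dg_sqm": gen.dg_sqm,
                "dg_dft": gen.dg_dft,
                "correction": gen.correction,
                "noise": gen.noise,
                "key_atoms": reaction.key_atoms.as_dict(),
            }
        )
    manifest = out_dir / "manifest.csv"
    qm_io.save_manifest(rows, manifest)
    sidecar = out_dir / "ground_truth.json"
    sidecar.write_text(json.dumps({"spec": vars_of(spec), "reactions": truth}, indent=2))
    return manifest, sidecar


def vars_of(spec: SyntheticReactionSpec) -> dict:
    d = dict(spec.__dict__)
    d["levels"] = list(d["levels"])
    return d


# ---------------------------------------------------------------------------
# synthetic feature tables (for the learn module)
# ---------------------------------------------------------------------------

_TRANSFORMS = (
    lambda x: x,
    lambda x: np.tanh(x),
    lambda x: 0.5 * x * np.abs(x),
    lambda x: np.sin(x),
)


@dataclass
class FeatureTableTruth:
    active: list[int]
    coefficients: list[float]
    noise: np.ndarray
    baseline: np.ndarray
    correlated_pair: tuple[int, int] | None


def generate_feature_table(
    n: int = 1000,
    n_features: int = 30,
    active: tuple[int, ...] = (2, 7, 11, 19, 24),
    coefficients: tuple[float, ...] | None = None,
    sigma: float = 0.5,
    seed: int = 0,
    correlated_pair: tuple[int, int, float] | None = None,
    n_literature: int = 0,
) -> tuple[FeatureTable, FeatureTableTruth]:
    """Correlated-Gaussian features with a sparse additive planted signal.

    Target: dG_DFT = baseline + g(active features) + N(0, sigma), with the
    baseline barrier included as the feature column "barrier" so the table
    supports both direct and delta targets.
    """
    if active == (2, 7, 11, 19, 24):
        # default pattern: keep the members that fit the feature count
        active = tuple(a for a in active if a < n_features) or (0,)
    if any(a >= n_features for a in active):
        raise ValueError("active indices must be < n_features")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, n_features))
    pair = None
    if correlated_pair is not None:
        i, j, rho = correlated_pair
        x[:, j] = rho * x[:, i] + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        pair = (i, j)
    coefs = (
        list(coefficients)
        if coefficients is not None
        else [3.0, 2.5, 2.0, 1.5, 1.0][: len(active)]
    )
    if len(coefs) != len(active):
        raise ValueError("coefficients must match active features")
    g = np.zeros(n)
    for k, (a, c) in enumerate(zip(active, coefs)):
        g += c * _TRANSFORMS[k % len(_TRANSFORMS)](x[:, a])
    baseline = rng.uniform(8.0, 40.0, n)
    noise = rng.normal(0.0, sigma, n)
    y = baseline + g + noise
    ids = [f"s{i:04d}" for i in range(n)]
    frame = pd.DataFrame(
        x, index=ids, columns=[f"f{i:02d}" for i in range(n_features)]
    )
    frame["barrier"] = baseline
    split = pd.Series("unassigned", index=ids)
    if n_literature:
        split.iloc[-n_literature:] = "literature"
    table = FeatureTable(
        frame=frame,
        level="SQM",
        subset="All",
        target=pd.Series(y, index=ids),
        split=split,
        baseline="barrier",
    )
    truth = FeatureTableTruth(
        active=list(active),
        coefficients=list(coefs),
        noise=noise,
        baseline=baseline,
        correlated_pair=pair,
    )
    return table, truth
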