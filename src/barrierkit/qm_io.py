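"""Structure / quantum-chemistry record I/O and reaction manifests.

Native formats are plain text: standard XYZ for bare geometries and a small
line-oriented "native log" dialect for geometry + energy + frequency +
Mulliken records (see :data:`NATIVE_LOG_HEADER`).  Gaussian-style logs are
supported through the pluggable parser registry so that externally produced
output files can be ingested without touching downstream code.

Conventions fixed at ingestion: coordinates in Angstrom, energies in
Hartree, frequencies in signed cm^-1 (negative = imaginary), charges in
elementary charge units.  All atom indexing is 0-based.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .constants import ATOMIC_NUMBER

ROLES = ("MA", "nucleophile", "TS", "product")

NATIVE_LOG_HEADER = "#NATIVELOG v1"


class ParseError(ValueError):
    """Malformed input file."""


class SpeciesMismatchError(ValueError):
    """Two records that should describe the same species do not."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Structure:
    """An ordered molecular geometry with a pipeline role tag."""

    symbols: tuple[str, ...]
    coords: tuple[tuple[float, float, float], ...]
    role: str = "MA"
    net_charge: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError("structure needs at least one atom")
        if len(self.symbols) != len(self.coords):
            raise ValueError("symbols/coords length mismatch")
        for sym in self.symbols:
            if sym not in ATOMIC_NUMBER:
                raise ValueError(f"unknown element symbol {sym!r}")
        for xyz in self.coords:
            if not all(math.isfinite(v) for v in xyz):
                raise ValueError("non-finite coordinate")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def positions(self):
        import numpy as np

        return np.asarray(self.coords, dtype=float)

    def subset(self, indices: Sequence[int]) -> "Structure":
        idx = list(indices)
        return replace(
            self,
            symbols=tuple(self.symbols[i] for i in idx),
            coords=tuple(self.coords[i] for i in idx),
        )


@dataclass(frozen=True)
class QMRecord:
    """A structure plus the electronic-structure data needed downstream."""

    structure: Structure
    level: str
    e_elec: float
    e_spe: float | None = None
    frequencies: tuple[float, ...] = ()
    mulliken: tuple[float, ...] | None = None
    temperature: float = 298.15
    pressure_or_conc: str = "1 atm"

    def __post_init__(self) -> None:
        if self.mulliken is not None and len(self.mulliken) != self.structure.n_atoms:
            raise ValueError("mulliken length must equal atom count")

    @property
    def composite_energy(self) -> float:
        """Solvent single-point energy when present, else gas-phase E."""
        return self.e_spe if self.e_spe is not None else self.e_elec

    @property
    def n_imaginary(self) -> int:
        return sum(1 for f in self.frequencies if f < 0)

    def validate_role(self) -> None:
        """Enforce the imaginary-frequency invariant for the record's role."""
        n_imag = self.n_imaginary
        if self.structure.role == "TS":
            if n_imag != 1:
                raise ValueError(
                    f"TS record {self.structure.label!r} has {n_imag} imaginary "
                    "frequencies, expected exactly 1"
                )
        elif n_imag != 0:
            raise ValueError(
                f"minimum record {self.structure.label!r} has {n_imag} imaginary "
                "frequencies, expected 0"
            )


@dataclass(frozen=True)
class KeyAtoms:
    """0-based indices locating the reacting atoms and fragment memberships.

    Indices refer to the TS atom ordering; MA structures must share the MA
    part of that ordering (MA atoms first, nucleophile atoms appended).
    """

    nucleophile_carbon: int
    beta_carbon: int
    carbonyl_oxygen: int
    core: tuple[int, ...]
    rgroup_attachments: tuple[int, ...]
    nucleophile_atoms: tuple[int, ...]

    def as_dict(self) -> dict:
        return {
            "nucleophile_carbon": self.nucleophile_carbon,
            "beta_carbon": self.beta_carbon,
            "carbonyl_oxygen": self.carbonyl_oxygen,
            "core": list(self.core),
            "rgroup_attachments": list(self.rgroup_attachments),
            "nucleophile_atoms": list(self.nucleophile_atoms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KeyAtoms":
        return cls(
            nucleophile_carbon=int(d["nucleophile_carbon"]),
            beta_carbon=int(d["beta_carbon"]),
            carbonyl_oxygen=int(d["carbonyl_oxygen"]),
            core=tuple(int(i) for i in d["core"]),
            rgroup_attachments=tuple(int(i) for i in d["rgroup_attachments"]),
            nucleophile_atoms=tuple(int(i) for i in d["nucleophile_atoms"]),
        )

    def to_compact(self) -> str:
        parts = [
            f"nuc={self.nucleophile_carbon}",
            f"beta={self.beta_carbon}",
            f"oxo={self.carbonyl_oxygen}",
            "core=" + ",".join(str(i) for i in self.core),
            "rg=" + ",".join(str(i) for i in self.rgroup_attachments),
            "nucatoms=" + ",".join(str(i) for i in self.nucleophile_atoms),
        ]
        return ";".join(parts)

    @classmethod
    def from_compact(cls, text: str) -> "KeyAtoms":
        fields: dict[str, str] = {}
        for chunk in text.split(";"):
            k, _, v = chunk.partition("=")
            fields[k.strip()] = v.strip()
        ints = lambda s: tuple(int(i) for i in s.split(",") if i != "")
        return cls(
            nucleophile_carbon=int(fields["nuc"]),
            beta_carbon=int(fields["beta"]),
            carbonyl_oxygen=int(fields["oxo"]),
            core=ints(fields["core"]),
            rgroup_attachments=ints(fields["rg"]),
            nucleophile_atoms=ints(fields["nucatoms"]),
        )


@dataclass
class ReactionRecord:
    """All per-level records for one reaction, plus key atoms and split tag."""

    reaction_id: str
    records: dict[str, dict[str, QMRecord]] = field(default_factory=dict)
    key_atoms: KeyAtoms | None = None
    split_tag: str = "unassigned"

    def get(self, level: str, role: str) -> QMRecord:
        try:
            return self.records[level][role]
        except KeyError:
            raise KeyError(
                f"reaction {self.reaction_id}: no {role} record at level {level}"
            ) from None

    def has(self, level: str, role: str) -> bool:
        return level in self.records and role in self.records[level]

    def levels(self) -> list[str]:
        return sorted(self.records)

    def validate_key_atoms(self) -> None:
        if self.key_atoms is None:
            return
        ka = self.key_atoms
        all_idx = (
            [ka.nucleophile_carbon, ka.beta_carbon, ka.carbonyl_oxygen]
            + list(ka.core)
            + list(ka.rgroup_attachments)
            + list(ka.nucleophile_atoms)
        )
        for level, by_role in self.records.items():
            for role, rec in by_role.items():
                n = rec.structure.n_atoms
                # MA/nucleophile structures only contain their own fragment.
                if role == "TS":
                    bad = [i for i in all_idx if not 0 <= i < n]
                    if bad:
                        raise ValueError(
                            f"reaction {self.reaction_id}: key atom indices {bad} "
                            f"out of range for {level}/{role} ({n} atoms)"
                        )


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------


def read_xyz(path: str | Path, role: str = "MA", net_charge: int = 0) -> Structure:
    """Read one standard XYZ file (count line, comment line, atom rows)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:1: malformed atom count {lines[0]!r}") from None
    if len(lines) < count + 2:
        raise ParseError(f"{path}: expected {count} atom rows, file truncated")
    label = lines[1].strip() if len(lines) > 1 else ""
    symbols: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for lineno, line in enumerate(lines[2 : 2 + count], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: expected 'El x y z', got {line!r}")
        try:
            xyz = (float(parts[1]), float(parts[2]), float(parts[3]))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from None
        symbols.append(parts[0])
        coords.append(xyz)
    return Structure(
        symbols=tuple(symbols),
        coords=tuple(coords),
        role=role,
        net_charge=net_charge,
        label=label,
    )


def write_xyz(structure: Structure, path: str | Path) -> None:
    path = Path(path)
    lines = [str(structure.n_atoms), structure.label]
    for sym, (x, y, z) in zip(structure.symbols, structure.coords):
        lines.append(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# native log dialect
# ---------------------------------------------------------------------------
#
#   #NATIVELOG v1
#   [level] AM1
#   [charge] 0
#   [role] TS
#   [energy] -123.456789
#   [spe] -123.456000            (optional)
#   [geometry]
#   C   0.0 0.0 0.0
#   ...
#   [frequencies]
#   -512.3 233.1 ...             (whitespace separated, may span lines)
#   [mulliken]
#   -0.51 0.22 ...               (one value per atom, may span lines)
#
# Repeated [geometry]/[energy] sections are allowed; the LAST one wins,
# mirroring how optimisation logs carry intermediate steps.


def write_native_log(rec: QMRecord, path: str | Path) -> None:
    s = rec.structure
    out = [NATIVE_LOG_HEADER]
    out.append(f"[level] {rec.level}")
    out.append(f"[charge] {s.net_charge}")
    out.append(f"[role] {s.role}")
    out.append(f"[label] {s.label}")
    out.append(f"[energy] {rec.e_elec:.12f}")
    if rec.e_spe is not None:
        out.append(f"[spe] {rec.e_spe:.12f}")
    out.append("[geometry]")
    for sym, (x, y, z) in zip(s.symbols, s.coords):
        out.append(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    if rec.frequencies:
        out.append("[frequencies]")
        out.append(" ".join(f"{f:.4f}" for f in rec.frequencies))
    if rec.mulliken is not None:
        out.append("[mulliken]")
        out.append(" ".join(f"{q:.6f}" for q in rec.mulliken))
    Path(path).write_text("\n".join(out) + "\n")


def _parse_native_log(text: str, path: Path, level: str | None) -> QMRecord:
    lines = text.splitlines()
    meta: dict[str, str] = {"role": "MA", "charge": "0", "label": "", "level": ""}
    energy: float | None = None
    spe: float | None = None
    geometry: list[tuple[str, float, float, float]] = []
    freqs: list[float] = []
    mulliken: list[float] = []
    section = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            tag, _, rest = line.partition("]")
            tag = tag.lstrip("[").strip().lower()
            rest = rest.strip()
            if tag in ("level", "role", "label"):
                meta[tag] = rest
                section = None
            elif tag == "charge":
                meta["charge"] = rest
                section = None
            elif tag == "energy":
                try:
                    energy = float(rest)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: bad energy {rest!r}") from None
                section = None
            elif tag == "spe":
                try:
                    spe = float(rest)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: bad spe {rest!r}") from None
                section = None
            elif tag == "geometry":
                geometry = []  # last block wins
                section = "geometry"
            elif tag == "frequencies":
                freqs = []
                section = "frequencies"
            elif tag == "mulliken":
                mulliken = []
                section = "mulliken"
            else:
                raise ParseError(f"{path}:{lineno}: unknown section [{tag}]")
            continue
        if section == "geometry":
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: bad geometry row {line!r}")
            try:
                geometry.append(
                    (parts[0], float(parts[1]), float(parts[2]), float(parts[3]))
                )
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from None
        elif section == "frequencies":
            try:
                freqs.extend(float(v) for v in line.split())
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric frequency") from None
        elif section == "mulliken":
            try:
                mulliken.extend(float(v) for v in line.split())
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric charge") from None
        else:
            raise ParseError(f"{path}:{lineno}: data outside any section: {line!r}")
    if energy is None:
        raise ParseError(f"{path}: no [energy] entry found")
    if not geometry:
        raise ParseError(f"{path}: no [geometry] block found")
    structure = Structure(
        symbols=tuple(g[0] for g in geometry),
        coords=tuple((g[1], g[2], g[3]) for g in geometry),
        role=meta["role"],
        net_charge=int(meta["charge"]),
        label=meta["label"],
    )
    return QMRecord(
        structure=structure,
        level=level or meta["level"] or "unknown",
        e_elec=energy,
        e_spe=spe,
        frequencies=tuple(freqs),
        mulliken=tuple(mulliken) if mulliken else None,
    )


# ---------------------------------------------------------------------------
# Gaussian-style parser (registry entry for externally produced logs)
# ---------------------------------------------------------------------------


def _parse_gaussian_log(text: str, path: Path, level: str | None) -> QMRecord:
    """Minimal Gaussian16-style parser: last standard orientation, last SCF
    energy, 'Frequencies --' rows, and the last Mulliken charge block."""
    lines = text.splitlines()
    geometry: list[tuple[str, float, float, float]] = []
    energy: float | None = None
    freqs: list[float] = []
    mulliken: list[float] = []
    symbols_by_z = {z: sym for sym, z in ATOMIC_NUMBER.items()}
    i = 0
    while i < len(lines):
        line = lines[i]
        if "Standard orientation" in line or "Input orientation" in line:
            block: list[tuple[str, float, float, float]] = []
            j = i + 5  # skip header rule lines
            while j < len(lines) and not lines[j].lstrip().startswith("----"):
                parts = lines[j].split()
                if len(parts) >= 6:
                    z = int(parts[1])
                    block.append(
                        (symbols_by_z[z], float(parts[-3]), float(parts[-2]), float(parts[-1]))
                    )
                j += 1
            if block:
                geometry = block
            i = j
        elif "SCF Done" in line:
            # e.g.  SCF Done:  E(RAM1) =  0.0421234  A.U. after ...
            parts = line.split("=")
            if len(parts) >= 2:
                try:
                    energy = float(parts[1].split()[0])
                except ValueError:
                    pass
        elif line.lstrip().startswith("Frequencies --"):
            freqs.extend(float(v) for v in line.split("--")[1].split())
        elif "Mulliken charges" in line and "sum of" not in line.lower():
            block_q: list[float] = []
            j = i + 2
            while j < len(lines):
                parts = lines[j].split()
                if len(parts) == 3 and parts[1] in ATOMIC_NUMBER:
                    block_q.append(float(parts[2]))
                    j += 1
                else:
                    break
            if block_q:
                mulliken = block_q
            i = j
        i += 1
    if energy is None:
        raise ParseError(f"{path}: no SCF energy found")
    if not geometry:
        raise ParseError(f"{path}: no orientation block found")
    structure = Structure(
        symbols=tuple(g[0] for g in geometry),
        coords=tuple((g[1], g[2], g[3]) for g in geometry),
    )
    return QMRecord(
        structure=structure,
        level=level or "unknown",
        e_elec=energy,
        frequencies=tuple(freqs),
        mulliken=tuple(mulliken) if mulliken else None,
    )


LogParser = Callable[[str, Path, "str | None"], QMRecord]

LOG_PARSERS: dict[str, LogParser] = {
    "native": _parse_native_log,
    "gaussian": _parse_gaussian_log,
}


def register_log_parser(name: str, parser: LogParser) -> None:
    LOG_PARSERS[name] = parser


def _sniff_dialect(text: str) -> str:
    if text.startswith(NATIVE_LOG_HEADER):
        return "native"
    return "gaussian"


def read_qm_log(
    path: str | Path, level: str | None = None, dialect: str | None = None
) -> QMRecord:
    """Parse a log file into a QMRecord, taking the LAST geometry/energy.

    ``dialect`` selects a registered parser; by default the file is sniffed
    (native header vs anything else -> gaussian).
    """
    path = Path(path)
    text = path.read_text()
    name = dialect or _sniff_dialect(text)
    try:
        parser = LOG_PARSERS[name]
    except KeyError:
        raise ValueError(f"unknown log dialect {name!r}") from None
    rec = parser(text, path, level)
    _check_frequency_count(rec, path)
    return rec


def _is_linear(structure: Structure, tol: float = 1e-6) -> bool:
    import numpy as np

    if structure.n_atoms <= 2:
        return True
    pos = structure.positions()
    pos = pos - pos.mean(axis=0)
    s = np.linalg.svd(pos, compute_uv=False)
    return bool(s[1] < tol * max(s[0], 1.0))


def _check_frequency_count(rec: QMRecord, path: Path) -> None:
    import warnings

    n = rec.structure.n_atoms
    if n == 1 or not rec.frequencies:
        return
    expected = 3 * n - 5 if _is_linear(rec.structure) else 3 * n - 6
    if len(rec.frequencies) != expected:
        warnings.warn(
            f"{path}: {len(rec.frequencies)} frequencies for {n} atoms "
            f"(expected {expected}); low-mode/projection conventions vary",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# merging and manifests
# ---------------------------------------------------------------------------


def merge_spe(opt: QMRecord, spe: QMRecord) -> QMRecord:
    """Attach a single-point record's energy to an optimisation record."""
    if opt.structure.symbols != spe.structure.symbols:
        raise SpeciesMismatchError(
            "cannot merge SPE: element sequences differ "
            f"({opt.structure.label!r} vs {spe.structure.label!r})"
        )
    return replace(opt, e_spe=spe.e_elec)


MANIFEST_COLUMNS = ["reaction_id", "level", "role", "path", "key_atoms", "split_tag"]


@dataclass
class ManifestIssue:
    reaction_id: str
    message: str


def load_manifest(
    path: str | Path, strict: bool = False
) -> tuple[list[ReactionRecord], list[ManifestIssue]]:
    """Load a CSV or JSON reaction manifest and resolve every referenced file.

    Returns the loadable reactions plus a per-reaction issue report; with
    ``strict=True`` any issue raises instead.  Paths are resolved relative to
    the manifest's directory.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        for row in rows:
            if isinstance(row.get("key_atoms"), dict):
                row["key_atoms"] = KeyAtoms.from_dict(row["key_atoms"]).to_compact()
    else:
        with path.open(newline="") as fh:
            rows = list(csv.DictReader(fh))
    base = path.parent

    by_reaction: dict[str, list[dict]] = {}
    order: list[str] = []
    for row in rows:
        rid = str(row["reaction_id"])
        if rid not in by_reaction:
            by_reaction[rid] = []
            order.append(rid)
        by_reaction[rid].append(row)

    reactions: list[ReactionRecord] = []
    issues: list[ManifestIssue] = []
    for rid in order:
        group = by_reaction[rid]
        rec = ReactionRecord(reaction_id=rid)
        failed = False
        for row in group:
            level = str(row["level"])
            role = str(row["role"])
            if role not in ROLES:
                issues.append(ManifestIssue(rid, f"unknown role {role!r}"))
                failed = True
                continue
            fpath = base / str(row["path"])
            if not fpath.exists():
                issues.append(ManifestIssue(rid, f"missing file {fpath}"))
                failed = True
                continue
            try:
                qrec = read_qm_log(fpath, level=level)
            except ParseError as exc:
                issues.append(ManifestIssue(rid, str(exc)))
                failed = True
                continue
            qrec = replace(qrec, structure=replace(qrec.structure, role=role))
            if level in rec.records and role in rec.records[level]:
                raise ValueError(
                    f"duplicate manifest entry for reaction {rid!r} at {level}/{role}"
                )
            rec.records.setdefault(level, {})[role] = qrec
            if row.get("key_atoms"):
                rec.key_atoms = KeyAtoms.from_compact(str(row["key_atoms"]))
            tag = str(row.get("split_tag") or "unassigned")
            if tag != "unassigned":
                rec.split_tag = tag
        if not failed:
            try:
                rec.validate_key_atoms()
            except ValueError as exc:
                issues.append(ManifestIssue(rid, str(exc)))
                failed = True
        if failed:
            continue
        reactions.append(rec)

    if strict and issues:
        detail = "; ".join(f"{i.reaction_id}: {i.message}" for i in issues)
        raise ValueError(f"manifest issues: {detail}")
    return reactions, issues


def save_manifest(rows: Iterable[dict], path: str | Path) -> None:
    """Write manifest rows (dicts with MANIFEST_COLUMNS keys) as CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in MANIFEST_COLUMNS})
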