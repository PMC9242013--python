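"""Quasiharmonic ideal-gas thermochemistry and activation barriers.

Free energies follow the rigid-rotor harmonic-oscillator (RRHO) partition
functions at 1 atm, with the low-frequency vibrational entropy optionally
damped toward a free-rotor limit (Grimme interpolation with a Head-Gordon
style damping function) or handled by Truhlar frequency raising.  A molar
standard-state term converts barriers to solution-phase concentrations.

Energies enter in Hartree and leave in kcal/mol; entropies are reported in
cal/(mol K).  Symmetry numbers are fixed at 1 and frequencies are unscaled
unless a scaling factor is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as C
from .qm_io import QMRecord, ReactionRecord

DEFAULT_QH_CUTOFF = 100.0  # cm^-1


@dataclass(frozen=True)
class ThermoResult:
    """Component thermochemistry terms for one species."""

    zpe: float            # kcal/mol
    u_trans: float        # kcal/mol
    u_rot: float          # kcal/mol
    u_vib: float          # kcal/mol
    s_trans: float        # cal/(mol K)
    s_rot: float          # cal/(mol K)
    s_vib_rrho: float     # cal/(mol K)
    s_vib_qh: float       # cal/(mol K)
    h: float              # kcal/mol, composite enthalpy
    g_qh: float           # kcal/mol, composite quasiharmonic free energy
    temperature: float    # K
    standard_state: str   # "1 atm" or "x mol/L"


def _vibrational_temps(frequencies_cm: np.ndarray, scale: float) -> np.ndarray:
    """Characteristic temperatures h c nu / k for each mode (K)."""
    nu_si = frequencies_cm * scale * 100.0 * C.C_LIGHT  # Hz
    return C.H_PLANCK * nu_si / C.KB


def translational_entropy(mass_amu: float, temperature: float, pressure_pa: float = C.ATM_PA) -> float:
    """Sackur-Tetrode translational entropy, cal/(mol K)."""
    m = mass_amu * C.AMU_KG
    lam_term = (2.0 * math.pi * m * C.KB * temperature / C.H_PLANCK**2) ** 1.5
    q_t = lam_term * C.KB * temperature / pressure_pa
    return C.R_CAL * (math.log(q_t) + 2.5)


def _inertia_moments(rec: QMRecord) -> np.ndarray:
    """Principal moments of inertia (kg m^2), ascending."""
    s = rec.structure
    masses = np.array([C.ATOMIC_MASS[sym] for sym in s.symbols]) * C.AMU_KG
    pos = s.positions() * 1e-10  # m
    com = (masses[:, None] * pos).sum(axis=0) / masses.sum()
    r = pos - com
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    ixx = (masses * (y**2 + z**2)).sum()
    iyy = (masses * (x**2 + z**2)).sum()
    izz = (masses * (x**2 + y**2)).sum()
    ixy = -(masses * x * y).sum()
    ixz = -(masses * x * z).sum()
    iyz = -(masses * y * z).sum()
    tensor = np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])
    return np.sort(np.linalg.eigvalsh(tensor))


def _rotational_terms(rec: QMRecord, temperature: float, sigma: int = 1) -> tuple[float, float, int]:
    """(S_rot in cal/(mol K), U_rot in kcal/mol, rotational DoF)."""
    n = rec.structure.n_atoms
    if n == 1:
        return 0.0, 0.0, 0
    moments = _inertia_moments(rec)
    linear = moments[0] < 1e-3 * moments[2]
    kT = C.KB * temperature
    if linear:
        i_b = moments[2]
        q_r = 8.0 * math.pi**2 * i_b * kT / (sigma * C.H_PLANCK**2)
        s_rot = C.R_CAL * (math.log(q_r) + 1.0)
        return s_rot, C.R_KCAL * temperature, 2
    qa = math.sqrt(math.pi * np.prod(8.0 * math.pi**2 * moments * kT / C.H_PLANCK**2)) / sigma
    s_rot = C.R_CAL * (math.log(qa) + 1.5)
    return s_rot, 1.5 * C.R_KCAL * temperature, 3


def _vib_frequencies_for_sums(rec: QMRecord) -> np.ndarray:
    """Real mode list with the TS's single imaginary mode dropped."""
    freqs = np.asarray(rec.frequencies, dtype=float)
    n_imag = int((freqs < 0).sum())
    role = rec.structure.role
    if role == "TS":
        if n_imag != 1:
            raise ValueError(
                f"TS {rec.structure.label!r}: expected exactly one imaginary "
                f"frequency, found {n_imag}"
            )
        freqs = freqs[freqs > 0]
    else:
        if n_imag != 0:
            raise ValueError(
                f"minimum {rec.structure.label!r}: found {n_imag} imaginary "
                "frequencies"
            )
    return freqs


def _rrho_mode_entropies(theta: np.ndarray, temperature: float) -> np.ndarray:
    """Harmonic-oscillator per-mode entropies, cal/(mol K)."""
    x = theta / temperature
    return C.R_CAL * (x / np.expm1(x) - np.log1p(-np.exp(-x)))


def _free_rotor_entropies(frequencies_cm: np.ndarray, temperature: float) -> np.ndarray:
    """Grimme's effective free-rotor per-mode entropies, cal/(mol K)."""
    nu_si = frequencies_cm * 100.0 * C.C_LIGHT
    mu = C.H_PLANCK / (8.0 * math.pi**2 * nu_si)
    mu_eff = mu * C.B_AV / (mu + C.B_AV)
    arg = 8.0 * math.pi**3 * mu_eff * C.KB * temperature / C.H_PLANCK**2
    return C.R_CAL * (0.5 + np.log(np.sqrt(arg)))


def quasiharmonic_entropy(
    frequencies_cm,
    temperature: float,
    cutoff: float = DEFAULT_QH_CUTOFF,
    scheme: str = "grimme",
    scale: float = 1.0,
) -> float:
    """Quasiharmonic vibrational entropy, cal/(mol K).

    ``grimme``: per-mode interpolation S = w S_HO + (1-w) S_FR with the
    damping w = 1/(1 + (cutoff/nu)^4).  ``truhlar``: frequencies below the
    cutoff are raised to the cutoff before the RRHO sum.  ``rrho``: no
    treatment.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    freqs = np.asarray(frequencies_cm, dtype=float) * scale
    if (freqs <= 0).any():
        raise ValueError("quasiharmonic entropy requires strictly real frequencies")
    if freqs.size == 0:
        return 0.0
    if scheme == "rrho":
        theta = _vibrational_temps(freqs, 1.0)
        return float(_rrho_mode_entropies(theta, temperature).sum())
    if scheme == "truhlar":
        raised = np.maximum(freqs, cutoff)
        theta = _vibrational_temps(raised, 1.0)
        return float(_rrho_mode_entropies(theta, temperature).sum())
    if scheme != "grimme":
        raise ValueError(f"unknown quasiharmonic scheme {scheme!r}")
    theta = _vibrational_temps(freqs, 1.0)
    s_ho = _rrho_mode_entropies(theta, temperature)
    s_fr = _free_rotor_entropies(freqs, temperature)
    if cutoff == 0.0:
        return float(s_ho.sum())
    w = 1.0 / (1.0 + (cutoff / freqs) ** 4)
    return float((w * s_ho + (1.0 - w) * s_fr).sum())


def standard_state_correction(
    temperature: float, concentration: float = 1.0, pressure_pa: float = C.ATM_PA
) -> float:
    """Free-energy shift (kcal/mol) from a 1 atm gas standard state to a
    molar concentration standard state: RT ln(c RT / p)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    c_si = concentration * 1000.0  # mol/m^3
    ratio = c_si * C.R_GAS * temperature / pressure_pa
    return C.R_KCAL * temperature * math.log(ratio)


def rrho_thermo(
    rec: QMRecord,
    temperature: float = 298.15,
    qh_scheme: str = "grimme",
    qh_cutoff: float = DEFAULT_QH_CUTOFF,
    freq_scale: float = 1.0,
    concentration: float | None = None,
) -> ThermoResult:
    """Full ideal-gas (quasi-)RRHO thermochemistry for one record.

    ``concentration`` (mol/L), when given, adds the molar standard-state
    term to G; otherwise G refers to 1 atm.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    s = rec.structure
    if s.n_atoms > 1 and not rec.frequencies:
        raise ValueError(
            f"polyatomic {s.label!r} has no frequencies; thermochemistry undefined"
        )
    mass = sum(C.ATOMIC_MASS[sym] for sym in s.symbols)

    s_trans = translational_entropy(mass, temperature)
    u_trans = 1.5 * C.R_KCAL * temperature
    s_rot, u_rot, _ = _rotational_terms(rec, temperature)

    freqs = _vib_frequencies_for_sums(rec) * freq_scale
    if freqs.size:
        theta = _vibrational_temps(freqs, 1.0)
        zpe = float((0.5 * C.R_KCAL * theta).sum())
        x = theta / temperature
        u_vib = float((C.R_KCAL * theta / np.expm1(x)).sum())
        s_vib_rrho = float(_rrho_mode_entropies(theta, temperature).sum())
        s_vib_qh = quasiharmonic_entropy(
            freqs, temperature, cutoff=qh_cutoff, scheme=qh_scheme
        )
    else:
        zpe = u_vib = s_vib_rrho = s_vib_qh = 0.0

    e0 = rec.composite_energy * C.HARTREE_TO_KCAL
    # H = E + ZPE + thermal corrections + RT (pV term for ideal gas)
    h = e0 + zpe + u_trans + u_rot + u_vib + C.R_KCAL * temperature
    s_total_cal = s_trans + s_rot + s_vib_qh
    g = h - temperature * s_total_cal / 1000.0
    state = "1 atm"
    if concentration is not None:
        g += standard_state_correction(temperature, concentration)
        state = f"{concentration:g} mol/L"
    return ThermoResult(
        zpe=zpe,
        u_trans=u_trans,
        u_rot=u_rot,
        u_vib=u_vib,
        s_trans=s_trans,
        s_rot=s_rot,
        s_vib_rrho=s_vib_rrho,
        s_vib_qh=s_vib_qh,
        h=h,
        g_qh=g,
        temperature=temperature,
        standard_state=state,
    )


@dataclass(frozen=True)
class BarrierRecord:
    reaction_id: str
    level: str
    dg_act: float  # kcal/mol


def activation_barrier(
    reaction: ReactionRecord,
    level: str,
    temperature: float = 298.15,
    concentration: float = 1.0,
    qh_scheme: str = "grimme",
    qh_cutoff: float = DEFAULT_QH_CUTOFF,
    freq_scale: float = 1.0,
) -> BarrierRecord:
    """Bimolecular activation free energy G(TS) - G(MA) - G(nucleophile)."""
    results = {}
    for role in ("MA", "nucleophile", "TS"):
        if not reaction.has(level, role):
            raise ValueError(
                f"reaction {reaction.reaction_id}: missing {role} record at "
                f"level {level}"
            )
        rec = reaction.get(level, role)
        rec.validate_role()
        results[role] = rrho_thermo(
            rec,
            temperature=temperature,
            qh_scheme=qh_scheme,
            qh_cutoff=qh_cutoff,
            freq_scale=freq_scale,
            concentration=concentration,
        )
    dg = results["TS"].g_qh - results["MA"].g_qh - results["nucleophile"].g_qh
    if not math.isfinite(dg):
        raise ValueError(f"reaction {reaction.reaction_id}: non-finite barrier")
    return BarrierRecord(reaction_id=reaction.reaction_id, level=level, dg_act=dg)
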