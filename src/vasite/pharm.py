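"""Binding-energy pharmacology: Kd, occupancy and concentration arithmetic.

Converts a binding free energy ΔG (kcal/mol) to an equilibrium
dissociation constant at 1 M standard state, Kd = exp(ΔG/RT), and a ligand
concentration to a fractional occupancy θ = [L]/([L]+Kd).  Also reproduces
the back-of-envelope concentration estimates relevant to anesthetic doses:
protein concentration from molecules-per-cell counts, and the
ligand-to-protein molecule ratio.

Default temperature is physiological (310 K).  Clinically, 1–2 MAC
(minimum alveolar concentration) of halothane corresponds to roughly
250–500 µM in tissue; that mapping is a quoted constant, not a computed
one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

GAS_CONSTANT_KCAL = 1.987e-3  # kcal/(mol·K)
AVOGADRO = 6.022e23  # 1/mol
BODY_TEMPERATURE_K = 310.0
MAC_CONCENTRATION_M = {1: 250e-6, 2: 500e-6}  # halothane, ~1 and ~2 MAC


@dataclass
class OccupancyModel:
    """ΔG → Kd → occupancy summary at one ligand concentration."""

    delta_g: float  # kcal/mol, negative = favorable
    temperature: float  # K
    kd: float  # molar
    ligand_conc: float  # molar
    occupancy: float  # fraction in [0, 1)

    @classmethod
    def from_energy(cls, delta_g: float, ligand_conc: float,
                    temperature: float = BODY_TEMPERATURE_K) -> "OccupancyModel":
        kd = kd_from_energy(delta_g, temperature)
        return cls(delta_g=delta_g, temperature=temperature, kd=kd,
                   ligand_conc=ligand_conc, occupancy=occupancy(ligand_conc, kd))


def kd_from_energy(delta_g: float, temperature: float = BODY_TEMPERATURE_K) -> float:
    """Dissociation constant (molar) from binding free energy.

    Kd = exp(ΔG/RT) · 1 M; ΔG = 0 gives the 1 M standard state."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    exponent = delta_g / (GAS_CONSTANT_KCAL * temperature)
    return math.exp(exponent) if exponent < 700 else math.inf


def energy_from_kd(kd: float, temperature: float = BODY_TEMPERATURE_K) -> float:
    """Inverse of :func:`kd_from_energy` (kcal/mol)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd)


def occupancy(ligand_conc: float, kd: float) -> float:
    """Equilibrium fractional occupancy θ = [L]/([L] + Kd)."""
    if ligand_conc < 0 or kd <= 0:
        raise ValueError("ligand_conc must be >= 0 and kd > 0")
    return ligand_conc / (ligand_conc + kd)


def brain_concentration(molecules_per_cell: float, n_cells: float,
                        volume_l: float) -> float:
    """Average molar concentration of a protein in a tissue volume."""
    if molecules_per_cell <= 0 or n_cells <= 0 or volume_l <= 0:
        raise ValueError("all arguments must be positive")
    return molecules_per_cell * n_cells / (AVOGADRO * volume_l)


def molecules_per_dimer(ligand_conc: float, protein_conc: float) -> float:
    """Ligand molecules available per protein molecule (concentration ratio)."""
    if protein_conc <= 0:
        raise ValueError("protein_conc must be positive")
    return ligand_conc / protein_conc


def round_sig(value: float, n_digits: int = 2) -> float:
    """Round to ``n_digits`` significant figures (reporting helper)."""
    if value == 0 or not math.isfinite(value):
        return value
    exponent = math.floor(math.log10(abs(value)))
    return round(value, n_digits - 1 - exponent)
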