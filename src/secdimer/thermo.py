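"""Thermodynamic bookkeeping for homodimer dissociation.

Free-energy differences between dimer variants follow from their
dissociation constants:

    ddG0_diss = R T ln(K_D,variant / K_D,reference)

with the sign convention that a positive value means the variant
dissociates more easily (destabilised dimer).  The absolute
dissociation free energy against the 1 M standard state is
dG0 = -R T ln(K_D[M]).  Simple additive budgets convert per-mutation
ddG values into hydrogen-bond totals, and buried apolar surface into an
empirical hydrophobic stabilisation at a constant energy per A^2.

The module also speciates sodium phosphate buffer (Henderson-
Hasselbalch at pKa2) to express buffer strength as molar ionic
strength I = 1/2 sum(c_i z_i^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "R_GAS",
    "MutantRecord",
    "BufferSpec",
    "ddg_dissociation",
    "dg_dissociation",
    "ddg_table",
    "hbond_energy_budget",
    "hydrophobic_energy",
    "phosphate_ionic_strength",
]

R_GAS = 8.314            # J/(mol K)
DEFAULT_T = 278.15       # K; cold-room SEC temperature (5 C)


@dataclass(frozen=True)
class MutantRecord:
    """One dimer variant: its K_D and derived destabilisation energy.

    ``kd_mM`` is ``None`` when the variant never populates the dimer over
    the accessible concentration range (K_D not determinable); ``ddg``
    is then a lower bound, carried separately by `ddg_table`.
    """

    name: str
    kd_mM: float | None
    ddg: float | None = None        # kJ/mol vs the reference
    hbond_mutant: bool = False      # mutation removes an interface H-bond

    def __post_init__(self) -> None:
        if self.kd_mM is not None and self.kd_mM <= 0:
            raise ValueError("kd_mM must be positive when determinable")


@dataclass
class BufferSpec:
    """Sodium phosphate buffer composition."""

    phosphate_total: float     # M
    pH: float
    pKa2: float = 7.20         # H2PO4- / HPO4^2- at 25 C, I -> 0

    def __post_init__(self) -> None:
        if self.phosphate_total < 0:
            raise ValueError("phosphate_total must be non-negative")
        if not 0.0 < self.pH < 14.0:
            raise ValueError("pH must lie in (0, 14)")

    @property
    def ionic_strength(self) -> float:
        return phosphate_ionic_strength(self)


def ddg_dissociation(kd_variant: float, kd_reference: float,
                     T: float = DEFAULT_T) -> float:
    """R T ln(K_D,variant / K_D,reference) in kJ/mol.

    Positive when the variant's dimer is weaker than the reference's.
    K_D units cancel but must match.
    """
    if kd_variant <= 0 or kd_reference <= 0:
        raise ValueError("dissociation constants must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return R_GAS * T * math.log(kd_variant / kd_reference) / 1000.0


def dg_dissociation(kd: float, T: float = DEFAULT_T) -> float:
    """Standard dissociation free energy -R T ln(K_D) in kJ/mol; K_D in M."""
    if kd <= 0:
        raise ValueError("K_D must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return -R_GAS * T * math.log(kd) / 1000.0


def ddg_table(kd_mM_by_name: dict[str, float | None], reference: str,
              T: float = DEFAULT_T) -> pd.DataFrame:
    """Per-variant ddG0_diss against ``reference``, as a tidy table.

    Variants with ``None`` K_D (never dimerise at accessible
    concentrations) get NaN with lower bounds instead: K_D greater than
    the largest determinable K_D in the table, ddG greater than the
    corresponding energy.
    """
    if reference not in kd_mM_by_name:
        raise KeyError(f"reference {reference!r} not in table")
    kd_ref = kd_mM_by_name[reference]
    if kd_ref is None or kd_ref <= 0:
        raise ValueError("reference K_D must be a positive number")
    determinable = [v for v in kd_mM_by_name.values() if v is not None]
    kd_floor = max(determinable)
    rows = []
    for name, kd in kd_mM_by_name.items():
        if kd is None:
            rows.append({"name": name, "kd_mM": np.nan, "ddg_kJ_mol": np.nan,
                         "kd_mM_lower_bound": kd_floor,
                         "ddg_lower_bound": ddg_dissociation(kd_floor, kd_ref, T)})
        else:
            rows.append({"name": name, "kd_mM": kd,
                         "ddg_kJ_mol": ddg_dissociation(kd, kd_ref, T),
                         "kd_mM_lower_bound": np.nan, "ddg_lower_bound": np.nan})
    return pd.DataFrame(rows).set_index("name")


def hbond_energy_budget(records: list[tuple[float, int]]) -> float:
    """Total energy of a set of interactions: sum of multiplicity * ddG.

    ``records`` holds ``(ddg_kJ_mol, multiplicity)`` pairs — e.g. one
    mutation probing a bond that occurs twice in a C2 dimer enters with
    multiplicity 2.
    """
    total = 0.0
    for ddg, mult in records:
        if mult < 1:
            raise ValueError("multiplicity must be >= 1")
        total += mult * ddg
    return total


def hydrophobic_energy(buried_apolar_area: float, gamma: float = 54.4) -> float:
    """Empirical hydrophobic stabilisation, gamma * area, in kJ/mol.

    ``gamma`` is in J/mol per A^2 of buried apolar surface (default
    54.4, the consensus protein-interface transfer coefficient).
    """
    if buried_apolar_area < 0:
        raise ValueError("buried area must be non-negative")
    return gamma * buried_apolar_area / 1000.0


def phosphate_ionic_strength(buffer: BufferSpec) -> float:
    """Molar ionic strength of a sodium phosphate buffer.

    Speciation between H2PO4- (z=-1) and HPO4^2- (z=-2) follows
    Henderson-Hasselbalch at ``pKa2``; Na+ is set by electroneutrality;
    then I = 1/2 sum(c_i z_i^2).  PO4^3- and H3PO4 are negligible in the
    pH 5-9 working range and are ignored.
    """
    c = buffer.phosphate_total
    if c == 0:
        return 0.0
    frac_hpo4 = 1.0 / (1.0 + 10.0 ** (buffer.pKa2 - buffer.pH))
    c2 = c * frac_hpo4          # HPO4^2-
    c1 = c - c2                 # H2PO4-
    na = c1 + 2.0 * c2
    return 0.5 * (na * 1 + c1 * 1 + c2 * 4)
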