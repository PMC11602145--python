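"""Physical constants and unit conversions.

Internal unit convention: forces in pN, lengths in nm, energies in kcal/mol.
The single conversion factor between the two energy scales is
1 kcal/mol = 6.9477 pN nm; every derived constant is recomputed from
``k_B`` and ``T`` so the thermal energy is never hard-coded twice.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant, kcal/(mol K)
KB_KCAL_MOL_K = 0.0019872

#: 1 kcal/mol expressed in pN nm (per molecule)
KCAL_PER_MOL_TO_PN_NM = 6.9477

#: Default experimental temperature (25 C)
DEFAULT_T_K = 298.15


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermal-energy bookkeeping at a fixed temperature.

    Parameters
    ----------
    T : float
        Absolute temperature in kelvin.
    k_B : float
        Boltzmann constant in kcal/(mol K).
    """

    T: float = DEFAULT_T_K
    k_B: float = KB_KCAL_MOL_K

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T} K")

    @property
    def kT_kcal_mol(self) -> float:
        """Thermal energy k_B T in kcal/mol."""
        return self.k_B * self.T

    @property
    def kT_pN_nm(self) -> float:
        """Thermal energy k_B T in pN nm."""
        return self.kT_kcal_mol * KCAL_PER_MOL_TO_PN_NM

    @property
    def beta_kcal_mol(self) -> float:
        """Inverse thermal energy 1/(k_B T) in mol/kcal."""
        return 1.0 / self.kT_kcal_mol

    @property
    def beta_pN_nm(self) -> float:
        """Inverse thermal energy 1/(k_B T) in 1/(pN nm)."""
        return 1.0 / self.kT_pN_nm


DEFAULT_CONSTANTS = PhysicalConstants()


def monovalent_equivalent(concentration_M: float, cation: str = "Na") -> float:
    """Map a salt concentration to its monovalent (NaCl) equivalent.

    Magnesium screens roughly 100x more efficiently than sodium at the
    concentrations relevant here (the "1:100 rule"), so 10 mM MgCl2 is
    treated as 1 M NaCl.
    """
    cation = cation.strip().lower()
    if cation in ("na", "nacl", "k", "kcl", "monovalent"):
        return concentration_M
    if cation in ("mg", "mgcl2", "divalent"):
        return 100.0 * concentration_M
    raise ValueError(f"unknown cation {cation!r}; use 'Na' or 'Mg'")
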