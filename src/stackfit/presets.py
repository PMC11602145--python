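"""Published parameter sets for the stacking model and the salt laws.

These are the fitted values for the polymeric sequences studied with this
model (poly-dA, poly-dGdA in ssDNA; poly-rA, poly-rC in ssRNA), expressed in
the package's unit convention (kcal/mol, nm, M).  Energy parameters follow a
logarithmic salt law theta(C) = theta0 + m * ln(C) with the intercept at
C = 1 M monovalent; the stacked persistence length follows a Debye law
p_S(C) = p_inf + m_p / sqrt(C).  The 1:100 rule maps 10 mM MgCl2 onto the
1 M NaCl reference condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elasticity import StackedElasticParams, UnstackedElasticParams
from .gamma2 import Gamma2Params
from .stmodel import StackingParams

__all__ = [
    "SaltLaw",
    "TC_UNSTACKED",
    "POLY_DA",
    "POLY_DGDA",
    "POLY_RA",
    "POLY_RC",
    "POLY_DA_SALT_LAWS",
    "MIXED_MOTIF_28B",
    "MIXED_MOTIF_TRACKS",
    "stacking_at_salt",
    "gamma2_at_salt",
    "stacked_params_at_salt",
]


@dataclass(frozen=True)
class SaltLaw:
    """theta(C): logarithmic (theta0 + m ln C) or Debye (theta_inf + m/sqrt C)."""

    intercept: float
    slope: float
    form: str = "logarithmic"  # or "inverse-sqrt"

    def __post_init__(self) -> None:
        if self.form not in ("logarithmic", "inverse-sqrt"):
            raise ValueError(f"unknown salt-law form {self.form!r}")

    def __call__(self, C: float) -> float:
        if C <= 0:
            raise ValueError(f"salt concentration must be positive, got {C} M")
        if self.form == "logarithmic":
            return self.intercept + self.slope * np.log(C)
        return self.intercept + self.slope / np.sqrt(C)


#: TC elasticity of unstacked ssDNA (salt dependence through Delta(C))
TC_UNSTACKED = UnstackedElasticParams(
    l_U=0.652, a=0.65, delta0=0.40, delta_slope=0.0109, C=1.0
)

#: poly-dA at the 10 mM MgCl2 (== 1 M NaCl equivalent) reference condition
POLY_DA = StackingParams(eps_ST=0.14, gamma_ST=0.86)
#: alternating dG/dA at the same reference condition
POLY_DGDA = StackingParams(eps_ST=0.02, gamma_ST=0.67)
#: ssRNA homopolymers (N = infinity analysis)
POLY_RA = StackingParams(eps_ST=0.18, gamma_ST=0.5)
POLY_RC = StackingParams(eps_ST=0.13, gamma_ST=0.4)

#: stacked-state WLC at the reference condition (poly-dA combined fit)
STACKED_WLC = StackedElasticParams(l_S=0.386, p_inf=9.9, m_p=0.0, C=1.0)

#: staged ("procedure I") salt laws for poly-dA, intercepts anchored at 1 M
POLY_DA_SALT_LAWS = {
    "eps_ST": SaltLaw(0.14, 0.004),
    "gamma_ST": SaltLaw(0.86, 0.05),
    "gamma2": SaltLaw(0.5, 0.08),
    "p_S": SaltLaw(9.9, 0.3, form="inverse-sqrt"),
}

#: repetitive 28-base motif of the mixed (purine/pyrimidine) sequence
MIXED_MOTIF_28B = "AAGAGTATGGAAAGTAAAAGAAATAAAG"
#: published grouping into three poly-purine regions of 9, 6 and 8 bases
#: (the leading 5-base and trailing 4-base runs join across the periodic
#: repeat into a single 9-base track)
MIXED_MOTIF_TRACKS = [(0, 5), (8, 6), (15, 8), (24, 4)]


def stacking_at_salt(C: float, laws: dict[str, SaltLaw] | None = None,
                     T: float = 298.15) -> StackingParams:
    """Stacking parameters at monovalent-equivalent concentration C (M)."""
    laws = laws or POLY_DA_SALT_LAWS
    return StackingParams(eps_ST=laws["eps_ST"](C), gamma_ST=laws["gamma_ST"](C), T=T)


def gamma2_at_salt(C: float, laws: dict[str, SaltLaw] | None = None,
                   T: float = 298.15) -> Gamma2Params:
    laws = laws or POLY_DA_SALT_LAWS
    return Gamma2Params(stacking=stacking_at_salt(C, laws, T), gamma2=laws["gamma2"](C))


def stacked_params_at_salt(C: float, laws: dict[str, SaltLaw] | None = None) -> StackedElasticParams:
    laws = laws or POLY_DA_SALT_LAWS
    law = laws["p_S"]
    return StackedElasticParams(l_S=0.386, p_inf=law.intercept, m_p=law.slope, C=C)
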