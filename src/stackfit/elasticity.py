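"""Polymer elasticity of single-stranded and short double-stranded nucleic acids.

Four elastic elements are provided:

* **Unstacked ssDNA** — Thick-Chain (TC) model: a necklace of disks of
  spacing ``a`` and salt-dependent effective radius ``Delta(C)``, which fixes
  the persistence length ``p_U = -a / ln(1 - a^2/(4 Delta^2))``.  The
  force-extension relation is exposed through a pluggable *dialect*; the
  default (``"fjc-kuhn"``) is a discrete freely-jointed chain with contour
  length ``l_U`` per base and Kuhn length ``b = 2 p_U``, which reproduces the
  TC persistence length by construction.
* **Stacked ssDNA** — inextensible worm-like chain (WLC), inverted
  Marko-Siggia interpolation (default dialect), with an optional
  seventh-order-corrected dialect.
* **Oriented hairpin diameter** — FJC with a single 2 nm monomer.
* **Short dsDNA segments** (handles) — inextensible WLC with p = 50 nm and a
  0.34 nm/bp rise.

All extension functions return nm per base (or per segment where stated),
take forces in pN, and are vectorized over ``f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "UnstackedElasticParams",
    "StackedElasticParams",
    "tc_persistence_length",
    "tc_extension",
    "tc_stretch_work",
    "wlc_extension",
    "wlc_stretch_work",
    "marko_siggia_force",
    "diameter_extension",
    "diameter_stretch_work",
    "dsdna_segment_extension",
    "stretch_work",
    "langevin",
]

TC_DIALECTS = ("fjc-kuhn",)
WLC_DIALECTS = ("marko-siggia", "ms7")

# Bouchiat et al. seventh-order correction coefficients for the WLC
# interpolation (terms a_2 x^2 ... a_7 x^7 added to Marko-Siggia).
_MS7_COEFFS = np.array(
    [-0.5164228, -2.737418, 16.07497, -38.87607, 39.49944, -14.17718]
)


def langevin(u):
    """Langevin function L(u) = coth(u) - 1/u, series-expanded near zero.

    The u -> 0 limit is handled by the Taylor series u/3 - u^3/45 + 2u^5/945
    to avoid the 0/0 indeterminacy.
    """
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < 1e-4
    us = u[small]
    out[small] = us / 3.0 - us**3 / 45.0 + 2.0 * us**5 / 945.0
    ub = u[~small]
    out[~small] = 1.0 / np.tanh(ub) - 1.0 / ub
    return out


def _log_sinh_over_u(u):
    """ln(sinh(u)/u), stable for both small and large u."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < 1e-4
    us = u[small]
    out[small] = us**2 / 6.0 - us**4 / 180.0
    ub = u[~small]
    # sinh(u)/u = e^u (1 - e^{-2u}) / (2u)
    out[~small] = ub + np.log1p(-np.exp(-2.0 * ub)) - np.log(2.0 * ub)
    return out


def tc_persistence_length(a: float, delta: float) -> float:
    """Persistence length of the Thick-Chain model, nm.

    ``p_U = -a / ln(1 - a^2 / (4 Delta^2))``; requires ``2 Delta > a`` so the
    logarithm argument is positive.
    """
    if a <= 0:
        raise ValueError(f"disk spacing a must be positive, got {a}")
    arg = 1.0 - a * a / (4.0 * delta * delta)
    if arg <= 0:
        raise ValueError(
            f"TC persistence length undefined: need 2*Delta > a, got a={a}, delta={delta}"
        )
    return -a / np.log(arg)


@dataclass(frozen=True)
class UnstackedElasticParams:
    """Thick-Chain parameters for unstacked ssDNA.

    Attributes
    ----------
    l_U : float
        Contour length per base, nm.
    a : float
        Disk spacing, nm.
    delta0 : float
        Salt-independent part of the effective disk radius, nm.
    delta_slope : float
        Debye coefficient of the radius, nm M^(1/2):
        ``Delta(C) = delta0 + delta_slope / sqrt(C)``.
    C : float
        Monovalent-equivalent salt concentration, M.
    dialect : str
        Force-extension dialect name.
    """

    l_U: float = 0.652
    a: float = 0.65
    delta0: float = 0.40
    delta_slope: float = 0.0109
    C: float = 1.0
    dialect: str = "fjc-kuhn"

    def __post_init__(self) -> None:
        if self.l_U <= 0 or self.a <= 0:
            raise ValueError("l_U and a must be positive")
        if self.C <= 0:
            raise ValueError(f"salt concentration must be positive, got {self.C} M")
        if self.dialect not in TC_DIALECTS:
            raise ValueError(f"unknown TC dialect {self.dialect!r}; known: {TC_DIALECTS}")
        if 2.0 * self.delta <= self.a:
            raise ValueError(
                f"Delta(C)={self.delta:.4f} nm must exceed a/2={self.a / 2:.4f} nm"
            )

    @property
    def delta(self) -> float:
        """Effective disk radius Delta(C) = delta0 + delta_slope/sqrt(C), nm."""
        return self.delta0 + self.delta_slope / np.sqrt(self.C)

    @property
    def p_U(self) -> float:
        """TC persistence length at this salt, nm."""
        return tc_persistence_length(self.a, self.delta)

    def at_salt(self, C: float) -> "UnstackedElasticParams":
        return replace(self, C=C)


@dataclass(frozen=True)
class StackedElasticParams:
    """WLC parameters for stacked ssDNA.

    ``p_S(C) = p_inf + m_p / sqrt(C)`` (Debye-like salt dependence);
    ``l_S`` is salt independent.
    """

    l_S: float = 0.386
    p_inf: float = 9.9
    m_p: float = 0.0
    C: float = 1.0
    dialect: str = "marko-siggia"

    def __post_init__(self) -> None:
        if self.l_S <= 0:
            raise ValueError("l_S must be positive")
        if self.C <= 0:
            raise ValueError(f"salt concentration must be positive, got {self.C} M")
        if self.dialect not in WLC_DIALECTS:
            raise ValueError(f"unknown WLC dialect {self.dialect!r}; known: {WLC_DIALECTS}")
        if self.p_S <= 0:
            raise ValueError(f"p_S(C)={self.p_S:.4f} nm must be positive")

    @property
    def p_S(self) -> float:
        """Persistence length at this salt, nm."""
        return self.p_inf + self.m_p / np.sqrt(self.C)

    def at_salt(self, C: float) -> "StackedElasticParams":
        return replace(self, C=C)


def _check_force(f):
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be nonnegative")
    return f


def tc_extension(params: UnstackedElasticParams, f, const: PhysicalConstants = DEFAULT_CONSTANTS):
    """Extension per unstacked base x_U(f), nm.

    Default dialect: discrete FJC with Kuhn length b = 2 p_U(a, Delta),
    x_U(f) = l_U * L(f b / kT).
    """
    f = _check_force(f)
    b = 2.0 * params.p_U
    u = f * b / const.kT_pN_nm
    return params.l_U * langevin(u)


def tc_stretch_work(params: UnstackedElasticParams, f, const: PhysicalConstants = DEFAULT_CONSTANTS):
    """Stretching work per unstacked base W_U(f) = int_0^f x_U df', pN nm.

    Closed form for the FJC dialect: W = l_U (kT/b) ln(sinh(u)/u).
    """
    f = _check_force(f)
    kT = const.kT_pN_nm
    b = 2.0 * params.p_U
    u = f * b / kT
    return params.l_U * (kT / b) * _log_sinh_over_u(u)


def marko_siggia_force(xhat, p: float, const: PhysicalConstants = DEFAULT_CONSTANTS, dialect: str = "marko-siggia"):
    """WLC interpolation force f(x/l) in pN for fractional extension xhat."""
    xhat = np.asarray(xhat, dtype=float)
    kT = const.kT_pN_nm
    base = xhat - 0.25 + 0.25 / (1.0 - xhat) ** 2
    if dialect == "ms7":
        corr = np.zeros_like(xhat)
        for i, c in enumerate(_MS7_COEFFS, start=2):
            corr = corr + c * xhat**i
        base = base + corr
    elif dialect != "marko-siggia":
        raise ValueError(f"unknown WLC dialect {dialect!r}")
    return (kT / p) * base


def _ms_force_deriv(xhat, p, kT, dialect):
    d = 1.0 + 0.5 / (1.0 - xhat) ** 3
    if dialect == "ms7":
        for i, c in enumerate(_MS7_COEFFS, start=2):
            d = d + i * c * xhat ** (i - 1)
    return (kT / p) * d


def _invert_wlc(f, p, const, dialect, rtol=1e-12, max_iter=100):
    """Invert the WLC interpolation: fractional extension xhat(f).

    Safeguarded Newton iteration with a bisection fallback; the residual
    |f(xhat) - f|/f is driven below ``rtol``.
    """
    f = np.asarray(f, dtype=float)
    kT = const.kT_pN_nm
    lo = np.zeros_like(f)
    hi = np.full_like(f, 1.0 - 1e-14)
    # high-force asymptote as the starting guess, clipped into (0, 1)
    with np.errstate(divide="ignore"):
        x = np.where(f > 0, 1.0 - 0.5 * np.sqrt(kT / (p * np.maximum(f, 1e-300))), 0.0)
    x = np.clip(x, 1e-12, 1.0 - 1e-12)
    for _ in range(max_iter):
        g = marko_siggia_force(x, p, const, dialect) - f
        hi = np.where(g > 0, np.minimum(hi, x), hi)
        lo = np.where(g < 0, np.maximum(lo, x), lo)
        step = g / _ms_force_deriv(x, p, kT, dialect)
        x_new = x - step
        bad = (x_new <= lo) | (x_new >= hi) | ~np.isfinite(x_new)
        x_new = np.where(bad, 0.5 * (lo + hi), x_new)
        converged = np.abs(g) <= rtol * np.maximum(f, 1e-30)
        if np.all(converged | (hi - lo < 1e-16)):
            x = np.where(converged, x, x_new)
            break
        x = x_new
    else:
        resid = np.max(np.abs(marko_siggia_force(x, p, const, dialect) - f))
        raise RuntimeError(
            f"WLC inversion did not converge: max residual {resid:.3e} pN "
            f"(p={p} nm, dialect={dialect})"
        )
    return np.where(f == 0, 0.0, x)


def wlc_extension(params: StackedElasticParams, f, const: PhysicalConstants = DEFAULT_CONSTANTS):
    """Extension per stacked base x_S(f), nm, by inverting the WLC interpolation."""
    f = _check_force(f)
    return params.l_S * _invert_wlc(f, params.p_S, const, params.dialect)


def _wlc_energy_per_contour(xhat, p, kT, dialect):
    """int_0^xhat f dxhat' (energy per unit contour length / l), pN."""
    e = 0.5 * xhat**2 - 0.25 * xhat + 0.25 / (1.0 - xhat) - 0.25
    if dialect == "ms7":
        for i, c in enumerate(_MS7_COEFFS, start=2):
            e = e + c * xhat ** (i + 1) / (i + 1)
    return (kT / p) * e


def wlc_stretch_work(params: StackedElasticParams, f, const: PhysicalConstants = DEFAULT_CONSTANTS):
    """Stretching work per stacked base W_S(f) = int_0^f x_S df', pN nm.

    Uses the Legendre transform W(f) = f x(f) - E(x(f)) with the analytic
    WLC energy E(x) = int_0^x f dx', so no quadrature is needed.
    """
    f = _check_force(f)
    kT = const.kT_pN_nm
    xhat = _invert_wlc(f, params.p_S, const, params.dialect)
    return params.l_S * (
        f * xhat - _wlc_energy_per_contour(xhat, params.p_S, kT, params.dialect)
    )


def diameter_extension(f, const: PhysicalConstants = DEFAULT_CONSTANTS, d: float = 2.0):
    """Oriented hairpin diameter x_d(f): FJC with a single monomer of 2 nm."""
    f = _check_force(f)
    u = f * d / const.kT_pN_nm
    return d * langevin(u)


def diameter_stretch_work(f, const: PhysicalConstants = DEFAULT_CONSTANTS, d: float = 2.0):
    """int_0^f x_d df' = kT ln(sinh(u)/u), pN nm."""
    f = _check_force(f)
    u = f * d / const.kT_pN_nm
    return const.kT_pN_nm * _log_sinh_over_u(u)


def dsdna_segment_extension(
    n_bp: int,
    f,
    const: PhysicalConstants = DEFAULT_CONSTANTS,
    p_nm: float = 50.0,
    rise_nm_per_bp: float = 0.34,
):
    """Extension of a short dsDNA segment, nm: inextensible WLC, p = 50 nm."""
    if n_bp < 0:
        raise ValueError("n_bp must be nonnegative")
    f = _check_force(f)
    if n_bp == 0:
        return np.zeros_like(f)
    contour = n_bp * rise_nm_per_bp
    return contour * _invert_wlc(f, p_nm, const, "marko-siggia")


def stretch_work(x_of_f, f: float, const: PhysicalConstants | None = None) -> float:
    """Generic stretching work W(f) = int_0^f x(f') df' by adaptive quadrature.

    ``x_of_f`` is any callable mapping force (pN) to extension (nm); the
    result is in pN nm.  The closed-form variants above should be preferred
    where they apply; this is the fallback for arbitrary dialects.
    """
    if f < 0:
        raise ValueError("force must be nonnegative")
    if f == 0:
        return 0.0
    val, err = quad(lambda ff: float(np.asarray(x_of_f(ff))), 0.0, f, epsrel=1e-10, limit=200)
    if not np.isfinite(val):
        raise RuntimeError(f"stretch-work quadrature failed at f={f} pN (err={err})")
    return val
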