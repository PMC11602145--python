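"""Helix-coil stacking model of ssDNA under force (two-state Ising chain).

Each of the N stackable bases is a spin: sigma = +1 stacked (S, short and
stiff, WLC elasticity), sigma = -1 unstacked (U, long and flexible, TC
elasticity).  The energy of a configuration at force f is

    E = -N_S [eps_ST + W_S(f)] - N_U W_U(f) - gamma_ST sum_{i=0..N} s_i s_{i+1}

with W_S, W_U the stretching work per base (integral of extension over
force) and fixed unstacked virtual sites s_0 = s_{N+1} = -1 at both ends,
so both boundary bonds contribute for every configuration.

The finite chain is solved exactly by a 2x2 transfer matrix with per-step
rescaling (stable to N ~ 1e5); the N -> infinity limit has closed forms for
the free energy per base, the stacked fraction, the zero-force stacking
free energy DG0 and the correlation length xi_ST(f), which peaks at the
stacking-unstacking transition force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_CONSTANTS, KCAL_PER_MOL_TO_PN_NM, PhysicalConstants
from .curves import ForceExtensionCurve
from .elasticity import (
    StackedElasticParams,
    UnstackedElasticParams,
    tc_extension,
    tc_stretch_work,
    wlc_extension,
    wlc_stretch_work,
)

__all__ = [
    "StackingParams",
    "ChainSpec",
    "ThermoResult",
    "free_energy_finite",
    "fec_finite",
    "stacked_fraction",
    "fec_infinite",
    "delta_g0",
    "correlation_length",
    "xi_max",
    "f_max",
    "enumerate_oracle",
]

_ENUM_MAX_N = 16


@dataclass(frozen=True)
class StackingParams:
    """Ising energy scales of the stacking model.

    eps_ST : stacking energy gain per base, kcal/mol (>= 0 in all fits here,
    but any real value is accepted).  gamma_ST : cooperativity penalty of an
    S/U domain wall, kcal/mol, must be >= 0 (ferromagnetic).  T : kelvin.
    """

    eps_ST: float
    gamma_ST: float
    T: float = DEFAULT_CONSTANTS.T

    def __post_init__(self) -> None:
        if self.gamma_ST < 0:
            raise ValueError(f"gamma_ST must be >= 0, got {self.gamma_ST}")

    @property
    def constants(self) -> PhysicalConstants:
        return PhysicalConstants(T=self.T)

    @property
    def beta_gamma(self) -> float:
        return self.gamma_ST / self.constants.kT_kcal_mol

    @property
    def beta_eps(self) -> float:
        return self.eps_ST / self.constants.kT_kcal_mol


@dataclass(frozen=True)
class ChainSpec:
    """A finite chain of N stackable bases with fixed unstacked virtual ends."""

    N: int

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")


@dataclass
class ThermoResult:
    """Equilibrium observables of one chain at one force."""

    f: float
    G_kcal_mol: float
    X_nm: float
    phi_S: float
    xi_bases: float


def _site_log_weights(sp: StackingParams, eU: UnstackedElasticParams,
                      eS: StackedElasticParams, f):
    """Log Boltzmann site weights (b_S, b_U) in kT units, vectorized over f.

    b_S = beta (eps_ST + W_S), b_U = beta W_U, with W in pN nm and eps
    converted from kcal/mol once.
    """
    const = sp.constants
    beta = const.beta_pN_nm
    eps_pn_nm = sp.eps_ST * KCAL_PER_MOL_TO_PN_NM
    bS = beta * (eps_pn_nm + wlc_stretch_work(eS, f, const))
    bU = beta * tc_stretch_work(eU, f, const)
    return np.asarray(bS, dtype=float), np.asarray(bU, dtype=float)


def _chain_stats(bS, bU, bond_g):
    """Exact finite-chain statistics by forward-backward transfer matrices.

    Parameters
    ----------
    bS, bU : arrays of shape (nf,)
        Site log-weights in kT units, per force point.
    bond_g : array of shape (N+1,)
        Coupling beta*gamma for bonds i=0..N (bond i joins sites i, i+1;
        sites 0 and N+1 are the virtual unstacked boundaries).

    Returns
    -------
    logZ : (nf,) array
    p_S : (nf, N) array of per-site stacked probabilities
    """
    bS = np.atleast_1d(np.asarray(bS, dtype=float))
    bU = np.atleast_1d(np.asarray(bU, dtype=float))
    bond_g = np.asarray(bond_g, dtype=float)
    N = bond_g.size - 1
    nf = bS.size
    # per-site log weight, state order [S, U]
    lw = np.stack([bS, bU], axis=-1)  # (nf, 2)

    # forward pass: alpha_i[s] ~ sum over s_1..s_{i-1}; rescale each step
    alphas = np.empty((N, nf, 2))
    logscale = np.zeros(nf)
    # boundary bond 0 with sigma_0 = -1: weight e^{-g s}
    v = np.exp(lw + np.array([-bond_g[0], bond_g[0]]))
    for i in range(N):
        if i > 0:
            g = bond_g[i]
            # v_new[s'] = sum_s v[s] e^{g s s'} * w[s']
            eg, emg = np.exp(g), np.exp(-g)
            vS = v[:, 0] * eg + v[:, 1] * emg
            vU = v[:, 0] * emg + v[:, 1] * eg
            v = np.stack([vS, vU], axis=-1) * np.exp(lw)
        m = np.max(v, axis=-1)
        v = v / m[:, None]
        logscale = logscale + np.log(m)
        alphas[i] = v

    # close with boundary bond N (sigma_{N+1} = -1)
    end = np.array([-bond_g[N], bond_g[N]])
    Z_res = alphas[N - 1] @ np.exp(end)
    logZ = logscale + np.log(Z_res)

    # backward pass: beta_i[s] with same per-step structure
    b = np.broadcast_to(np.exp(end), (nf, 2)).copy()
    p_S = np.empty((nf, N))
    for i in range(N - 1, -1, -1):
        num = alphas[i] * b
        p_S[:, i] = num[:, 0] / num.sum(axis=-1)
        if i > 0:
            g = bond_g[i]
            eg, emg = np.exp(g), np.exp(-g)
            wb = np.exp(lw) * b
            bSn = wb[:, 0] * eg + wb[:, 1] * emg
            bUn = wb[:, 0] * emg + wb[:, 1] * eg
            b = np.stack([bSn, bUn], axis=-1)
            m = np.max(b, axis=-1)
            b = b / m[:, None]
    return logZ, p_S


def _finite_logZ_meanNS(chain: ChainSpec, sp: StackingParams,
                        eU: UnstackedElasticParams, eS: StackedElasticParams, f):
    f = np.atleast_1d(np.asarray(f, dtype=float))
    bS, bU = _site_log_weights(sp, eU, eS, f)
    bond_g = np.full(chain.N + 1, sp.beta_gamma)
    logZ, p_S = _chain_stats(bS, bU, bond_g)
    return logZ, p_S.sum(axis=-1)


def free_energy_finite(chain: ChainSpec, sp: StackingParams,
                       eU: UnstackedElasticParams, eS: StackedElasticParams, f):
    """Free energy G(f) = -kT ln Z of the finite chain, kcal/mol.

    Vectorized over f; stable for N up to ~1e5 via per-step rescaling.
    """
    scalar = np.isscalar(f) or np.ndim(f) == 0
    logZ, _ = _finite_logZ_meanNS(chain, sp, eU, eS, f)
    G = -sp.constants.kT_kcal_mol * logZ
    return float(G[0]) if scalar else G


def fec_finite(chain: ChainSpec, sp: StackingParams, eU: UnstackedElasticParams,
               eS: StackedElasticParams, f_grid, per_base: bool = False) -> ForceExtensionCurve:
    """Force-extension curve X(f) = <N_S> x_S + <N_U> x_U of the finite chain.

    The extension is the exact transfer-matrix expectation, equal to
    -dG/df by the thermodynamic identity.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any(np.diff(f_grid) <= 0) or np.any(f_grid < 0):
        raise ValueError("f_grid must be nonnegative and strictly increasing")
    const = sp.constants
    _, mean_NS = _finite_logZ_meanNS(chain, sp, eU, eS, f_grid)
    xS = wlc_extension(eS, f_grid, const)
    xU = tc_extension(eU, f_grid, const)
    X = mean_NS * xS + (chain.N - mean_NS) * xU
    if per_base:
        X = X / chain.N
    return ForceExtensionCurve(
        f=f_grid, x=X, per_base=per_base, N=chain.N, N_loop=chain.N,
        salt_M=eU.C,
        meta={
            "model": "st-finite", "eps_ST": sp.eps_ST, "gamma_ST": sp.gamma_ST,
            "phi_S": mean_NS / chain.N,
            "tc_dialect": eU.dialect, "wlc_dialect": eS.dialect,
        },
    )


def stacked_fraction(chain: ChainSpec, sp: StackingParams, eU: UnstackedElasticParams,
                     eS: StackedElasticParams, f):
    """Mean fraction of stacked bases phi_S = <N_S>/N at force f."""
    scalar = np.isscalar(f) or np.ndim(f) == 0
    _, mean_NS = _finite_logZ_meanNS(chain, sp, eU, eS, f)
    phi = mean_NS / chain.N
    return float(phi[0]) if scalar else phi


def _field_A(sp: StackingParams, eU: UnstackedElasticParams,
             eS: StackedElasticParams, f):
    """Effective Ising field A(f) = eps/2 - (W_U - W_S)/2, kcal/mol."""
    const = sp.constants
    dW = (tc_stretch_work(eU, f, const) - wlc_stretch_work(eS, f, const)) / KCAL_PER_MOL_TO_PN_NM
    return sp.eps_ST / 2.0 - dW / 2.0


def fec_infinite(sp: StackingParams, eU: UnstackedElasticParams,
                 eS: StackedElasticParams, f_grid) -> ForceExtensionCurve:
    """Per-base FEC in the thermodynamic limit from the leading eigenvalue.

    x_b = phi_S x_S + (1 - phi_S) x_U with the bulk magnetization
    m = sinh(beta A)/sqrt(e^{-4 beta gamma} + sinh^2(beta A)), phi_S = (1+m)/2.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any(np.diff(f_grid) <= 0) or np.any(f_grid < 0):
        raise ValueError("f_grid must be nonnegative and strictly increasing")
    const = sp.constants
    beta = const.beta_kcal_mol
    A = _field_A(sp, eU, eS, f_grid)
    sh = np.sinh(beta * A)
    m = sh / np.sqrt(np.exp(-4.0 * sp.beta_gamma) + sh**2)
    phi_S = 0.5 * (1.0 + m)
    xS = wlc_extension(eS, f_grid, const)
    xU = tc_extension(eU, f_grid, const)
    x_b = phi_S * xS + (1.0 - phi_S) * xU
    return ForceExtensionCurve(
        f=f_grid, x=x_b, per_base=True, N=None, salt_M=eU.C,
        meta={
            "model": "st-infinite", "eps_ST": sp.eps_ST, "gamma_ST": sp.gamma_ST,
            "phi_S": phi_S, "tc_dialect": eU.dialect, "wlc_dialect": eS.dialect,
        },
    )


def delta_g0(sp: StackingParams) -> float:
    """Zero-force stacking free energy per base, kcal/mol (N = infinity).

    Free-energy difference between the relaxed chain at f = 0 and the fully
    unstacked reference:

        DG0 = eps/2 + kT ln[ cosh(beta eps/2)
                             + sqrt(e^{-4 beta gamma} + sinh^2(beta eps/2)) ]

    DG0 >= eps/2 always, and DG0 -> eps as gamma -> infinity.
    """
    const = sp.constants
    beta = const.beta_kcal_mol
    h = beta * sp.eps_ST / 2.0
    root = np.sqrt(np.exp(-4.0 * sp.beta_gamma) + np.sinh(h) ** 2)
    return sp.eps_ST / 2.0 + const.kT_kcal_mol * np.log(np.cosh(h) + root)


def correlation_length(sp: StackingParams, eU: UnstackedElasticParams,
                       eS: StackedElasticParams, f):
    """Stacking correlation length xi_ST(f) in bases (N = infinity).

    xi = -1/ln(lambda_2/lambda_1) of the transfer matrix:

        xi = -1 / ln[ (cosh(bA) - sqrt(e^{-4bg} + sinh^2(bA)))
                    / (cosh(bA) + sqrt(e^{-4bg} + sinh^2(bA))) ]

    with A(f) = eps/2 - (1/2) int_0^f (x_U - x_S) df'.  xi has a single
    maximum at the transition force and drops to zero at high force;
    gamma = 0 gives xi = 0 identically (the eigenvalue ratio vanishes).
    """
    scalar = np.isscalar(f) or np.ndim(f) == 0
    f = np.atleast_1d(np.asarray(f, dtype=float))
    if sp.gamma_ST == 0:
        out = np.zeros_like(f)
        return float(out[0]) if scalar else out
    beta = sp.constants.beta_kcal_mol
    A = _field_A(sp, eU, eS, f)
    ch = np.cosh(beta * A)
    root = np.sqrt(np.exp(-4.0 * sp.beta_gamma) + np.sinh(beta * A) ** 2)
    ratio = (ch - root) / (ch + root)
    xi = np.where(ratio > 0, -1.0 / np.log(np.clip(ratio, 1e-300, None)), 0.0)
    return float(xi[0]) if scalar else xi


def xi_max(sp: StackingParams) -> float:
    """Maximum of the correlation length over force, bases.

    Depends only on the cooperativity: xi_max = -1/ln(tanh(beta gamma_ST)).
    """
    if sp.gamma_ST <= 0:
        raise ValueError("xi_max requires gamma_ST > 0")
    return -1.0 / np.log(np.tanh(sp.beta_gamma))


def f_max(sp: StackingParams, eU: UnstackedElasticParams, eS: StackedElasticParams,
          f_lo: float = 0.1, f_hi: float = 60.0, scan_step: float = 0.5) -> float:
    """Force (pN) at which xi_ST peaks: the root of A(f) = 0.

    Equivalently eps_ST = int_0^f (x_U - x_S) df'.  Located by a sign-change
    scan followed by bracketed root-finding (tolerance 1e-3 pN in f).
    """
    if float(np.atleast_1d(_field_A(sp, eU, eS, 0.0))[0]) <= 0:
        # the integral condition is already met at the origin
        return 0.0
    fs = np.arange(f_lo, f_hi + scan_step, scan_step)
    A = _field_A(sp, eU, eS, fs)
    sign_change = np.nonzero(A[:-1] * A[1:] <= 0)[0]
    if sign_change.size == 0:
        raise ValueError(
            f"no stacking-unstacking transition in ({f_lo}, {f_hi}] pN: "
            f"A stays positive (eps_ST={sp.eps_ST}, gamma_ST={sp.gamma_ST})"
        )
    i = sign_change[0]
    g = lambda ff: float(np.atleast_1d(_field_A(sp, eU, eS, ff))[0])
    return brentq(g, fs[i], fs[i + 1], xtol=1e-3)


def enumerate_oracle(chain: ChainSpec, sp: StackingParams, eU: UnstackedElasticParams,
                     eS: StackedElasticParams, f: float,
                     bond_g: np.ndarray | None = None):
    """Exhaustive 2^N enumeration of the chain at one force (N <= 16).

    Independent cross-check of the transfer matrix: sums the Boltzmann
    weight of every configuration including both boundary bonds.

    Returns
    -------
    (Z_rel, mean_NS, pair_corr) where ``Z_rel`` is the partition function
    with the maximal log weight factored out and restored (log-sum-exp),
    ``pair_corr[i, j] = <s_i s_j>`` (1-based sites mapped to 0-based).
    Also returns the exact logZ for comparison via the dict in position 3.
    """
    if chain.N > _ENUM_MAX_N:
        raise ValueError(f"enumeration refused for N={chain.N} > {_ENUM_MAX_N}")
    N = chain.N
    bS, bU = _site_log_weights(sp, eU, eS, float(f))
    bS, bU = float(bS), float(bU)
    if bond_g is None:
        bond_g = np.full(N + 1, sp.beta_gamma)
    bond_g = np.asarray(bond_g, dtype=float)

    codes = np.arange(2**N, dtype=np.uint32)
    bits = ((codes[:, None] >> np.arange(N)[None, :]) & 1).astype(np.int8)
    sigma = 2 * bits - 1  # (2^N, N), +1 = stacked
    full = np.concatenate(
        [-np.ones((sigma.shape[0], 1), dtype=np.int8), sigma,
         -np.ones((sigma.shape[0], 1), dtype=np.int8)], axis=1,
    )
    n_S = bits.sum(axis=1)
    site_term = n_S * bS + (N - n_S) * bU
    bond_term = (full[:, :-1] * full[:, 1:]).astype(float) @ bond_g
    logw = site_term + bond_term
    mx = logw.max()
    w = np.exp(logw - mx)
    Z = w.sum()
    logZ = mx + np.log(Z)
    p = w / Z
    mean_NS = float(n_S @ p)
    pair_corr = (sigma.astype(float) * p[:, None]).T @ sigma.astype(float)
    return Z, mean_NS, pair_corr, {"logZ": logZ, "p_S_sites": (bits.astype(float) * p[:, None]).sum(axis=0)}
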