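"""Synthetic force-spectroscopy data with the model's statistical structure.

Generators for force-extension curves (model mean plus instrument noise),
force-distance pulling curves (folded/unfolded branches with an unfolding
rip and a refolding jump, on a Hookean trap) and exact equilibrium spin
configurations of the stacking chain.  Everything is a pure function of its
arguments and a seed, so fixtures are reproducible bit for bit.

Instrument noise defaults are 0.1 pN in force and 1 nm in extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .curves import ForceDistanceCurve, ForceExtensionCurve
from .elasticity import (
    StackedElasticParams,
    UnstackedElasticParams,
    diameter_extension,
    dsdna_segment_extension,
    tc_extension,
    wlc_extension,
)
from .stmodel import StackingParams, _chain_stats, _site_log_weights

__all__ = [
    "NoiseModel",
    "ConstructSpec",
    "gen_fec",
    "gen_fdc",
    "sample_configurations",
    "CONSTRUCTS",
]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian instrument noise: sigma_f on force, sigma_x on extension."""

    sigma_f: float = 0.1  # pN
    sigma_x: float = 1.0  # nm

    def __post_init__(self) -> None:
        if self.sigma_f < 0 or self.sigma_x < 0:
            raise ValueError("noise amplitudes must be nonnegative")


@dataclass(frozen=True)
class ConstructSpec:
    """Geometry of a hairpin construct as seen by the pulling assay.

    ``n_total`` is the number of ssDNA bases released on unfolding (stem
    strands + loop + the 15 b freed with the blocking oligo); ``n_loop`` of
    them form the (possibly stacking) loop.
    """

    name: str
    n_total: int
    n_loop: int
    loop_type: str = "dA"  # dA | dGdA | dT | mixed
    rip_force_pN: float = 40.0
    refold_force_pN: float = 4.0
    salt_M: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.n_loop <= self.n_total):
            raise ValueError("need 0 <= n_loop <= n_total")


#: the hairpin geometries used throughout: 20 bp stem + 20 b loop releases
#: 2*20 + 20 + 15 = 75 b; 15 bp stem + 40 b loop releases 2*15 + 40 + 15 = 85 b
CONSTRUCTS = {
    "H0": ConstructSpec("H0", n_total=75, n_loop=20, loop_type="dT"),
    "H20": ConstructSpec("H20", n_total=75, n_loop=20, loop_type="dA"),
    "H40": ConstructSpec("H40", n_total=85, n_loop=40, loop_type="dA"),
    "L40": ConstructSpec("L40", n_total=55, n_loop=40, loop_type="dA"),
}


def _model_X_total(construct: ConstructSpec, eU: UnstackedElasticParams,
                   eS: StackedElasticParams | None, sp: StackingParams | None,
                   f, const: PhysicalConstants):
    """Noiseless total released-ssDNA extension X(f) for a construct."""
    f = np.asarray(f, dtype=float)
    xU = tc_extension(eU, f, const)
    n_stem = construct.n_total - construct.n_loop
    if sp is None or construct.loop_type in ("dT", "dU"):
        return construct.n_total * xU
    # evaluate via the stats helper: f here need not be an increasing grid
    bS, bU = _site_log_weights(sp, eU, eS, f)
    bond_g = np.full(construct.n_loop + 1, sp.beta_gamma)
    _, p_S = _chain_stats(bS, bU, bond_g)
    mean_NS = p_S.sum(axis=-1)
    xS = wlc_extension(eS, f, const)
    X_loop = mean_NS * xS + (construct.n_loop - mean_NS) * xU
    return n_stem * xU + X_loop


def gen_fec(curve: ForceExtensionCurve, noise: NoiseModel, seed: int,
            n_cycles: int = 50) -> ForceExtensionCurve:
    """Add instrument noise to a noiseless model FEC.

    The effective per-point extension noise combines the direct extension
    noise with the force noise propagated through the local slope:
    sigma_eff^2 = (sigma_x^2 + (sigma_f dX/df)^2) / n_cycles.  The noise
    amplitudes are per raw sample; an experimental FEC point is the
    equal-force branch average over the molecule's pulling cycles, so the
    per-point noise shrinks with the number of cycles (default 50, typical
    of a pulling experiment at kHz acquisition).  For per-base curves the
    extension noise is further divided by the number of bases the
    measurement was rescaled by (curve.N_loop, or N).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    dxdf = np.gradient(curve.x, curve.f)
    n_scale = 1.0
    if curve.per_base:
        n = curve.N_loop or curve.N
        if n is None:
            raise ValueError("per-base curve needs N or N_loop to scale noise")
        n_scale = float(n)
    sigma_eff = np.sqrt(
        (noise.sigma_x / n_scale) ** 2 + (noise.sigma_f * dxdf) ** 2
    ) / np.sqrt(n_cycles)
    x = curve.x + rng.normal(0.0, 1.0, size=curve.x.shape) * sigma_eff
    return ForceExtensionCurve(
        f=curve.f.copy(), x=x, se=sigma_eff, per_base=curve.per_base,
        N=curve.N, N_loop=curve.N_loop, salt_M=curve.salt_M,
        molecule_id=curve.molecule_id,
        meta={**curve.meta, "noise": {"sigma_f": noise.sigma_f, "sigma_x": noise.sigma_x},
              "seed": seed},
    )


def gen_fdc(construct: ConstructSpec, eU: UnstackedElasticParams,
            eS: StackedElasticParams | None = None, sp: StackingParams | None = None,
            noise: NoiseModel = NoiseModel(), seed: int = 0,
            trap_stiffness_pN_nm: float = 0.08, handle_bp: int = 29,
            f_start: float = 1.0, f_stop: float = 50.0,
            n_points_per_branch: int = 400, n_cycles: int = 1,
            const: PhysicalConstants = DEFAULT_CONSTANTS) -> ForceDistanceCurve:
    """Simulate a pulling cycle lambda(f) with an unfolding rip and refold jump.

    Folded branch: two 29 bp handles + oriented hairpin diameter + bead in a
    Hookean trap.  Unfolded branch: left 29 bp handle + released ssDNA +
    shortened 14 bp right handle + bead.  At the rip the trap position is
    continuous while the force drops; the post-rip force is found by
    inverting the unfolded branch at the rip position.
    """
    rng = np.random.default_rng(seed)

    def lam_folded(f):
        f = np.asarray(f, dtype=float)
        return (2.0 * dsdna_segment_extension(handle_bp, f, const)
                + diameter_extension(f, const) + f / trap_stiffness_pN_nm)

    def lam_unfolded(f):
        f = np.asarray(f, dtype=float)
        return (dsdna_segment_extension(handle_bp, f, const)
                + _model_X_total(construct, eU, eS, sp, f, const)
                + dsdna_segment_extension(handle_bp - 15, f, const)
                + f / trap_stiffness_pN_nm)

    def _scalar(fn, ff):
        return float(np.asarray(fn(np.atleast_1d(ff))).reshape(-1)[0])

    lam_rip = _scalar(lam_folded, construct.rip_force_pN)
    f_after_rip = brentq(lambda ff: _scalar(lam_unfolded, ff) - lam_rip,
                         1e-3, construct.rip_force_pN, xtol=1e-6)
    lam_refold = _scalar(lam_unfolded, construct.refold_force_pN)
    f_after_refold = brentq(lambda ff: _scalar(lam_folded, ff) - lam_refold,
                            1e-3, f_stop, xtol=1e-6)

    lam_parts, f_parts, cyc_parts, dir_parts = [], [], [], []
    for cyc in range(n_cycles):
        segments = [
            ("pull", np.linspace(f_start, construct.rip_force_pN, n_points_per_branch), lam_folded),
            ("pull", np.linspace(f_after_rip, f_stop, n_points_per_branch), lam_unfolded),
            ("relax", np.linspace(f_stop, construct.refold_force_pN, n_points_per_branch), lam_unfolded),
            ("relax", np.linspace(f_after_refold, f_start, n_points_per_branch), lam_folded),
        ]
        for direction, f_seg, lam_fn in segments:
            lam = lam_fn(f_seg)
            f_parts.append(f_seg + rng.normal(0.0, noise.sigma_f, f_seg.shape))
            lam_parts.append(lam + rng.normal(0.0, noise.sigma_x, lam.shape))
            cyc_parts.append(np.full(f_seg.size, cyc, dtype=int))
            dir_parts.append(np.full(f_seg.size, direction, dtype=object))

    return ForceDistanceCurve(
        lam=np.concatenate(lam_parts), f=np.concatenate(f_parts),
        cycle=np.concatenate(cyc_parts), direction=np.concatenate(dir_parts),
        meta={
            "construct": construct.name, "n_total": construct.n_total,
            "n_loop": construct.n_loop, "loop_type": construct.loop_type,
            "salt_M": construct.salt_M, "seed": seed,
            "trap_stiffness_pN_nm": trap_stiffness_pN_nm,
            "rip_force_pN": construct.rip_force_pN,
            "refold_force_pN": construct.refold_force_pN,
        },
    )


def sample_configurations(N: int, sp: StackingParams, eU: UnstackedElasticParams,
                          eS: StackedElasticParams, f: float, n_samples: int,
                          seed: int) -> np.ndarray:
    """Exact equilibrium samples of the spin chain at force f.

    Forward-filter / backward-sample over the transfer matrix: draws
    ``n_samples`` independent configurations (+1 stacked / -1 unstacked)
    from the Boltzmann distribution with both fixed unstacked boundaries.
    Returns an (n_samples, N) int8 array.
    """
    if N < 1 or N > 100_000:
        raise ValueError("N out of supported range [1, 1e5]")
    rng = np.random.default_rng(seed)
    bS, bU = _site_log_weights(sp, eU, eS, float(f))
    bS, bU = float(bS), float(bU)
    g = sp.beta_gamma
    lw = np.array([bS, bU])

    # forward pass (scalar force): alpha_i[s], rescaled each step
    alphas = np.empty((N, 2))
    v = np.exp(lw + np.array([-g, g]))
    v /= v.max()
    alphas[0] = v
    for i in range(1, N):
        eg, emg = np.exp(g), np.exp(-g)
        v = np.array([v[0] * eg + v[1] * emg, v[0] * emg + v[1] * eg]) * np.exp(lw)
        v /= v.max()
        alphas[i] = v

    sigma = np.empty((n_samples, N), dtype=np.int8)
    # last site: P(s) ~ alpha_N[s] e^{-g s}
    wS = alphas[N - 1, 0] * np.exp(-g)
    wU = alphas[N - 1, 1] * np.exp(g)
    pS = wS / (wS + wU)
    sigma[:, N - 1] = np.where(rng.random(n_samples) < pS, 1, -1)
    # backward: P(s_i = S | s_{i+1}) ~ alpha_i[S] e^{g * s_{i+1}}, etc.
    for i in range(N - 2, -1, -1):
        s_next = sigma[:, i + 1].astype(float)
        wS = alphas[i, 0] * np.exp(g * s_next)
        wU = alphas[i, 1] * np.exp(-g * s_next)
        pS = wS / (wS + wU)
        sigma[:, i] = np.where(rng.random(n_samples) < pS, 1, -1)
    return sigma
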