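"""Weighted least-squares fitting of the elasticity and stacking models.

Supports the staged analysis ("procedure I": first the unstacked TC
elasticity across salts, then the stacking parameters at the reference
salt, then the logarithmic salt laws with anchored intercepts, finally the
track-boundary coupling gamma_2 on mixed sequences) and the simultaneous
global fit ("procedure II": every sequence and salt at once with the
two-coupling model).  Uncertainties come from bootstrap resampling.

Conventions: salt laws for energies use the NATURAL logarithm of the
molar concentration; Debye laws are theta_inf + m/sqrt(C).  Weights are
inverse squared standard errors where curves carry them, unit otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import lmfit
import numpy as np
from scipy.stats import qmc

from .curves import ForceExtensionCurve
from .elasticity import StackedElasticParams, UnstackedElasticParams, tc_extension
from .gamma2 import Gamma2Params, SequenceAnnotation, fec_mixed, rescale_purine_extension
from .stmodel import ChainSpec, StackingParams, fec_finite, fec_infinite

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_tc",
    "fit_st",
    "fit_salt_laws",
    "fit_gamma2",
    "fit_all_procedure2",
    "bootstrap_errors",
]


@dataclass(frozen=True)
class FitConfig:
    """Optimizer and bootstrap settings; the seed fully determines a run."""

    multistart: int = 8
    seed: int = 0
    bootstrap_n: int = 500
    bootstrap_unit: str = "points"  # or "molecules"
    max_refit_failure_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.bootstrap_unit not in ("points", "molecules"):
            raise ValueError("bootstrap_unit must be 'points' or 'molecules'")


@dataclass
class FitResult:
    """Point estimates, uncertainties and provenance for one fit."""

    params: dict[str, float]
    stderr: dict[str, float] = field(default_factory=dict)
    residual_sum_sq: float = float("nan")
    n_points: int = 0
    per_curve_rss: list[float] = field(default_factory=list)
    per_curve_autocorr: list[float] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def _weights(curve: ForceExtensionCurve) -> np.ndarray:
    if curve.se is not None and np.all(np.isfinite(curve.se)) and np.all(curve.se > 0):
        return 1.0 / curve.se
    return np.ones_like(curve.f)


def _minimize(params: lmfit.Parameters, residual: Callable, multistart: int, seed: int) -> lmfit.minimizer.MinimizerResult:
    """Trust-region least squares with Latin-hypercube multistarts."""
    best = lmfit.minimize(residual, params, method="least_squares", xtol=1e-13, ftol=1e-13, gtol=1e-13)
    free = [n for n, p in params.items() if p.vary]
    if multistart > 1 and free:
        bounded = [n for n in free
                   if np.isfinite(params[n].min) and np.isfinite(params[n].max)]
        sampler = qmc.LatinHypercube(d=max(len(bounded), 1), seed=seed)
        draws = sampler.random(multistart - 1)
        for row in draws:
            trial = params.copy()
            for j, name in enumerate(bounded):
                lo, hi = params[name].min, params[name].max
                trial[name].value = lo + row[j] * (hi - lo)
            try:
                res = lmfit.minimize(residual, trial, method="least_squares", xtol=1e-13, ftol=1e-13, gtol=1e-13)
            except Exception:
                continue
            if res.success and res.chisqr < best.chisqr:
                best = res
    if not best.success:
        raise RuntimeError(f"fit did not converge: {best.message}")
    return best


def _result_from(mini: lmfit.minimizer.MinimizerResult, residual: Callable,
                 curves: Sequence[ForceExtensionCurve], provenance: dict) -> FitResult:
    values = {n: float(p.value) for n, p in mini.params.items()}
    per_curve = []
    autocorr = []
    off = 0
    r = np.asarray(mini.residual)
    for c in curves:
        rc = r[off:off + len(c)]
        per_curve.append(float(np.sum(rc**2)))
        # lag-1 residual autocorrelation flags a mis-specified elastic model
        if rc.size > 2 and np.std(rc) > 0:
            d = rc - rc.mean()
            autocorr.append(float((d[:-1] @ d[1:]) / (d @ d)))
        else:
            autocorr.append(float("nan"))
        off += len(c)
    return FitResult(
        params=values,
        stderr={n: float(p.stderr) if p.stderr is not None else float("nan")
                for n, p in mini.params.items()},
        residual_sum_sq=float(mini.chisqr),
        n_points=int(r.size),
        per_curve_rss=per_curve,
        per_curve_autocorr=autocorr,
        provenance=provenance,
    )


# ---------------------------------------------------------------- TC fit


def fit_tc(fecs: Sequence[ForceExtensionCurve], config: FitConfig = FitConfig(),
           init: UnstackedElasticParams | None = None) -> FitResult:
    """Fit the TC unstacked elasticity across salt conditions.

    Shared l_U, a and the Debye radius law Delta(C) = delta0 +
    delta_slope/sqrt(C) are fitted simultaneously to per-base unstacked
    FECs.  With a single salt condition, a and Delta are only jointly
    identified through the persistence length, so the radius law is frozen
    at its initial values (a warning is emitted).
    """
    if not fecs:
        raise ValueError("no curves given")
    salts = sorted({c.salt_M for c in fecs})
    if any(s is None for s in salts):
        raise ValueError("every curve must carry salt_M")
    init = init or UnstackedElasticParams()
    single_salt = len(salts) < 2
    if single_salt:
        warnings.warn(
            "single salt condition: a and Delta are only jointly identified "
            "through p_U; freezing the Delta(C) law at its initial values",
            stacklevel=2,
        )
    p = lmfit.Parameters()
    p.add("l_U", value=init.l_U, min=0.3, max=1.2)
    p.add("a", value=init.a, min=0.2, max=1.2)
    p.add("delta0", value=init.delta0, min=0.1, max=1.0, vary=not single_salt)
    p.add("delta_slope", value=init.delta_slope, min=0.0, max=0.2, vary=not single_salt)

    def residual(pars):
        out = []
        for c in fecs:
            try:
                eU = UnstackedElasticParams(
                    l_U=pars["l_U"].value, a=pars["a"].value,
                    delta0=pars["delta0"].value, delta_slope=pars["delta_slope"].value,
                    C=c.salt_M,
                )
            except ValueError:
                out.append(np.full(len(c), 1e6))
                continue
            model = tc_extension(eU, c.f)
            if not c.per_base:
                model = model * (c.N if c.N else 1)
            out.append((c.x - model) * _weights(c))
        return np.concatenate(out)

    mini = _minimize(p, residual, config.multistart, config.seed)
    return _result_from(mini, residual, fecs, {
        "fit": "tc", "salts_M": salts, "dialect": init.dialect, "config": config.__dict__,
    })


# ---------------------------------------------------------------- ST fit


def _st_model_curve(curve: ForceExtensionCurve, sp: StackingParams,
                    eU: UnstackedElasticParams, eS: StackedElasticParams) -> np.ndarray:
    """Per-base model prediction matched to a data curve's length metadata."""
    n = curve.N_loop or curve.N
    if n is None:
        return fec_infinite(sp, eU, eS, curve.f).x
    return fec_finite(ChainSpec(int(n)), sp, eU, eS, curve.f, per_base=True).x


def fit_st(fecs: Sequence[ForceExtensionCurve], eU: UnstackedElasticParams,
           config: FitConfig = FitConfig(),
           init: dict[str, float] | None = None) -> FitResult:
    """Combined fit of (l_S, p_S, eps_ST, gamma_ST) to loop FECs.

    All curves share a single parameter set; each is modeled with the
    finite-chain solution at its own N (or the thermodynamic limit when N
    is unset), so finite-size differences between lengths carry the
    leverage on the cooperativity.
    """
    if not fecs:
        raise ValueError("no curves given")
    init = init or {}
    p = lmfit.Parameters()
    p.add("l_S", value=init.get("l_S", 0.38), min=0.2, max=0.6)
    p.add("p_S", value=init.get("p_S", 8.0), min=1.0, max=40.0)
    p.add("eps_ST", value=init.get("eps_ST", 0.1), min=0.0, max=0.6)
    p.add("gamma_ST", value=init.get("gamma_ST", 0.6), min=0.0, max=2.5)

    def residual(pars):
        sp = StackingParams(pars["eps_ST"].value, pars["gamma_ST"].value)
        eS = StackedElasticParams(l_S=pars["l_S"].value, p_inf=pars["p_S"].value,
                                  m_p=0.0, C=1.0)
        out = []
        for c in fecs:
            out.append((c.x - _st_model_curve(c, sp, eU, eS)) * _weights(c))
        return np.concatenate(out)

    mini = _minimize(p, residual, config.multistart, config.seed)
    return _result_from(mini, residual, fecs, {
        "fit": "st", "Ns": [c.N_loop or c.N for c in fecs],
        "tc_dialect": eU.dialect, "config": config.__dict__,
    })


# ------------------------------------------------------------ salt laws


def fit_salt_laws(fecs: Sequence[ForceExtensionCurve], eU_ref: UnstackedElasticParams,
                  anchors: dict[str, float], config: FitConfig = FitConfig(),
                  l_S: float = 0.386) -> FitResult:
    """Fit the logarithmic salt laws of the stacking energies across salts.

    eps(C) = eps0 + m_eps ln C and gamma(C) = gamma0 + m_gamma ln C with the
    1 M intercepts fixed to ``anchors`` (keys 'eps_ST', 'gamma_ST'); the
    stacked persistence length is co-fitted as a Debye law
    p_S(C) = p_inf + m_p/sqrt(C); l_S is held salt independent.
    """
    salts = sorted({c.salt_M for c in fecs})
    if len(salts) < 3:
        raise ValueError(f"need >= 3 salt conditions, got {len(salts)}")
    for key in ("eps_ST", "gamma_ST"):
        if key not in anchors:
            raise ValueError(f"missing anchor for {key!r}")
    p = lmfit.Parameters()
    p.add("m_eps", value=0.005, min=-0.05, max=0.05)
    p.add("m_gamma", value=0.05, min=-0.1, max=0.3)
    p.add("p_inf", value=9.0, min=1.0, max=30.0)
    p.add("m_p", value=0.3, min=0.0, max=5.0)

    def residual(pars):
        out = []
        for c in fecs:
            C = c.salt_M
            sp = StackingParams(
                anchors["eps_ST"] + pars["m_eps"].value * np.log(C),
                max(anchors["gamma_ST"] + pars["m_gamma"].value * np.log(C), 0.0),
            )
            eS = StackedElasticParams(l_S=l_S, p_inf=pars["p_inf"].value,
                                      m_p=pars["m_p"].value, C=C)
            out.append((c.x - _st_model_curve(c, sp, eU_ref.at_salt(C), eS)) * _weights(c))
        return np.concatenate(out)

    mini = _minimize(p, residual, config.multistart, config.seed)
    return _result_from(mini, residual, fecs, {
        "fit": "salt-laws", "salts_M": salts, "anchors": anchors,
        "l_S": l_S, "config": config.__dict__,
    })


# ------------------------------------------------------------- gamma_2


def fit_gamma2(fecs: Sequence[ForceExtensionCurve], annotation: SequenceAnnotation,
               eU_ref: UnstackedElasticParams, stacking_laws: dict[str, float],
               p_S_law: dict[str, float], config: FitConfig = FitConfig(),
               l_S: float = 0.386, shared_slope: float | None = None) -> FitResult:
    """Fit the track-boundary coupling law gamma_2(C) = gamma2_0 + m_gamma2 ln C.

    All other parameters are fixed: ``stacking_laws`` carries eps0/m_eps/
    gamma0/m_gamma, ``p_S_law`` carries p_inf/m_p.  Data are per-purine-base
    FECs of the annotated mixed sequence.  ``shared_slope`` fixes m_gamma2
    to a given value (the constrained variant that borrows the gamma_ST
    salt slope).
    """
    if not fecs:
        raise ValueError("no curves given")
    p = lmfit.Parameters()
    p.add("gamma2_0", value=0.5, min=0.0, max=2.0)
    if shared_slope is None:
        p.add("m_gamma2", value=0.05, min=-0.1, max=0.3)
    else:
        p.add("m_gamma2", value=shared_slope, vary=False)

    def residual(pars):
        out = []
        for c in fecs:
            C = c.salt_M
            sp = StackingParams(
                stacking_laws["eps_ST"] + stacking_laws["m_eps"] * np.log(C),
                max(stacking_laws["gamma_ST"] + stacking_laws["m_gamma"] * np.log(C), 0.0),
            )
            g2 = max(pars["gamma2_0"].value + pars["m_gamma2"].value * np.log(C), 0.0)
            eS = StackedElasticParams(l_S=l_S, p_inf=p_S_law["p_inf"],
                                      m_p=p_S_law.get("m_p", 0.0), C=C)
            eU = eU_ref.at_salt(C)
            mixed = fec_mixed(annotation, Gamma2Params(sp, g2), eU, eS, c.f)
            model = rescale_purine_extension(mixed.x, annotation, eU, c.f)
            out.append((c.x - model) * _weights(c))
        return np.concatenate(out)

    mini = _minimize(p, residual, config.multistart, config.seed)
    return _result_from(mini, residual, fecs, {
        "fit": "gamma2", "shared_slope": shared_slope,
        "salts_M": sorted({c.salt_M for c in fecs}), "config": config.__dict__,
    })


# ------------------------------------------------------- global (proc II)


def fit_all_procedure2(pure_fecs: Sequence[ForceExtensionCurve],
                       mixed_fecs: Sequence[ForceExtensionCurve],
                       annotation: SequenceAnnotation,
                       eU_ref: UnstackedElasticParams,
                       config: FitConfig = FitConfig(),
                       init: dict[str, float] | None = None) -> FitResult:
    """Simultaneous fit of every sequence and salt with the two-coupling model.

    Free parameters: the two energy salt laws (eps0, m_eps, gamma0,
    m_gamma), the boundary law (gamma2_0, m_gamma2), the stacked-state
    elasticity (l_S, p_inf, m_p).  Homopolymer curves use the single-
    coupling model at their N; mixed-sequence curves use the annotated
    two-coupling model rescaled per purine base.
    """
    init = init or {}
    p = lmfit.Parameters()
    p.add("eps0", value=init.get("eps0", 0.12), min=0.0, max=0.6)
    p.add("m_eps", value=init.get("m_eps", 0.005), min=-0.05, max=0.05)
    p.add("gamma0", value=init.get("gamma0", 0.8), min=0.0, max=2.5)
    p.add("m_gamma", value=init.get("m_gamma", 0.05), min=-0.1, max=0.3)
    p.add("gamma2_0", value=init.get("gamma2_0", 0.5), min=0.0, max=2.0)
    p.add("m_gamma2", value=init.get("m_gamma2", 0.05), min=-0.1, max=0.3)
    p.add("l_S", value=init.get("l_S", 0.38), min=0.2, max=0.6)
    p.add("p_inf", value=init.get("p_inf", 9.0), min=1.0, max=30.0)
    p.add("m_p", value=init.get("m_p", 0.3), min=0.0, max=5.0)

    all_curves = list(pure_fecs) + list(mixed_fecs)

    def residual(pars):
        out = []
        for c in pure_fecs:
            C = c.salt_M
            sp = StackingParams(
                pars["eps0"].value + pars["m_eps"].value * np.log(C),
                max(pars["gamma0"].value + pars["m_gamma"].value * np.log(C), 0.0),
            )
            eS = StackedElasticParams(l_S=pars["l_S"].value, p_inf=pars["p_inf"].value,
                                      m_p=pars["m_p"].value, C=C)
            out.append((c.x - _st_model_curve(c, sp, eU_ref.at_salt(C), eS)) * _weights(c))
        for c in mixed_fecs:
            C = c.salt_M
            sp = StackingParams(
                pars["eps0"].value + pars["m_eps"].value * np.log(C),
                max(pars["gamma0"].value + pars["m_gamma"].value * np.log(C), 0.0),
            )
            g2 = max(pars["gamma2_0"].value + pars["m_gamma2"].value * np.log(C), 0.0)
            eS = StackedElasticParams(l_S=pars["l_S"].value, p_inf=pars["p_inf"].value,
                                      m_p=pars["m_p"].value, C=C)
            eU = eU_ref.at_salt(C)
            mixed = fec_mixed(annotation, Gamma2Params(sp, g2), eU, eS, c.f)
            model = rescale_purine_extension(mixed.x, annotation, eU, c.f)
            out.append((c.x - model) * _weights(c))
        return np.concatenate(out)

    mini = _minimize(p, residual, config.multistart, config.seed)
    return _result_from(mini, residual, all_curves, {
        "fit": "global-procedure2",
        "n_pure": len(pure_fecs), "n_mixed": len(mixed_fecs),
        "config": config.__dict__,
    })


# ------------------------------------------------------------ bootstrap


def bootstrap_errors(fit_fn: Callable[[Sequence[ForceExtensionCurve]], FitResult],
                     fecs: Sequence[ForceExtensionCurve],
                     n: int = 500, seed: int = 0,
                     unit: str = "points") -> dict[str, float]:
    """Bootstrap standard errors of a fit.

    ``fit_fn`` maps a list of curves to a FitResult (close over any other
    arguments).  Resampling draws data points with replacement within each
    curve (default) or whole curves ("molecules").  Deterministic given the
    seed; warns if more than 5% of the refits fail.
    """
    if unit not in ("points", "molecules"):
        raise ValueError("unit must be 'points' or 'molecules'")
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {}
    failures = 0
    for _ in range(n):
        if unit == "points":
            resampled = []
            for c in fecs:
                # multiset resample expressed as per-point multiplicity
                # weights, so the force grid stays strictly increasing
                counts = np.bincount(rng.integers(0, len(c), size=len(c)),
                                     minlength=len(c))
                sel = counts > 0
                base_se = c.se[sel] if c.se is not None else np.ones(int(sel.sum()))
                resampled.append(ForceExtensionCurve(
                    f=c.f[sel], x=c.x[sel],
                    se=base_se / np.sqrt(counts[sel]),
                    per_base=c.per_base, N=c.N, N_loop=c.N_loop,
                    salt_M=c.salt_M, molecule_id=c.molecule_id, meta=dict(c.meta),
                ))
        else:
            picks = rng.integers(0, len(fecs), size=len(fecs))
            resampled = [fecs[i] for i in picks]
        try:
            res = fit_fn(resampled)
        except Exception:
            failures += 1
            continue
        for k, v in res.params.items():
            samples.setdefault(k, []).append(v)
    if n > 0 and failures / n > 0.05:
        warnings.warn(f"bootstrap refit failure rate {failures}/{n}", stacklevel=2)
    return {k: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
            for k, v in samples.items()}
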