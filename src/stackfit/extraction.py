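"""Turn pulling force-distance curves into ssDNA force-extension curves.

The two-branches method: a hairpin pulling cycle has a folded branch (below
the unfolding rip) and an unfolded branch (above it); at equal force the
trap-position difference between the branches, corrected for the oriented
hairpin diameter and the 15 bp of duplex released with the blocking oligo,
is the extension of the released ssDNA:

    X_ssDNA(f) = lambda_U(f) - lambda_F(f) + x_d(f) + x_dsDNA_15bp(f)

The loop contribution per base then follows by subtracting the unstacked
elastic response of the stem (+ right-handle) bases:

    x_b = (X_ssDNA - (N - N_loop) x_U(f)) / N_loop

The validity window is 5-45 pN; points where either branch lacks support
are masked, never extrapolated.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .curves import ForceDistanceCurve, ForceExtensionCurve
from .elasticity import (
    UnstackedElasticParams,
    diameter_extension,
    dsdna_segment_extension,
    tc_extension,
)

__all__ = [
    "classify_branches",
    "two_branches_extension",
    "rescale_loop",
    "infer_N",
    "average_molecules",
    "FORCE_WINDOW_PN",
]

#: validity window of the two-branches method, pN
FORCE_WINDOW_PN = (5.0, 45.0)


def classify_branches(fdc: ForceDistanceCurve, drop_threshold_pN: float = 1.0,
                      window_points: int = 5) -> ForceDistanceCurve:
    """Label each point of a pulling cycle as folded or unfolded.

    A rip is a force drop larger than ``drop_threshold_pN`` within
    ``window_points`` consecutive samples of the pulling half-cycle; the
    refolding jump is the mirror event (force rise while relaxing).  Points
    before the unfolding rip on the pull are folded, points after unfolded;
    symmetrically on the relax half-cycle.
    """
    branch = np.array(fdc.branch, dtype=object)
    n_rips = 0
    for cyc in np.unique(fdc.cycle):
        for direction in ("pull", "relax"):
            sel = np.nonzero((fdc.cycle == cyc) & (fdc.direction == direction))[0]
            if sel.size < window_points + 1:
                continue
            f = fdc.f[sel]
            w = window_points
            jump = f[w:] - f[:-w]
            if direction == "pull":
                events = np.nonzero(jump < -drop_threshold_pN)[0]
            else:
                events = np.nonzero(jump > drop_threshold_pN)[0]
            if events.size == 0:
                continue
            n_rips += 1
            k = events[0]  # first sample index where the jump window starts
            # split at the force extremum inside the window: the last point
            # of the pre-rip branch is the rip force itself
            win = f[k: k + w + 1]
            if direction == "pull":
                split = k + int(np.argmax(win))
                branch[sel[: split + 1]] = "folded"
                branch[sel[split + 1:]] = "unfolded"
            else:
                split = k + int(np.argmin(win))
                branch[sel[: split + 1]] = "unfolded"
                branch[sel[split + 1:]] = "folded"
    if n_rips == 0:
        raise ValueError(
            "no rip found in any cycle: curve rejected "
            f"(threshold {drop_threshold_pN} pN over {window_points} points)"
        )
    out = ForceDistanceCurve(
        lam=fdc.lam, f=fdc.f, cycle=fdc.cycle, direction=fdc.direction,
        branch=branch, meta=dict(fdc.meta),
    )
    out.meta["n_rips"] = n_rips
    return out


def _branch_lambda_of_f(fdc: ForceDistanceCurve, label: str, f_grid: np.ndarray):
    """Monotone piecewise-linear lambda(f) for one branch, averaged over cycles.

    Returns (lam, mask) where mask marks grid forces inside the branch
    support of at least one cycle.
    """
    acc = np.zeros_like(f_grid)
    cnt = np.zeros_like(f_grid)
    for cyc in np.unique(fdc.cycle):
        sel = (fdc.cycle == cyc) & (fdc.branch == label)
        if not np.any(sel):
            continue
        f = fdc.f[sel]
        lam = fdc.lam[sel]
        order = np.argsort(f)
        f, lam = f[order], lam[order]
        f, idx = np.unique(f, return_index=True)
        lam = lam[idx]
        inside = (f_grid >= f[0]) & (f_grid <= f[-1])
        acc[inside] += np.interp(f_grid[inside], f, lam)
        cnt[inside] += 1
    mask = cnt > 0
    lam_grid = np.full_like(f_grid, np.nan)
    lam_grid[mask] = acc[mask] / cnt[mask]
    return lam_grid, mask


def two_branches_extension(fdc: ForceDistanceCurve, f_grid=None,
                           bso_release_bp: int = 15,
                           const: PhysicalConstants = DEFAULT_CONSTANTS) -> ForceExtensionCurve:
    """ssDNA extension X(f) from a branch-labeled FDC.

    Branches are interpolated in force (default grid: 0.5 pN over 5-45 pN),
    averaged over cycles per molecule, and differenced at equal force; the
    hairpin-diameter and released-duplex corrections are added.  Grid points
    outside the joint branch support are dropped.
    """
    if f_grid is None:
        f_grid = np.arange(FORCE_WINDOW_PN[0], FORCE_WINDOW_PN[1] + 0.25, 0.5)
    f_grid = np.asarray(f_grid, dtype=float)
    lam_F, mask_F = _branch_lambda_of_f(fdc, "folded", f_grid)
    lam_U, mask_U = _branch_lambda_of_f(fdc, "unfolded", f_grid)
    mask = mask_F & mask_U & (f_grid >= FORCE_WINDOW_PN[0]) & (f_grid <= FORCE_WINDOW_PN[1])
    if not np.any(mask):
        raise ValueError("no common force support between folded and unfolded branches")
    f = f_grid[mask]
    X = (lam_U[mask] - lam_F[mask]
         + diameter_extension(f, const)
         + dsdna_segment_extension(bso_release_bp, f, const))
    return ForceExtensionCurve(
        f=f, x=X, per_base=False,
        meta={"method": "two-branches", "bso_release_bp": bso_release_bp,
              **{k: v for k, v in fdc.meta.items()}},
    )


def rescale_loop(fec: ForceExtensionCurve, N: int, N_loop: int,
                 eU: UnstackedElasticParams,
                 const: PhysicalConstants = DEFAULT_CONSTANTS) -> ForceExtensionCurve:
    """Extension per loop base: subtract the unstacked stem contribution.

    x_b = (X - (N - N_loop) x_U(f)) / N_loop;  N = N_loop degenerates to X/N.
    """
    if N_loop <= 0 or N < N_loop:
        raise ValueError(f"need N >= N_loop > 0, got N={N}, N_loop={N_loop}")
    xU = tc_extension(eU, fec.f, const)
    x_b = (fec.x - (N - N_loop) * xU) / N_loop
    se = fec.se / N_loop if fec.se is not None else None
    return ForceExtensionCurve(
        f=fec.f, x=x_b, se=se, per_base=True, N=N, N_loop=N_loop,
        salt_M=fec.salt_M if fec.salt_M is not None else eU.C,
        molecule_id=fec.molecule_id,
        meta={**fec.meta, "rescaled": "per-loop-base"},
    )


def infer_N(fec: ForceExtensionCurve, eU: UnstackedElasticParams,
            f_window=(30.0, 50.0),
            const: PhysicalConstants = DEFAULT_CONSTANTS) -> tuple[float, float]:
    """Number of released bases from the high-force unstacked elasticity.

    At 30-50 pN the chain is fully unstacked, so X(f) = N x_U(f); N is the
    single-parameter least-squares slope, returned with its standard error.
    """
    sel = (fec.f >= f_window[0]) & (fec.f <= f_window[1])
    if np.count_nonzero(sel) < 3:
        raise ValueError(
            f"need >= 3 points in {f_window} pN to infer N, got {np.count_nonzero(sel)}"
        )
    xU = tc_extension(eU, fec.f[sel], const)
    X = fec.x[sel]
    denom = float(xU @ xU)
    N_hat = float(xU @ X) / denom
    resid = X - N_hat * xU
    dof = max(X.size - 1, 1)
    se = float(np.sqrt((resid @ resid) / dof / denom))
    return N_hat, se


def average_molecules(fecs: list[ForceExtensionCurve],
                      f_grid=None) -> ForceExtensionCurve:
    """Pointwise mean FEC across molecules with standard errors of the mean.

    Curves are interpolated onto a common grid (the intersection of their
    supports by default).  A single curve is returned as-is with the se
    flagged undefined (NaN).
    """
    if not fecs:
        raise ValueError("no curves to average")
    per_base = fecs[0].per_base
    if any(c.per_base != per_base for c in fecs):
        raise ValueError("cannot average per-base and total-extension curves")
    if f_grid is None:
        if all(c.f.shape == fecs[0].f.shape and np.array_equal(c.f, fecs[0].f)
               for c in fecs):
            f_grid = fecs[0].f
        else:
            lo = max(c.f.min() for c in fecs)
            hi = min(c.f.max() for c in fecs)
            if hi <= lo:
                raise ValueError("curves have no common force support")
            f_grid = np.arange(np.ceil(lo * 2) / 2, hi + 1e-9, 0.5)
    f_grid = np.asarray(f_grid, dtype=float)
    stack = np.vstack([c.interp(f_grid).x for c in fecs])
    mean = stack.mean(axis=0)
    n = len(fecs)
    if n == 1:
        se = np.full_like(mean, np.nan)
    else:
        se = stack.std(axis=0, ddof=1) / np.sqrt(n)
    return ForceExtensionCurve(
        f=f_grid, x=mean, se=se, per_base=per_base,
        N=fecs[0].N, N_loop=fecs[0].N_loop, salt_M=fecs[0].salt_M,
        meta={"n_molecules": n},
    )
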