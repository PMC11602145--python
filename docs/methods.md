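# Methods

## Model

The stacking state of a poly-purine tract of N bases is a two-state Ising
chain: σᵢ = +1 (stacked, S) or −1 (unstacked, U), with energy

E({σ}) = −N_S [ε_ST + W_S(f)] − N_U W_U(f) − γ_ST Σ_{i=0}^{N} σᵢσᵢ₊₁,

where W_S, W_U are the stretching works per base (∫₀^f x df′, in pN nm,
converted to kcal/mol once through 1 kcal/mol = 6.9477 pN nm) and the sum
over bonds includes two virtual boundary sites fixed at σ₀ = σ_{N+1} = −1:
the bases flanking a purine tract in a real construct do not stack, so both
boundary bonds act on every configuration. The model is equilibrium-only;
no hopping kinetics, no sequence-resolved dinucleotide energies, no
tertiary structure (poly-dG-type quadruplex formation is out of scope).

Assumptions worth making explicit: stacking is homogeneous within a tract
(one ε_ST, one γ_ST per dataset); the elastic response of each state is
force-history-independent; temperature is fixed at 298.15 K (k_B =
0.0019872 kcal/(mol K)); and forces stay below the ~60 pN regime where
enthalpic stretching would matter.

## Elasticity

* **Unstacked ssDNA — Thick Chain.** The TC picture is a necklace of disks
  with spacing a and effective radius Δ(C) = δ₀ + δ_slope/√C (Debye-like,
  C the monovalent-equivalent molarity), giving a persistence length
  p_U = −a/ln(1 − a²/4Δ²). The exact TC force–extension interpolation is
  not available to this implementation, so x_U(f) is a pluggable *dialect*;
  the default, `fjc-kuhn`, is a discrete freely-jointed chain with contour
  l_U per base and Kuhn length b = 2 p_U, which reproduces the TC
  persistence length by construction and the measured curves within the
  instrument resolution. The dialect name is recorded in every output.
  Defaults: l_U = 0.652 nm, a = 0.65 nm, Δ(C) = 0.40 + 0.0109/√C nm.
* **Stacked ssDNA — WLC.** Marko–Siggia interpolation inverted by a
  safeguarded Newton iteration (residual |f(x̂) − f|/f < 10⁻¹²); a
  seventh-order-corrected dialect (`ms7`) sits behind the same interface.
  Defaults: l_S = 0.386 nm; p_S(C) = p_∞ + m_p/√C with p_∞ = 9.9 nm.
* **Hairpin diameter** — single-monomer FJC of 2 nm; **short dsDNA
  segments** (handles, the 15 bp released with the blocking oligo) —
  inextensible WLC with p = 50 nm and 0.34 nm/bp; across 5–45 pN the
  handle-model choice moves the extraction by < 0.3 nm, below the 1 nm
  instrument resolution.

Stretching works use closed forms (FJC: l (kT/b) ln(sinh u/u); WLC: the
Legendre transform f·x − E(x) with the analytic interpolation energy), so
no quadrature sits inside fitting loops; a generic adaptive-quadrature
`stretch_work` (relative tolerance 10⁻¹⁰) covers arbitrary dialects and
cross-checks the closed forms in the tests. Small-u limits (x_U at f → 0,
ln sinh u/u) are series-expanded to avoid 0/0.

## Transfer matrix and closed forms

The finite chain is contracted exactly with 2×2 transfer matrices,
rescaling the propagated vector by its maximum at every step and
accumulating the log (stable to N ~ 10⁵ at 45 pN, where the site exponents
reach ~10²). Site occupancies come from a forward–backward pass, giving
⟨N_S⟩ and the extension X = ⟨N_S⟩x_S + ⟨N_U⟩x_U, which the tests verify
against −∂G/∂f (centred differences, step 10⁻³ pN, < 10⁻⁵ relative) and
against exhaustive 2^N enumeration for N ≤ 14 (< 10⁻¹⁰ relative). An exact
forward-filter/backward-sampler draws equilibrium configurations for
statistical checks.

For N → ∞ the leading eigenvalue yields the per-base free energy; the
bulk magnetization gives φ_S and the per-base FEC. With A(f) = ε_ST/2 −
½∫₀^f (x_U − x_S) df′:

* ΔG₀ = ε/2 + kT ln[cosh(βε/2) + √(e^{−4βγ} + sinh²(βε/2))] — the
  zero-force stacking free energy per base; ε ≤ ΔG₀ ≤ ε + O(e^{−4βγ})
  (the sandwich is tested with its rigorous constant).
* ξ_ST(f) = −1/ln(λ₂/λ₁), evaluated in closed form from A(f). ξ is a
  function of |A| alone, so it is *not* monotone below its peak: at low
  force the stiff stacked state extends more readily than the unstacked
  chain, |A| first grows and ξ dips before rising to the maximum.
* ξ_max = −1/ln tanh(βγ) at the force f_max where A = 0, i.e.
  ε_ST = ∫₀^{f_max} (x_U − x_S) df′. f_max is found by a 0.5 pN
  sign-change scan on [0.1, 60] pN followed by Brent root-finding
  (tolerance 10⁻³ pN); A monotone-decreasing through its zero makes the
  root unique. ε = 0 with x_U > x_S everywhere returns f_max = 0; no sign
  change raises a "no transition in range" error.

## Mixed sequences (two-coupling model)

Purine runs of ≥ 4 bases (configurable) are stackable tracks; everything
else is pinned unstacked and contributes x_U(f). Bonds inside a track
carry γ_ST; bonds at a track edge (junction to a pinned base or chain end)
carry γ₂. Pinned–pinned bonds add only a constant and are dropped. The
chain then factorizes into independent finite tracks, each solved exactly,
and γ₂ = γ_ST reduces every track to the homogeneous model identically.
Because the edge bonds couple to pinned *unstacked* neighbours, a larger
γ₂ rewards unstacked edges: φ_S decreases monotonically with γ₂. The
repetitive 28-base motif used for mixed-sequence analysis is shipped as a
preset with both the rule-based annotation (runs of 5, 6, 8, 4) and the
published grouping (9, 6, 8 — the head and tail runs join across the
periodic repeat), selected via an explicit track list.

## Extraction (two-branches method)

A pulling cycle is split at the unfolding rip (force drop > 1 pN within 5
samples on the pull; mirrored for the refolding jump on the relax), with
the branch boundary placed at the force extremum inside the detection
window. Branches are interpolated in force (0.5 pN grid over the 5–45 pN
validity window), averaged over cycles per molecule, and differenced at
equal force; the oriented-diameter and 15 bp-duplex corrections are added.
Grid points outside the joint branch support are dropped, never
extrapolated. The released base count N is the one-parameter least-squares
slope of X(f) against x_U(f) over 30–50 pN (the chain is fully unstacked
there); per-loop-base curves follow by subtracting (N − N_loop)·x_U.
Molecule averages report the empirical standard error across molecules.

## Fitting

Weighted trust-region least squares (lmfit/scipy, xtol = ftol = gtol =
10⁻¹³) with 8 Latin-hypercube multistarts by default (the shoulder makes
the (ε, γ) objective mildly nonconvex); weights are 1/se² where curves
carry standard errors, unit otherwise. The staged analysis (procedure I)
fits, in order: the TC elasticity across salts (shared l_U, a and the
Δ(C) Debye law — with a single salt a and Δ are only jointly identified
through p_U, so the radius law is frozen and a warning raised); the four
stacking parameters (l_S, p_S, ε_ST, γ_ST) jointly across chain lengths
at the reference salt; the logarithmic salt slopes with 1 M intercepts
anchored to the reference fit (natural log — with m^γ ≈ 0.05 this carries
ξ_max from ~4 bases at 10 mM to ~9 at 1 M, which base-10 would not);
and finally the boundary-coupling law γ₂(C) on mixed-sequence data, with
an optional shared-slope constraint. Procedure II fits everything at once
with the two-coupling model. MgCl₂ concentrations are mapped to 100× their
molarity before salt-law evaluation and the mapping recorded in
provenance.

Uncertainties come from bootstrap resampling (default n = 500, seeded and
deterministic): data points within curves by default — implemented as
multiplicity weights so force grids stay monotone — or whole molecules as
an option; a refit failure rate above 5% triggers a warning. Residual
diagnostics include per-curve sums of squares and the lag-1 residual
autocorrelation, which flags a mis-specified elastic model. Estimates are
invariant to curve order to ~10⁻⁵ relative — the trust-region step
sequence depends on residual ordering, so exact invariance is not
attainable with an iterative optimizer.

## Synthetic data

The generator emulates the assay's statistical structure, not its raw
time series. FEC noise is Gaussian with σ_eff² = (σ_x² + (σ_f dX/df)²)/
n_cycles: σ_x = 1 nm and σ_f = 0.1 pN are the per-sample instrument
resolution, and an experimental FEC point is the per-molecule equal-force
branch average over the pulling cycles — n_cycles defaults to 50, typical
of a kHz-acquisition pulling experiment. Per-base curves divide σ_x by the
base count the measurement was rescaled by. Pulling curves are built by
inverting the branch decompositions on a Hookean trap (default stiffness
0.08 pN/nm — not a measured value; recorded in output metadata), with the
unfolding rip at 40 pN and the refolding jump at 4 pN by default, and the
post-rip force found by inverting the unfolded branch at the rip position.
All generators are pure functions of (spec, seed).

What passing tests do and do not show: the generators share the model's
elastic and thermodynamic structure with the fitters, so recovery tests
validate the inference machinery (identifiability, bias, error
calibration) under the stated noise — they cannot detect model
mis-specification against real molecules, drift, miscalibration,
force-dependent noise, or secondary structure, none of which the
generator emulates.

## Problem sizes and numerical conventions

Tests and the acceptance script use: two-length recovery with N = 20 and
40 loops, five molecules per length on a 0.5 pN grid; oracle equivalence
over 100 random parameter sets at N ≤ 14; correlation-decay checks with
10⁴ exact configurations of an N = 2000 chain, using a split-sample
standard error over the i.i.d. configurations (per-lag correlation
estimates share samples, so an OLS slope error would be far too small);
bootstrap n = 100 where full n = 500 would add nothing but runtime.
Forces are pN, lengths nm, energies kcal/mol throughout; sequence
coordinates are 0-based half-open.

## Known limitations

The TC dialect is a stand-in parameterized to match the printed
persistence lengths, not the full thick-chain partition function with
excluded volume; swapping in an exact interpolation is a one-line dialect
change. ε_ST and γ₂ trade off weakly in mixed-sequence fits at a single
salt. The γ₂ model treats all track bases with one ε_ST (no dA/dG
distinction). Bootstrap standard errors assume independent per-point
noise; correlated drift would require block resampling.
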