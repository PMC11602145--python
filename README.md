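# stackfit

Thermodynamics of base stacking in single-stranded nucleic acids under
force, for single-molecule force spectroscopists and modellers. Poly-purine
ssDNA (and ssRNA) tracts partially stack into a short, stiff helical
conformation; pulling the molecule unstacks it cooperatively, leaving a
characteristic shoulder in the force–extension curve (FEC). `stackfit`
implements the helix-coil ("ST") model of this transition, the polymer
elasticity of both states, the extraction of FECs from optical-tweezers
pulling curves, multi-dataset fitting with salt laws and bootstrap errors,
and a synthetic-data generator that emulates the assay.

## The model

Each of the N stackable bases is an Ising spin, σᵢ = +1 (stacked, S) or
−1 (unstacked, U). At force f the energy of a configuration is

    E({σ}) = −N_S [ε_ST + ∫₀^f x_S df′] − N_U ∫₀^f x_U df′ − γ_ST Σᵢ σᵢσᵢ₊₁

with fixed unstacked virtual sites σ₀ = σ_{N+1} = −1 at both ends. ε_ST is
the stacking free-energy gain per base (~0.1 kcal/mol), γ_ST the
cooperativity penalty of an S/U domain wall (~10× larger), x_S(f) a
worm-like chain (contour l_S, persistence p_S) and x_U(f) the Thick-Chain
elasticity of unstacked ssDNA (contour l_U per base, disk spacing a,
salt-dependent radius Δ(C), persistence p_U = −a/ln(1 − a²/4Δ²)). The
finite chain is solved exactly by a 2×2 transfer matrix; X(f) = −∂G/∂f.
In the long-chain limit the model gives closed forms for

- the zero-force stacking free energy per base ΔG₀ (≈ ε_ST for βγ ≳ 1),
- the force-dependent stacking correlation length ξ_ST(f),
- its maximum ξ_max = −1/ln tanh(βγ_ST), reached at the transition force
  f_max solving ε_ST = ∫₀^{f_max} (x_U − x_S) df′.

Heterogeneous sequences are handled by a two-coupling variant: purine
tracks carry γ_ST inside and a distinct γ₂ at purine–pyrimidine junctions,
with non-track bases pinned unstacked. Energy parameters follow
logarithmic salt laws θ(C) = θ⁰ + m ln C (C in M, 1 M intercepts); the
1:100 rule maps MgCl₂ to its monovalent equivalent.

## Worked example

`examples/correlation_length.py` evaluates the closed forms for the four
polymeric sequences with their fitted parameters:

```
sequence    DG0 kcal/mol  xi(0) b  xi_max b  f_max pN
poly-dA            0.146     3.84      9.11     18.56
poly-dGdA          0.070     4.72      4.78     13.68
poly-rA            0.223     2.07      2.67     20.03
poly-rC            0.215     1.74      1.89     18.19
```

Reading the poly-dA row: stacking is worth 0.146 kcal/mol per base at zero
force; correlations between stacked bases extend over ~4 bases at rest,
peak at ~9 bases exactly at the unstacking transition (18.6 pN at 1 M
NaCl-equivalent salt), and vanish at high force. The other examples cover
finite-size FECs (`predict_fec.py`), the two-branches extraction pipeline
on simulated pulling data (`extract_two_branches.py`), parameter recovery
with bootstrap errors (`fit_recovery.py`), and mixed sequences
(`mixed_sequence.py`). A thin CLI wraps the same functions:

```bash
stackfit predict-fec --model st --n 40 --salt 1.0 --out fec.tsv
stackfit simulate fdc --construct H40 --seed 3 --out fdc.tsv
stackfit extract --fdc fdc.tsv --n-loop 40 --out loop.tsv
stackfit fit --model st --fec loop.tsv --out result.json
```

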