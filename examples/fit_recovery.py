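"""Parameter recovery: fit the stacking model to synthetic two-length data.

Generates noisy per-base FECs for 20- and 40-base poly-dA loops (five
molecules each), fits the four model parameters jointly, and reports
bootstrap standard errors.  The finite-size difference between the two
lengths is what pins down the cooperativity.
"""

import numpy as np

from stackfit import ChainSpec, FitConfig, NoiseModel, average_molecules, bootstrap_errors, fec_finite, fit_st, gen_fec
from stackfit.presets import POLY_DA, STACKED_WLC, TC_UNSTACKED

eU, eS = TC_UNSTACKED, STACKED_WLC
f_grid = np.arange(5.0, 45.01, 0.5)

curves = []
for N, seed0 in ((20, 300), (40, 400)):
    mean = fec_finite(ChainSpec(N), POLY_DA, eU, eS, f_grid, per_base=True)
    mean.N_loop, mean.salt_M = N, 1.0
    reps = [gen_fec(mean, NoiseModel(), seed0 + k) for k in range(5)]
    curves.append(average_molecules(reps, f_grid))

res = fit_st(curves, eU, FitConfig(multistart=4, seed=11))
se = bootstrap_errors(
    lambda cs: fit_st(cs, eU, FitConfig(multistart=1, seed=11), init=res.params),
    curves, n=100, seed=12,
)

truth = {"l_S": 0.386, "p_S": 9.9, "eps_ST": 0.14, "gamma_ST": 0.86}
units = {"l_S": "nm", "p_S": "nm", "eps_ST": "kcal/mol", "gamma_ST": "kcal/mol"}
print(f"{'parameter':<10}{'true':>8}{'fit':>9}{'boot se':>9}  unit")
for k, v in truth.items():
    print(f"{k:<10}{v:>8.3f}{res.params[k]:>9.3f}{se[k]:>9.3f}  {units[k]}")
print()
print("Each estimate should sit within a few bootstrap standard errors of the")
print("generating value; eps_ST and gamma_ST land inside their published")
print("uncertainties (0.01 and 0.02 kcal/mol respectively).")
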