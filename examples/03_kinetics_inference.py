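"""Maximum-likelihood kinetics from multiple labeling durations.

With several pulse lengths the mean curve a(t) is traced at several points,
so transcription and degradation separate without any steady-state
assumption.  The same machinery fits the zero-inflated (promoter on/off)
variant and scores every gene with an adjusted deviance R^2 used to select
well-modeled genes.
"""

import numpy as np

import labelvelo as lv
from labelvelo.distributions import mean_new_baseline

rng = np.random.default_rng(7)
durations = np.array([0.25, 0.5, 0.75, 1.0, 2.0, 3.0])  # hours
t = np.repeat(durations, 300)
p = rng.uniform(0.5, 2.0, t.size)

print("gene   true gamma   est gamma   adj R2_D   robustness")
r2 = []
for g in range(6):
    alpha = rng.uniform(0.5, 1.5)
    gamma = rng.uniform(0.1, 1.0)
    l = rng.poisson(p * mean_new_baseline(alpha, gamma, t))
    fit = lv.fit_csp_baseline(l, p, t)
    rob = lv.robustness_measure(l, p, t)
    r2.append(fit.r2_adj)
    print(
        f"{g:4d}   {gamma:10.3f}   {fit.params['gamma_t']:9.3f}   "
        f"{fit.r2_adj:8.3f}   {rob:10.1f}"
    )
selected = lv.select_genes(r2, fraction=0.4)
print(f"top-40% genes by goodness of fit: {list(selected)}")

# zero-inflated variant: 30% of cells silent
alpha, gamma, p_off = 3.0, 0.5, 0.3
a = mean_new_baseline(alpha, gamma, t)
on = rng.random(t.size) >= p_off
l = np.where(on, rng.poisson(p * a), 0)
fit = lv.fit_csp_switching(l, p, t)
print(
    f"switching model: true p_off = {p_off}, estimated = {fit.params['p_off']:.3f}; "
    f"alpha = {fit.params['alpha']:.2f}/h, gamma_t = {fit.params['gamma_t']:.2f}/h"
)
# The robustness column integrates the profile-likelihood slope over
# gamma in (0, 1.5]: slowly degrading genes sit in a quasi-linear regime
# where gamma is weakly identified, and score low.
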