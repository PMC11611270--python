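# labelvelo

Stochastic-model-based inference of absolute RNA kinetic parameters and
time-resolved RNA velocity from metabolic-labeling single-cell RNA-seq
(tscRNA-seq: scEU-seq, scNT-seq, sci-fate, scSLAM-seq and relatives).

In these assays nascent transcripts are chemically labeled for a known
duration *t*, so each gene's counts split into new/labeled and old/unlabeled
molecules. Because *t* is physical time, transcription (α), splicing (β) and
degradation (γ) rates become identifiable in absolute units (per hour) — and
with them a velocity d⟨r⟩/dt in molecules per hour, rather than the
relative-time velocities of spliced/unspliced methods.

`labelvelo` treats the counts as what they are — small integers — instead of
smoothed continuous values. Three chemical master equations (transcription +
degradation; + splicing; + promoter on/off switching) are solved in closed
form; combined with binomial capture noise at per-cell size factor `p_j`,
the measured labeled counts follow cell-specific Poisson-family laws:

| model     | measured law                           | parameters      |
|-----------|----------------------------------------|-----------------|
| baseline  | `l ~ Poisson(p_j a(t))`                | α, γ_t          |
| splicing  | `(u_l, s_l) ~ Poisson(p_j b(t)) ⊗ Poisson(p_j c(t))` | α, β, γ_s |
| switching | `l ~ ZIP(p_j a(t), p_off)`             | α, γ_t, p_off   |

with `a(t) = α(1 − e^{−γ_t t})/γ_t`, `b(t) = α(1 − e^{−βt})/β`, and `c(t)`
the corresponding spliced-pool solution. On top of these laws the package
provides:

- a modified chi-square goodness-of-fit test valid when **every cell has its
  own distribution parameters** (and a duration-vs-total independence test);
- maximum-likelihood estimators for one-shot experiments (steady-state
  closed form, or a two-stage steady-state-free method using splicing
  information) and for kinetics experiments with multiple pulse lengths,
  with adjusted deviance-R² model scoring, gene selection, and a robustness
  index for the degradation rate;
- kNN post-processing that relaxes every rate except degradation to
  gene-cell-specific values, and the resulting total/spliced RNA velocities
  with correctness/consistency metrics and a phase-duration algorithm;
- exact Gillespie simulators of labeling experiments (bifurcating one-shot
  design and non-steady pulse design) with ground truth, used throughout the
  test suite.

## Worked example

```python
import numpy as np
import labelvelo as lv
from labelvelo.distributions import mean_new_baseline

rng = np.random.default_rng(1)
n, alpha, gamma, t = 4000, 5.0, 0.5, 1.0     # rates in 1/h, t in hours
p = rng.uniform(0.5, 2.0, n)                  # size factors
new = rng.poisson(p * mean_new_baseline(alpha, gamma, t))
total = new + rng.poisson(p * (alpha / gamma) * np.exp(-gamma * t))
print(lv.fit_oneshot_steady(new, total, p, t))
```

prints

```
(5.016320829210878, 0.501195392583885)
```

and running `examples/02_oneshot_inference.py` prints the same fit as

```
steady route:  true (alpha, gamma_t) = (5.0, 0.5)
               est  (alpha, gamma_t) = (5.016, 0.501)  [1/h]
```

i.e. from a single one-hour labeling experiment on 4000 cells the
transcription rate is recovered as ≈5.0 molecules/hour and the total-mRNA
degradation rate as ≈0.50/hour (a 1.4 h half-life), both in physical units.
The same script then runs the steady-state-free two-stage route on exact
stochastic-simulation data with all four unspliced/spliced × labeled/
unlabeled layers.

Typical container-level workflow:

```python
exp = lv.LabelingExperiment.read_h5ad("counts.h5ad")   # layers: new/total/...
exp.attach_size_factors()
nb = lv.build_knn(lv.pca_representation(exp), k=30, durations=exp.labeling_duration)
fit = lv.fit_csp_baseline(exp.layers["new"][:, 0], exp.size_factor,
                          exp.labeling_duration, r=exp.layers["total"][:, 0])
alpha_j = lv.cellwise_baseline(exp.layers["new"][:, 0], exp.size_factor, nb,
                               fit.params["gamma_t"], exp.labeling_duration)
v = alpha_j - fit.params["gamma_t"] * lv.knn_smooth(exp, nb, ["total"])["total"][:, 0]
```

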