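# stagecycle

Multi-stage Markov representation of the cell cycle: Erlang and
exponentially modified Erlang (EME) cell-cycle-time distributions,
simulated **exactly** with the Gillespie stochastic simulation
algorithm.

## Why

Real cell-cycle times (CCTs) are nothing like exponential — a newborn
cell cannot divide again immediately — yet stochastic models of
proliferation routinely represent division as a single first-order
reaction so that Gillespie's algorithm applies. `stagecycle` splits the
cell cycle of mean length `C` into `k` exponential stages,

    X_1 --λ--> X_2 --λ--> ... --λ--> X_k --λ--> 2 X_1,    λ = k/C,

which makes the CCT Erlang(k, λ) (hypoexponential in the general
unequal-rate case, EME when a final stage of a different rate is
appended) while keeping every individual event exponential — so the
standard Gillespie machinery still simulates the process exactly. The
variance `C²/k` shrinks as stages are added, approaching synchronous
division.

The choice of CCT distribution changes model *means*, not just
variances. The package provides, alongside the simulators:

* exact series solutions for the mean stage counts over the k-th roots
  of unity, the asymptotic law `M(t) ≈ [2^{1/k}/(2α_k)] e^{α_k t/C}`
  with `α_k = k(2^{1/k} − 1)`, and the infinite-k limits
  (`2^{⌊t/C⌋}`, with coefficient 3/4 at integer `t/C`);
* steady-state stage proportions `M̂_j = 2^{(k−j)/k}(2^{1/k} − 1)` —
  cells are *not* distributed proportionally to stage durations;
* least-squares fitting of exponential / Erlang / EME densities to
  binned CCT histograms, with a synthetic-histogram generator;
* two illustrative applications: a well-mixed cancer stem-cell
  proliferation/differentiation model, and a 2-D on-lattice
  volume-exclusion growth-to-confluence model with two division-abort
  rules (stage reset vs checkpoint hold).

Intended users: modellers of proliferating cell populations (tumour
growth, development, tissue culture assays) who want realistic CCT
distributions without leaving the Gillespie framework, and anyone
fitting CCT histograms to stage-structured distributions.

## Worked example

Four stages slow mean growth relative to the naive single-stage model
with the same mean CCT (`C = 10`):

```python
import numpy as np
from stagecycle import (ErlangParams, asymptotic_law, ensemble_summary,
                        exact_total_mean)

k, C, reps = 4, 10.0, 2000
ts = [10.0, 20.0, 30.0]
summ = ensemble_summary(reps, ErlangParams.from_mean(k, C),
                        t_end=30.0, record_times=ts, seed=1)
print("t    SSA mean   exact mean   naive k=1")
for i, t in enumerate(ts):
    print(f"{t:4.0f}  {summ.mean_total[i]:8.3f}  "
          f"{exact_total_mean(t, k, C):10.3f}  {np.exp(t / C):9.3f}")
law = asymptotic_law(k)
print(f"alpha_4 = {law.alpha_k:.4f}, prefactor = {law.prefactor:.4f}")
```

```
t    SSA mean   exact mean   naive k=1
  10     1.659       1.672      2.718
  20     3.547       3.569      7.389
  30     7.589       7.608     20.086
alpha_4 = 0.7568, prefactor = 0.7857
```

Starting from one cell, the exact four-stage mean after three mean cell
cycles is ≈ 7.6 cells versus ≈ 20.1 for the exponential-CCT model — the
2000-replicate Gillespie ensemble agrees with the exact mean to within
Monte-Carlo error. Asymptotically the four-stage population grows like
`0.786 · e^{0.757 t/C}` instead of `e^{t/C}`: both the exponent and the
prefactor are smaller than the naive model's.

## Command line

Each subcommand writes CSV/JSON outputs plus a `manifest.json` recording
parameters, seed and version, so every output is reproducible from its
manifest:

```sh
stagecycle chain    --k 4 --c 10 --t-end 30 --reps 1000 --seed 1 --outdir out/
stagecycle stemcell --k 10 --rho-s 1 --r1 0.2 --r3 0.15 --t-end 100 \
                    --reps 10000 --threshold 1000 --seed 1 --outdir out/
stagecycle lattice  --lx 100 --ly 100 --k 10 --abort-rule hold --density 0.01 \
                    --tbar-end 10 --reps 20 --seed 1 --outdir out/
stagecycle fit      --histogram hist.csv --fit eme --k-min 1 --k-max 60
stagecycle analytic --k-max 30 --outdir out/
```

Histogram CSV format: header `bin_left_edge,density_height`, one row per
bin, and a final row holding the right-most edge with an empty height.
Parameters may also come from a YAML file via `--config`, with flags
taking precedence.

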