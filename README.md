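# tamodel

Minimal ODE modelling of bacterial **type II toxin–antitoxin (TA)**
gene-expression dynamics: simulate a three-species kinetic model and its
nested variants, fit them to toxin/antitoxin expression time courses, rank
the variants by collective AIC/BIC, and cluster the fitted kinetic
parameter vectors into a central group and outliers.

## Who this is for

Type II TA operons encode a stable protein toxin and an unstable protein
antitoxin; the two form a complex that represses the operon, while free
toxin slows cell growth.  Their regulation is central to bacterial stress
physiology and to the biology of persister cells.  `tamodel` is for
systems biologists who have bulk expression time courses for TA pairs
(e.g. time-resolved RNA-Seq of *E. coli*, which carries eleven
well-characterised type II modules such as *relB–relE* or *hipB–hipA*)
and want to turn each pair's two curves into an interpretable vector of
kinetic constants.

## The model

For antitoxin z1, toxin z2 and TA complex z3:

```
dz1/dt = −d1 z1 + k1 / ((1 + z3/s1)(bm z2 + 1)) − k2 z1 z2 + z3
dz2/dt = −d2 z2 / (bc z2 + 1) − k2 z1 z2 + z3 + 1 / ((1 + z3/s2)(bm z2 + 1))
dz3/dt = −d3 (−k2 z1 z2 + z3)
```

Ingredients: mass-action complex formation/dissociation, transcriptional
repression of both genes by the complex (scales s1, s2), and toxin-induced
growth modulation (bm lowers production, bc lowers the toxin's own
dilution).  With the fitted initial complex level c0 = z3(0) the full
model has 10 adjustable constants; seven simpler variants arise by tying
s1 = s2 and/or fixing bm = 0, bc = 0 (down to 6 constants).  Fits minimise
a mean-weighted least-squares objective over both curves simultaneously
(per-curve weight 1/mean², so the low-abundance curve is not ignored),
using basin-hopping over a Nelder–Mead + least-squares local search.
Variants are compared with `aic = N ln(χ²/N) + 2 Nv` and
`bic = N ln(χ²/N) + ln(N) Nv`; fitted full-model parameter vectors are
log-standardised, embedded with PCA, and clustered with DBSCAN
(eps = 0.8) into a main cluster plus outliers.  See `docs/methods.md`
for assumptions, defaults and limitations.

## Worked example

Simulate the model, generate a small synthetic dataset from it, fit two
variants and rank them:

```python
import numpy as np
from tamodel import (
    GeneratorConfig, OptConfig, ZParams, generate_dataset, fit_all,
    collective_selection, best_model, simulate,
)

params = ZParams(k1=3.0, k2=1.0, d1=2.0, d2=0.3, d3=1.0,
                 s1=0.1, s2=2.0, bm=1.0, bc=1.0, c0=1.0)
traj = simulate(params, (0.0, 0.0, params.c0), np.linspace(0, 10, 6))
print(traj.to_frame().round(4).to_string(index=False))

cfg = GeneratorConfig(n_central=3, n_outliers=0, master_seed=7)
timecourses, truth = generate_dataset(cfg)
opt = OptConfig(n_hops=3, local_maxiter=120, ls_max_nfev=80)
fits = fit_all(timecourses, variants=["full", "s1=s2_no_bm_bc"], opt=opt, seed=7)
rows = collective_selection(fits, criterion="bic")
for r in rows:
    print(r.variant_name, f"chi2={r.chi2:.3e}", f"bic={r.bic:.1f}")
print("best by bic:", best_model(rows, "bic"))
```

Output:

```
 time_h     z1     z2     z3
    0.0 0.0000 0.0000 1.0000
    2.0 0.2111 1.2821 0.3482
    4.0 0.1592 1.6859 0.2789
    6.0 0.1408 1.9312 0.2718
    8.0 0.1304 2.1098 0.2738
   10.0 0.1235 2.2484 0.2765
full chi2=4.990e-10 bic=-710.6
s1=s2_no_bm_bc chi2=2.941e-04 bic=-322.2
best by bic: full
```

Reading it: the trajectory shows the typical TA signature — the unstable
antitoxin (z1) settles low while the stable toxin (z2) accumulates, and
the complex (z3) relaxes from its initial level c0 = 1.  On three
noiseless pairs generated by the full model, the full model fits to the
solver floor (χ² ≈ 5e-10 summed over N = 30 timepoints) while the
7-parameter variant without growth feedback is left with a structural
residual four orders of magnitude larger, so BIC — which penalises the
full model's three extra constants — still prefers the full model by a
wide margin.

A command-line interface mirrors the library
(`tamodel simulate|synth|fit|select|cluster|run`); real datasets are
loaded from a long-format TSV (`pair`, `role`, `time_h`, `value`), with
raw values multiplied by c = 1e5 on loading.

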