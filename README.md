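# citsens

Finite-difference parametric sensitivity estimation for **stiff**
discrete stochastic biochemical reaction networks, via coupled implicit
tau-leaping.

## The problem

Stochastic models of biochemical kinetics — the chemical master equation
(CME) and its Monte Carlo samplers — depend on rate constants that are
rarely well constrained. Local sensitivity analysis asks how an expected
output responds to a small change in one constant:

    S_h(t) = [ E f(X^{c+h}(t)) − E f(X^c(t)) ] / h

where X^c is the copy-number process at parameter c, h a small
perturbation, and f an observable such as a species count. Estimating
S_h naively from two independent ensembles needs enormous path counts,
because the variance of the difference is dominated by the paths' own
noise. Coupling the two ensembles — driving the nominal and perturbed
paths from shared randomness so that their difference stays small —
collapses that variance. The exact coupled finite-difference scheme
(CFD) does this with the next-reaction method, but exact simulation is
hopeless for *stiff* networks, where fast reversible reactions force
billions of events per path.

`citsens` implements the coupled implicit tau-leaping estimator (CIT):
nominal and perturbed paths advance together by adaptive implicit leaps
whose Poisson firing counts are split into a shared part with rate
min(a_j^c, a_j^{c+h}) and small residual parts, preserving the
variance-killing coupling while stepping over the fast time-scales.
Step-size selection handles partial-equilibrium reversible pairs
(exempted from the leap condition when |a⁺ − a⁻| ≤ δ·min(a⁺, a⁻)) and
critical reactions (within n_c firings of exhausting a reactant,
advanced by exact single firings). The package also ships the exact SSA,
the exact CFD baseline, uncoupled finite-difference baselines, a
truncated-CME solver used as ground truth on small models, and the three
published stiff benchmark networks (decay-dimerisation, genetic positive
feedback loop, Collins toggle switch) plus reduced validation variants.

See `docs/methods.md` for the full algorithm, numerical policies, and
what the validation suite does and does not establish.

## Worked example

Sensitivity of the dimer count S2 to the dimerisation constant C2 = 50
in the stiff decay-dimerisation network (rates spanning seven orders of
magnitude), with perturbation h = 0.05 and 400 coupled paths:

```python
import numpy as np
from citsens import (LeapControls, OutputGrid, build_fixture,
                     estimate_sensitivity)

fx = build_fixture("decay_dimer")          # C=(0.05, 50, 1e6, 0.05)
s = estimate_sensitivity(
    fx.net, "R2", 0.05, fx.x0, T=1.0,
    controls=LeapControls(n_c=10), R=400, seed=7,
    grid=OutputGrid(0.0, 1.0, 5), method="cit", f="S2",
)
for t, m, se in zip(s.times, s.mean, s.se):
    print(f"t={t:4.2f}  dE[S2]/dC2 ~ {m:8.3f} +- {se:.3f}")
print("mean leaps per path:", s.mean_leaps)
```

```
t=0.00  dE[S2]/dC2 ~    0.000 +- 0.000
t=0.25  dE[S2]/dC2 ~    1.700 +- 0.288
t=0.50  dE[S2]/dC2 ~    1.350 +- 0.261
t=0.75  dE[S2]/dC2 ~    1.100 +- 0.249
t=1.00  dE[S2]/dC2 ~    0.850 +- 0.236
mean leaps per path: 88.8
```

The sensitivity is positive and of order one (raising C2 converts
monomers to dimers faster, slightly raising the dimer pool on the slow
manifold), resolved in under ninety implicit leaps per path — an exact
path of this model takes on the order of 10⁸ reaction events. An uncoupled implicit-tau finite
difference at the same R has a sample variance roughly twenty times
larger (see the variance-reduction test).

The same interface runs from a shell:

```sh
sens estimate --model decay_dimer --method cit --param R2 --h 0.05 \
     --T 1 --paths 400 --seed 7 --grid 5 --out sens.tsv
sens simulate --model toggle_switch --method implicit-tau --T 100 \
     --paths 10 --seed 1 --out traj.tsv
```

`sens estimate` writes a TSV (time, mean_Z, sd_Z, se_Z, paths) and a
JSON sidecar with every control and seed. Models can also be plain-text
files (see `citsens.parse_model`).

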