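# crsens

Structural sensitivity analysis of consumer–resource models in
equilibrium: how much of an ecosystem's stability landscape survives
when its nonlinear interactions are replaced by the proportional
(Lotka–Volterra-type) terms that empirically-based food web models use?

Empirical food web models estimate per-capita interaction strengths from
observed biomass densities and material fluxes, assuming type I
(proportional) functional responses. The Jacobian built from those
estimates yields a recovery rate −Re(λ) after small perturbations —
engineering resilience — which is often read as an indicator of how
close a system is to a regime shift. `crsens` tests that reading inside
a controlled model world: classical two-species consumer–resource models
with nonlinear functional responses serve as the "true" ecosystems,
their equilibria are sampled as if they were field observations, and
Lotka–Volterra-type counterparts are parameterized from those
observations so that equilibrium densities and fluxes match exactly.
Both descriptions of the *same* equilibrium are then followed along an
environmental gradient to see which bifurcations each can express.

## Models

All systems describe a resource *A* (algae) and a consumer *Z*
(zooplankton):

| tag | resource growth | consumption | consumer loss |
|-----|-----------------|-------------|----------------|
| LV  | rA | gZA | mZ |
| LVV | rA(1 − A/K) | gZA | mZ |
| RM  | rA(1 − A/K) | gZA/(A + a) | mZ |
| RMS | rA(1 − A/K) + l(K − A)¹ | gZA/(A + a) | mZ + FZ²/(Z² + z²) |

¹ the RMS resource equation carries a chemostat influx *lK* next to the
loss term *lA*.

Each nonlinear term can be linearized while preserving the equilibrium:
r_lin = r(1 − A\*/K), g_lin = g/(A\* + a), F_lin = FZ\*/(Z\*² + z²).
Applying these replacements selectively gives six counterpart systems
(LVV_LV, RM_LV, RM_LVV, RMS_LV, RMS_LVV, RMS_RM); the suffix names the
dynamics imposed on the parent's equilibrium.

Along a gradient in K (enrichment) or F (top-consumer pressure) the
package tracks every interior equilibrium branch, classifies local
stability from the analytic 2×2 Jacobian, and detects

* **transcritical** bifurcations (predator invasion) by bisection on the
  sign of Z\*,
* **Hopf** bifurcations by bisection on the zero of Re(λ) along a branch,
* **folds** (saddle-nodes, the mechanism behind alternative stable
  states) by bisection on the interior-equilibrium count of RMS, and
* **homoclinic** (global) bifurcations — invisible to any local
  analysis — by bisecting on the outcome of trajectory-based attractor
  probes.

## Worked example

The RMS model at K = 10 along the top-consumer gradient F:

```python
import crsens as cs

p = cs.default_params()                  # algae-zooplankton values, K = 10
grad_F = cs.GradientSpec.default("F")    # F in [0, 0.3], 1000 points

folds = cs.detect_fold("RMS", p, grad_F)
hopf = cs.detect_hopf("RMS", p, grad_F)
homo = cs.detect_global(p, grad_F, fold_events=folds, hopf=hopf)
print(f"folds:      F = {folds[0].param_value:.4f}, {folds[1].param_value:.4f}")
print(f"Hopf:       F = {hopf.param_value:.4f}")
print(f"homoclinic: F = {homo[0].param_value:.4f} .. {homo[1].param_value:.4f}")
```

prints

```
folds:      F = 0.0759, 0.2408
Hopf:       F = 0.2404
homoclinic: F = 0.0784 .. 0.2401
```

i.e. alternative stable states exist for F between the two folds; the
oscillatory branch stabilizes through a supercritical Hopf at F = 0.2404
just before vanishing at the upper fold; and between F = 0.0784 and
F = 0.2401 the limit cycle has collided with the saddle (homoclinic
connection), so a perturbed system lands in the alternative state.

The linearized view of the same equilibrium tells a different story:

```python
eq = cs.numeric_equilibria_rms("RMS", p.replace(F=0.15))[0]
lin = cs.linearize("RMS", p.replace(F=0.15), eq, "LV")
J = cs.jacobian("RMS_LV", lin, eq)
print(cs.classify(cs.eigen(J)).value, cs.eigen(J).dominant_real)
```

```
stable_focus -0.0189
```

while the nonlinear RMS at the very same equilibrium is an unstable
focus (Re(λ) = +0.098) inside the homoclinic window. Equal equilibria
and fluxes, opposite stability verdicts — the package exists to map out
exactly where and why this happens.

The same analyses are scriptable from the shell:

```sh
crsens compare --model RMS --linearizations LV,LVV,RM --param F --out rms.csv
crsens bifurcations --model RMS --param F --out events.json
crsens phase --model RM --K 5 --init 1.2,1.2 --out phase.csv
```

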