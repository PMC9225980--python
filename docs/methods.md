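# Methods

## Model family

Four nonlinear consumer–resource systems in two state variables
(resource *A*, consumer *Z*) share the template

    dA/dt = growth(A) − consumption(A, Z) − lA [+ lK]
    dZ/dt = e·consumption(A, Z) − mZ − top_loss(Z)

with `growth` either proportional (*rA*) or logistic (*rA(1 − A/K)*),
`consumption` either mass-action (*gZA*, Holling type I without ceiling)
or saturating (*gZA/(A + a)*, type II), and `top_loss` absent or sigmoid
(*FZ²/(Z² + z²)*, type III, an implicit prey-switching top consumer).
The RMS model adds the chemostat influx *lK* so the resource is not
washed out when grazed down. Default parameters are the classical
algae–zooplankton set shipped in `crsens/data/table1.toml`
(r = 0.5, g = 0.4, a = 0.6, l = 0.01, e = 0.6, m = 0.15, z = 0.5;
gradients K ∈ [0, 10], F ∈ [0, 0.3]). All rates are per time unit,
densities in resource/consumer units.

## Equilibrium-preserving linearization

Replacing a nonlinear term by a proportional one whose coefficient is
evaluated at an interior equilibrium (A\*, Z\*),

    r_lin = r (1 − A*/K),   g_lin = g / (A* + a),   F_lin = F Z* / (Z*² + z²),

leaves both the equilibrium densities and every material flux through
the equilibrium unchanged. This is exactly the information an empirical
food-web study can measure — standing stocks and flux-per-stock ratios —
so the linearized systems stand in for empirically parameterized
Lotka–Volterra-type models of the "observed" equilibrium. A
`LinearizedSystem` stores its parent equilibrium and is analyzed only
there; when a gradient is swept, the counterpart is rebuilt from the
parent's equilibrium at every grid point. Linearization at an infeasible
equilibrium (Z\* ≤ 0) is refused rather than extrapolated: there is
nothing to observe.

The Jacobians of all ten systems come from one generic analytic form
(term derivatives assembled per variant), never finite differences.
Structural zeros are emitted exactly: at an interior equilibrium the
consumer diagonal J₂₂ vanishes identically whenever the consumer
equation is linear in Z (every variant except the nonlinear RMS), and
J₁₁ vanishes for fully proportional resource equations without influx
(LV, LVV_LV, RM_LV). Floating-point evaluation of the same expressions
would leave ~1e−17 residues that blur the neutral-center classification.

## Equilibria

LV, LVV, RM and every linearized counterpart have closed forms; the
counterparts inherit their parent's expressions by construction. The
RMS family needs a numerical solve: substituting the resource-nullcline
relation Z(A) = [rA(1 − A/K) − lA + lK](A + a)/(gA) into the consumer
equation leaves one scalar residual in A. The residual is scanned on
2000 log-spaced **plus** 2000 uniform points over (1e−6, 1.5K] — the log
grid resolves roots at low A, the uniform grid the near-carrying-capacity
root pair that merges at the lower fold — sign changes are polished by
Brent's method to 1e−10 and near-duplicates merged at 1e−8 relative.
The search ceiling 1.5K is a package choice: above K the net resource
term is negative and Z(A) crosses zero shortly after, so no interior
root can exist much beyond K. The consumer-free state (K, 0) is an
exact equilibrium of RMS; it is reported separately and excluded from
branch tracking, which follows interior equilibria only.

## Stability and regimes

Eigenvalues come from the characteristic quadratic in closed form.
Regimes follow the trace–determinant plane: saddle (det < 0), node vs
focus (discriminant sign), stable vs unstable (sign of the dominant real
part), and neutral center when a conjugate pair lies within 1e−9 of the
imaginary axis. Real eigenvalues near zero are deliberately *not*
labelled neutral — they are the stable/unstable side of a transcritical
passage; neutrality is structural only for conservative LV dynamics.

## Bifurcation detection

All detectors locate a sign change on a gradient grid (default 1000
uniform points) and refine it by bisection, so the resolved threshold
depends on the grid only through bracketing; doubling the grid moves no
event by more than its refinement tolerance.

* **Transcritical**: bisection on the sign of the interior Z\*
  (tolerance 1e−6 in the parameter). The closed form
  K_c = A\*/(1 − l/r) serves as an independent cross-check in the tests.
* **Hopf**: bisection on the zero crossing of Re(λ) along a branch
  (1e−6), rejected if the eigenvalues are real at the crossing.
  Branches are indexed by ascending A\*; branch 0 is the low-A/high-Z
  oscillatory branch of RMS.
* **Fold**: bisection on the interior-equilibrium count of RMS (1e−5).
  Only the nonlinear RMS can fold: every other variant, including the
  standalone linearized counterparts, has a unique interior equilibrium
  (their consumer equation fixes A\* uniquely), so the detector returns
  an empty list for them by that uniqueness argument.
* **Homoclinic**: the limit cycle around the oscillatory RMS branch is
  probed by integrating the full system from a state displaced off the
  branch equilibrium (LSODA, rtol 1e−8, atol 1e−10). The probe
  classifies the late-time behaviour (first half of the horizon
  discarded): return to the equilibrium, sustained oscillation (last
  five consumer peaks within 1% at amplitude > 1e−3), or convergence to
  a different equilibrium. The boundary in F between "sustained cycle"
  and "escape to the alternative state" is bisected to 1e−4, matching
  the four decimals at which such thresholds are conventionally quoted.

The generic probe uses a 1% displacement and a 5000-time-unit horizon.
Homoclinic refinement instead uses 0.25% displacement and a
15000-time-unit horizon: just below the Hopf point the re-born cycle is
small and the basin boundary (the saddle's stable manifold) passes close
to the focus, so a 1% start can land outside the basin and the bisection
would then return the Hopf point rather than the cycle's true
disappearance; the smaller displacement stays inside the basin across
the whole refinement window while escape, when the cycle is gone, is
still completed well within the horizon (Re(λ) ≳ 3e−3 near the upper
boundary).

Branch continuation in sweeps matches equilibria between neighbouring
grid points by nearest A\* with a jump threshold of 10% of the scanned
A-range, allocating fresh branch ids when a fold creates a pair.

## Virtual observations

`sample_observation` evaluates each model term at an interior
equilibrium (production, consumption, top-consumer loss, plus the two
standing stocks) as one "field observation";
`fit_linear_from_observation` recovers a fully linear system from
flux-per-stock ratios (r_lin = production/A, g_lin = consumption/(A·Z),
F_lin = top loss/Z). At zero noise the round trip reproduces the
analytic linearization to machine precision. Observation noise, when
requested, is independent multiplicative lognormal with scale σ on each
of the five quantities (zero by default, so the baseline behaviour is
noise-free); lognormal noise keeps fluxes positive and is
median-unbiased for the fitted ratios. Draws are a fixed-order function
of the seed, so observations are reproducible across platforms. The
generator emulates only the observational step — equilibrium stocks and
fluxes read off a system at rest; it does not emulate temporal sampling,
estimation error in the carried-over rates (l, e, m), or multi-species
aggregation, so noise-robustness results here say nothing about those
error sources in real food-web data.

## Numerical values at the defaults

Under the default parameter set the package computes: invasion
thresholds K = 0.6378 (LVV and LVV_LV) and K = 1.0204 (RM and RM_LV);
the enrichment Hopf of RM at K = 2.653; RMS folds at F = 0.0759 and
0.2408, Hopf at F = 0.2404, homoclinic window F = 0.0784–0.2401 (at
K = 10). The lower fold is often quoted as 0.076 at coarser precision;
both roundings refer to the same point. The qualitative sequences of
the counterparts: LVV_LV and RM_LV are neutral centers above threshold;
RM_LVV and RMS_LVV are stable everywhere with no bifurcations; RMS_LV is
a stable focus for every F (the chemostat influx puts J₁₁ = −lK/A\* < 0
on the diagonal); RMS_RM keeps a Hopf but loses the folds.

## Problem sizes and tolerances used by the shipped analyses

Gradient grids of 1000 points; RMS residual scans of 2×2000 points;
bisection tolerances 1e−6 (transcritical, Hopf), 1e−5 (fold), 1e−4
(homoclinic); ODE tolerances rtol 1e−8 / atol 1e−10 (1e−10/1e−12 in the
conservation test). The full acceptance recomputation runs in a few
seconds on one core.

## Limitations

Two species only; no two-parameter continuation (the (K, F) plane is
explored one axis at a time); sub/supercritical Hopf labels rest on
simulated behaviour, not Lyapunov coefficients; the fold-of-limit-cycles
bounding the narrow cycle/equilibrium coexistence slivers next to the
homoclinic window is not detected; no transient-amplification
(reactivity) metrics.
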