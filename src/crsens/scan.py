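"""Gradient sweeps and codimension-1 bifurcation detection.

The environmental gradient is either the resource carrying capacity K
(eutrophication) or the top-consumer intake rate F (predation pressure
on the consumer).  Along a gradient the package tracks every interior
equilibrium branch, evaluates local stability, and locates

* transcritical bifurcations (predator invasion thresholds) by bisection
  on the sign of the interior consumer equilibrium,
* Hopf bifurcations by bisection on the zero crossing of the dominant
  eigenvalue's real part along a branch,
* folds (saddle-node bifurcations) by bisection on the interior
  equilibrium count of the RMS model, and
* homoclinic (global) bifurcations by bisection on the outcome of
  trajectory-based attractor probes -- the one phenomenon invisible to
  local eigenvalue analysis.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from . import models
from .exceptions import (
    BifurcationNotFoundError,
    ConfigurationError,
    IntegrationError,
    UnsupportedVariantError,
)
from .linearize import linearize
from .models import Equilibrium, ModelVariant, boundary_equilibrium_rms
from .params import NonlinearParams, default_gradient_range
from .stability import EigenPair, classify, eigen

__all__ = [
    "GradientSpec",
    "BifurcationEvent",
    "AttractorOutcome",
    "sweep",
    "detect_transcritical",
    "transcritical_closed_form",
    "detect_hopf",
    "detect_fold",
    "attractor_probe",
    "detect_global",
    "events_to_json",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GradientSpec:
    """A one-parameter sweep: which parameter, range, and grid resolution."""

    parameter: str  # "K" or "F"
    lo: float
    hi: float
    n_points: int = 1000

    def __post_init__(self) -> None:
        if self.parameter not in ("K", "F"):
            raise ConfigurationError("gradient parameter must be 'K' or 'F'")
        if not self.lo < self.hi:
            raise ConfigurationError("gradient requires lo < hi")
        if self.n_points < 10:
            raise ConfigurationError("gradient needs at least 10 points")

    @classmethod
    def default(cls, parameter: str, n_points: int = 1000) -> "GradientSpec":
        lo, hi = default_gradient_range(parameter)
        return cls(parameter, lo, hi, n_points)

    def grid(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_points)


@dataclass(frozen=True)
class BifurcationEvent:
    """A detected threshold along a gradient, refined by bisection."""

    kind: str  # transcritical | hopf | fold | homoclinic
    param_value: float
    branch_id: int = 0
    refinement_tol: float = 1e-6
    parameter: str = "K"

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "parameter": self.parameter,
            "param_value": self.param_value,
            "branch_id": self.branch_id,
            "refinement_tol": self.refinement_tol,
        }


class AttractorOutcome(str, enum.Enum):
    SETTLES_TO_EQ = "settles_to_eq"
    LIMIT_CYCLE = "limit_cycle"
    OTHER_ATTRACTOR = "other_attractor"


# ---------------------------------------------------------------------------
# helpers


def _at(params: NonlinearParams, parameter: str, value: float) -> NonlinearParams:
    return params.replace(**{parameter: float(value)})


def _branch_equilibria(variant: ModelVariant, p: NonlinearParams) -> list[Equilibrium]:
    """Feasible interior equilibria of the *parent* model, sorted by A*."""
    parent = variant.parent
    if parent.has_chemostat:
        return models.numeric_equilibria_rms(ModelVariant.RMS, p)
    if p.K == 0 and "logistic" in parent.retained_terms:
        return []  # logistic growth degenerates at the gradient origin
    eq = models.closed_form_equilibria(parent, p)[0]
    return [eq] if eq.feasible and eq.Z_star > 0 else []


def _eigenpair(variant: ModelVariant, p: NonlinearParams, eq: Equilibrium) -> EigenPair:
    """Eigenvalues of ``variant`` at a parent equilibrium, re-linearizing
    the counterpart system at that point when the variant is linearized."""
    if variant.is_nonlinear:
        J = models.jacobian(variant, p, eq)
    else:
        lin = linearize(variant.parent, p, eq, variant.target_dynamics)
        J = models.jacobian(variant, lin, eq)
    return eigen(J)


# ---------------------------------------------------------------------------
# sweep


def sweep(
    variant: ModelVariant,
    params: NonlinearParams,
    grad: GradientSpec,
) -> pd.DataFrame:
    """Equilibria and stability of every branch across a gradient.

    Returns a table with one row per (grid point, branch):
    ``param, branch, A_star, Z_star, re_lambda, im_lambda, regime``.
    Grid points without a feasible interior equilibrium are flagged with
    an ``absent`` regime and NaN densities.  RMS branches are matched
    between neighbouring grid points by nearest A* (jump threshold 10%
    of the scanned A range); a new branch id is allocated whenever a
    fold creates a pair.
    """
    variant = ModelVariant.coerce(variant)
    rows: list[tuple] = []
    active: dict[int, float] = {}  # branch id -> last A*
    next_id = 0
    jump = 0.1 * 1.5 * max(params.K, grad.hi if grad.parameter == "K" else params.K)

    for x in grad.grid():
        p = _at(params, grad.parameter, x)
        try:
            eqs = _branch_equilibria(variant, p)
        except (UnsupportedVariantError, ConfigurationError):
            raise
        except Exception:  # solver failure: flag row, keep sweeping
            logger.warning("equilibrium solve failed at %s=%g", grad.parameter, x)
            eqs = []
        if not eqs:
            rows.append((x, -1, np.nan, np.nan, np.nan, np.nan, "absent"))
            active.clear()
            continue
        # branch continuation by nearest A*
        assigned: dict[int, Equilibrium] = {}
        unmatched = list(eqs)
        for bid, lastA in sorted(active.items()):
            if not unmatched:
                break
            best = min(unmatched, key=lambda e: abs(e.A_star - lastA))
            if abs(best.A_star - lastA) <= jump:
                assigned[bid] = best
                unmatched.remove(best)
        for e in unmatched:
            assigned[next_id] = e
            next_id += 1
        active = {bid: e.A_star for bid, e in assigned.items()}
        for bid, e in sorted(assigned.items()):
            try:
                ep = _eigenpair(variant, p, e)
                regime = classify(ep).value
                re_l, im_l = ep.dominant_real, max(ep.lambda1.imag, ep.lambda2.imag)
            except Exception:
                re_l = im_l = np.nan
                regime = "absent"
            rows.append((x, bid, e.A_star, e.Z_star, re_l, im_l, regime))

    return pd.DataFrame(
        rows,
        columns=["param", "branch", "A_star", "Z_star", "re_lambda", "im_lambda", "regime"],
    )


# ---------------------------------------------------------------------------
# transcritical


def transcritical_closed_form(variant: ModelVariant, params: NonlinearParams) -> float:
    """Closed-form invasion threshold K = A* / (1 - l/r).

    The interior consumer equilibrium crosses zero where the resource
    equilibrium A* (independent of K in all non-RMS variants) meets the
    consumer-free resource level K (1 - l/r).
    """
    variant = ModelVariant.coerce(variant)
    if variant.has_chemostat:
        raise UnsupportedVariantError("no closed-form threshold for the RMS family")
    A_star = models.closed_form_equilibria(variant, params.replace(K=1.0))[0].A_star
    return A_star / (1.0 - params.l / params.r)


def detect_transcritical(
    variant: ModelVariant,
    params: NonlinearParams,
    grad: GradientSpec,
    refinement_tol: float = 1e-6,
) -> BifurcationEvent:
    """Predator invasion threshold by bisection on the sign of Z*."""
    variant = ModelVariant.coerce(variant)
    if variant.has_chemostat:
        raise UnsupportedVariantError(
            "transcritical detection uses closed-form equilibria; not available "
            "for the RMS family"
        )

    def z_star(x: float) -> float:
        p = _at(params, grad.parameter, x)
        return models.closed_form_equilibria(variant, p)[0].Z_star

    grid = grad.grid()
    if grid[0] == 0.0 and grad.parameter == "K":
        grid = grid.copy()
        grid[0] = min(1e-9, grid[1] / 2)
    vals = np.array([z_star(x) for x in grid])
    sign_change = np.nonzero(vals[:-1] * vals[1:] < 0)[0]
    if len(sign_change) == 0:
        raise BifurcationNotFoundError(
            f"Z* does not change sign over {grad.parameter} in "
            f"[{grad.lo}, {grad.hi}] for {variant.value}"
        )
    i = int(sign_change[0])
    lo, hi = float(grid[i]), float(grid[i + 1])
    flo = vals[i]
    while hi - lo > refinement_tol:
        mid = 0.5 * (lo + hi)
        if flo * z_star(mid) <= 0:
            hi = mid
        else:
            lo = mid
            flo = z_star(mid)
    return BifurcationEvent(
        "transcritical", 0.5 * (lo + hi), 0, refinement_tol, grad.parameter
    )


# ---------------------------------------------------------------------------
# Hopf


def detect_hopf(
    variant: ModelVariant,
    params: NonlinearParams,
    grad: GradientSpec,
    branch_id: int = 0,
    refinement_tol: float = 1e-6,
) -> BifurcationEvent:
    """Hopf bifurcation by bisection on Re(lambda) along a branch.

    ``branch_id`` indexes interior equilibria sorted by A*; branch 0 is
    the low-A / high-Z (oscillatory) branch of the RMS model.  A sign
    change with real eigenvalues on either side is rejected rather than
    reported as a Hopf.
    """
    variant = ModelVariant.coerce(variant)

    def pair(x: float) -> EigenPair | None:
        p = _at(params, grad.parameter, x)
        eqs = _branch_equilibria(variant, p)
        if not eqs:
            return None
        eq = eqs[min(branch_id, len(eqs) - 1)]
        return _eigenpair(variant, p, eq)

    grid = grad.grid()
    if grid[0] == 0.0 and grad.parameter == "K":
        grid = grid.copy()
        grid[0] = grid[1] / 2
    prev_x: float | None = None
    prev: EigenPair | None = None
    bracket = None
    for x in grid:
        ep = pair(float(x))
        if ep is not None and prev is not None:
            if prev.dominant_real != 0.0 and ep.dominant_real != 0.0 \
                    and prev.dominant_real * ep.dominant_real < 0:
                bracket = (prev_x, float(x), prev)
                break
        if ep is not None:
            prev_x, prev = float(x), ep
    if bracket is None:
        raise BifurcationNotFoundError(
            f"Re(lambda) does not cross zero for {variant.value} over "
            f"{grad.parameter} in [{grad.lo}, {grad.hi}]"
        )
    lo, hi, plo = bracket
    while hi - lo > refinement_tol:
        mid = 0.5 * (lo + hi)
        ep = pair(mid)
        if ep is None or plo.dominant_real * ep.dominant_real <= 0:
            hi = mid
        else:
            lo, plo = mid, ep
    for side in (lo, hi):
        ep = pair(side)
        if ep is None or not ep.oscillatory:
            raise BifurcationNotFoundError(
                "eigenvalues are real at the Re(lambda) sign change; the event "
                "is a fold or transcritical side-effect, not a Hopf"
            )
    return BifurcationEvent("hopf", 0.5 * (lo + hi), branch_id, refinement_tol, grad.parameter)


# ---------------------------------------------------------------------------
# folds


def detect_fold(
    variant: ModelVariant,
    params: NonlinearParams,
    grad: GradientSpec,
    refinement_tol: float = 1e-5,
) -> list[BifurcationEvent]:
    """Saddle-node bifurcations from changes in interior-equilibrium count.

    Only the nonlinear RMS model carries the cubic equilibrium structure
    that produces folds; every other variant (closed-form or standalone
    linearized counterpart) has a unique interior equilibrium, so the
    list is empty.  Events carry the id of the middle (saddle) branch.
    """
    variant = ModelVariant.coerce(variant)
    if variant is not ModelVariant.RMS:
        return []

    def count(x: float) -> int:
        return len(models.numeric_equilibria_rms(variant, _at(params, grad.parameter, x)))

    grid = grad.grid()
    counts = [count(float(x)) for x in grid]
    events = []
    for i in range(len(grid) - 1):
        if counts[i] != counts[i + 1]:
            lo, hi = float(grid[i]), float(grid[i + 1])
            clo = counts[i]
            while hi - lo > refinement_tol:
                mid = 0.5 * (lo + hi)
                if count(mid) == clo:
                    lo = mid
                else:
                    hi = mid
            events.append(
                BifurcationEvent("fold", 0.5 * (lo + hi), 1, refinement_tol, grad.parameter)
            )
    return sorted(events, key=lambda e: e.param_value)


# ---------------------------------------------------------------------------
# trajectory-based attractor probes


def attractor_probe(
    variant: ModelVariant,
    params,
    eq: Equilibrium,
    horizon: float = 5000.0,
    displacement: float = 0.01,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    settle_tol: float = 1e-3,
) -> AttractorOutcome:
    """Late-time behaviour of the system displaced slightly off ``eq``.

    Integrates the full (nonlinear or linearized) vector field from a
    state displaced by ``displacement`` (relative) off the equilibrium
    with a stiff-capable adaptive integrator, discards the first half of
    the horizon as transient, and classifies the remainder:

    * convergence back to ``eq``  ->  ``SETTLES_TO_EQ``
    * bounded sustained oscillation (successive consumer peaks agree
      within 1% at amplitude > 1e-3)  ->  ``LIMIT_CYCLE``
    * convergence to a different equilibrium  ->  ``OTHER_ATTRACTOR``
    """
    variant = ModelVariant.coerce(variant)
    if not eq.interior:
        raise ConfigurationError("attractor probes start from interior equilibria")
    p = params if isinstance(params, NonlinearParams) else params.params
    y0 = [eq.A_star * (1.0 + displacement), eq.Z_star * (1.0 + displacement)]
    t_eval = np.linspace(horizon / 2.0, horizon, 20000)
    sol = solve_ivp(
        models.make_rhs(variant, params),
        (0.0, horizon),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed for {variant.value}: {sol.message}")
    A, Z = sol.y
    # candidate attracting equilibria at these parameters
    candidates = list(models.equilibria(variant, params))
    if variant.has_chemostat:
        candidates.append(boundary_equilibrium_rms(p))
    scale = max(1.0, eq.A_star, eq.Z_star)
    tail = slice(int(0.9 * len(Z)), None)
    tail_amp = float(np.ptp(Z[tail]))
    if tail_amp < settle_tol:
        fin = np.array([A[-1], Z[-1]])
        dists = [np.hypot(fin[0] - c.A_star, fin[1] - c.Z_star) for c in candidates]
        nearest = candidates[int(np.argmin(dists))]
        same = (
            abs(nearest.A_star - eq.A_star) < 1e-6 * scale
            and abs(nearest.Z_star - eq.Z_star) < 1e-6 * scale
        )
        return AttractorOutcome.SETTLES_TO_EQ if same else AttractorOutcome.OTHER_ATTRACTOR
    peaks, _ = find_peaks(Z)
    if len(peaks) >= 5:
        last5 = Z[peaks[-5:]]
        if float(np.ptp(last5)) < 0.01 * float(np.mean(np.abs(last5))) \
                and float(np.ptp(Z)) > 1e-3:
            return AttractorOutcome.LIMIT_CYCLE
    # oscillation persists but peaks have not converged within the horizon;
    # treat sustained bounded oscillation as a cycle
    return AttractorOutcome.LIMIT_CYCLE


def detect_global(
    params: NonlinearParams,
    grad: GradientSpec,
    *,
    variant: ModelVariant = ModelVariant.RMS,
    fold_events: list[BifurcationEvent] | None = None,
    hopf: BifurcationEvent | None = None,
    refinement_tol: float = 1e-4,
    displacement: float = 0.0025,
    horizon: float = 15000.0,
    rtol: float = 1e-8,
) -> list[BifurcationEvent]:
    """Homoclinic boundaries of the RMS limit cycle by probe bisection.

    Within the bistable window the limit cycle around the low-A branch
    collides with the saddle and disappears; a probe started just off the
    oscillatory equilibrium then escapes to the alternative stable node.
    The two boundaries in F between the ``LIMIT_CYCLE`` and
    ``OTHER_ATTRACTOR`` probe outcomes are refined by bisection.

    The probe displacement defaults to 0.25% here (smaller than the
    generic probe): close to the Hopf point the reborn cycle is small and
    the start point must stay inside the saddle's stable-manifold loop.
    """
    variant = ModelVariant.coerce(variant)
    if variant is not ModelVariant.RMS:
        raise BifurcationNotFoundError(
            f"{variant.value} has no fold/saddle structure: probe outcomes are "
            "identical across the gradient"
        )
    if grad.parameter != "F":
        raise ConfigurationError("global-bifurcation detection scans the F gradient")
    folds = fold_events if fold_events is not None else detect_fold(variant, params, grad)
    if len(folds) != 2:
        raise BifurcationNotFoundError(
            f"expected a bistable window bounded by two folds, found {len(folds)}"
        )
    if hopf is None:
        hopf = detect_hopf(variant, params, grad, branch_id=0)

    def escaped(F: float) -> bool:
        p = _at(params, "F", F)
        eqs = models.numeric_equilibria_rms(variant, p)
        out = attractor_probe(
            variant, p, eqs[0], horizon=horizon, displacement=displacement, rtol=rtol
        )
        return out is AttractorOutcome.OTHER_ATTRACTOR

    def bisect(lo: float, hi: float, escaped_is_high: bool) -> float:
        while hi - lo > refinement_tol:
            mid = 0.5 * (lo + hi)
            if escaped(mid) == escaped_is_high:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    events = []
    # lower boundary: cycle survives just above the lower fold, escapes beyond
    lo = folds[0].param_value + 5e-4
    hi = min(folds[0].param_value + 0.02, hopf.param_value)
    if escaped(lo) or not escaped(hi):
        raise BifurcationNotFoundError("probe outcomes do not bracket a lower boundary")
    events.append(
        BifurcationEvent("homoclinic", bisect(lo, hi, True), 0, refinement_tol, "F")
    )
    # upper boundary: escapes below, bounded (cycle or focus) just under the Hopf
    lo = hopf.param_value - 5e-3
    hi = hopf.param_value - refinement_tol
    if not escaped(lo) or escaped(hi):
        raise BifurcationNotFoundError("probe outcomes do not bracket an upper boundary")
    up = bisect(lo, hi, False)
    events.append(BifurcationEvent("homoclinic", up, 0, refinement_tol, "F"))
    return events


def events_to_json(events: list[BifurcationEvent], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([e.to_dict() for e in events], fh, indent=2)
        fh.write("\n")
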