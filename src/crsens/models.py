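"""Consumer-resource model definitions, equilibria and analytic Jacobians.

Four nonlinear models are supported -- Lotka-Volterra (LV),
Lotka-Volterra-Verhulst (LVV, logistic resource), Rosenzweig-MacArthur
(RM, logistic resource + Holling type II predation) and
Rosenzweig-MacArthur-Scheffer (RMS, adds a Holling type III top-consumer
loss on the consumer and a chemostat resource influx ``l*K``) -- together
with their six equilibrium-preserving linearized counterparts
(see :mod:`crsens.linearize`).

The right-hand side of every variant has the common shape::

    dA/dt = growth(A) - consumption(A, Z) - l*A [+ l*K]
    dZ/dt = e*consumption(A, Z) - m*Z - top_loss(Z)

where each term is either the nonlinear form or its proportional
(linearized) replacement, so a single analytic Jacobian covers all ten
systems.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq

from .exceptions import (
    ConfigurationError,
    DomainError,
    StaleEquilibriumError,
    UnsupportedVariantError,
)
from .params import NonlinearParams

__all__ = [
    "ModelVariant",
    "State",
    "Equilibrium",
    "JacobianMatrix",
    "rhs",
    "closed_form_equilibria",
    "numeric_equilibria_rms",
    "boundary_equilibrium_rms",
    "jacobian",
    "equilibria",
]

logger = logging.getLogger(__name__)

#: Relative tolerance used to certify that a point is an equilibrium.
RESIDUAL_RTOL = 1e-10


class ModelVariant(str, enum.Enum):
    """Closed set of the ten model systems.

    Nonlinear parents: LV, LVV, RM, RMS.  Linearized counterparts carry a
    suffix naming the dynamics imposed on the parent's equilibrium, e.g.
    ``RMS_RM`` is the RMS system with only the type III term linearized
    (RM dynamics retained).
    """

    LV = "LV"
    LVV = "LVV"
    RM = "RM"
    RMS = "RMS"
    LVV_LV = "LVV_LV"
    RM_LV = "RM_LV"
    RM_LVV = "RM_LVV"
    RMS_LV = "RMS_LV"
    RMS_LVV = "RMS_LVV"
    RMS_RM = "RMS_RM"

    @property
    def is_nonlinear(self) -> bool:
        return "_" not in self.value

    @property
    def parent(self) -> "ModelVariant":
        """The nonlinear model this variant analyses (itself if nonlinear)."""
        return ModelVariant(self.value.split("_")[0])

    @property
    def target_dynamics(self) -> "ModelVariant | None":
        """For linearized variants, the dynamics imposed on the parent."""
        if self.is_nonlinear:
            return None
        return ModelVariant(self.value.split("_", 1)[1])

    @property
    def retained_terms(self) -> frozenset[str]:
        """Nonlinear terms kept by this variant's dynamics."""
        base = self if self.is_nonlinear else self.target_dynamics
        kept = {
            ModelVariant.LV: frozenset(),
            ModelVariant.LVV: frozenset({"logistic"}),
            ModelVariant.RM: frozenset({"logistic", "hollingII"}),
            ModelVariant.RMS: frozenset({"logistic", "hollingII", "hollingIII"}),
        }[base]
        if not self.is_nonlinear:
            # a linearized variant can only retain what its parent has
            kept = kept & self.parent.retained_terms
        return kept

    @property
    def has_chemostat(self) -> bool:
        """True for the RMS family (constant resource influx ``l*K``)."""
        return self.parent is ModelVariant.RMS

    @classmethod
    def coerce(cls, tag: "str | ModelVariant") -> "ModelVariant":
        try:
            return cls(tag)
        except ValueError as exc:
            raise ConfigurationError(f"unknown model variant {tag!r}") from exc


class State(NamedTuple):
    """Instantaneous (resource, consumer) densities."""

    A: float
    Z: float


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point (A*, Z*) of one of the model systems.

    ``interior`` is True when the consumer coexists (Z* > 0);
    infeasible interior solutions (Z* <= 0) are returned flagged rather
    than dropped so that transcritical detection can bisect on the sign
    of Z*.  ``branch_id`` distinguishes coexisting RMS solutions
    (ordered by A*).
    """

    A_star: float
    Z_star: float
    interior: bool
    branch_id: int = 0

    @property
    def feasible(self) -> bool:
        return not self.interior or self.Z_star > 0


@dataclass(frozen=True)
class JacobianMatrix:
    """2x2 community matrix evaluated at an equilibrium (entries time^-1)."""

    J11: float
    J12: float
    J21: float
    J22: float

    @property
    def trace(self) -> float:
        return self.J11 + self.J22

    @property
    def det(self) -> float:
        return self.J11 * self.J22 - self.J12 * self.J21

    def as_array(self) -> np.ndarray:
        return np.array([[self.J11, self.J12], [self.J21, self.J22]])


# ---------------------------------------------------------------------------
# term dispatch


@dataclass(frozen=True)
class _Dynamics:
    """Resolved term structure of one variant: which terms are nonlinear,
    and the effective proportional coefficients where they are not."""

    p: NonlinearParams
    logistic: bool
    holling2: bool
    holling3: bool
    chemostat: bool
    r_eff: float  # used when logistic growth is linearized away
    g_eff: float  # used when the type II response is linearized away
    f_eff: float  # linear top-consumer loss coefficient (0 outside RMS family)


def _resolve(variant: ModelVariant, params) -> _Dynamics:
    variant = ModelVariant.coerce(variant)
    kept = variant.retained_terms
    if variant.is_nonlinear:
        if not isinstance(params, NonlinearParams):
            raise ConfigurationError(
                f"nonlinear variant {variant.value} requires NonlinearParams, "
                f"got {type(params).__name__}"
            )
        p = params
        return _Dynamics(
            p=p,
            logistic="logistic" in kept,
            holling2="hollingII" in kept,
            holling3="hollingIII" in kept,
            chemostat=variant.has_chemostat,
            r_eff=p.r,
            g_eff=p.g,
            f_eff=0.0,
        )
    # linearized system: duck-typed on the LinearizedSystem attributes so the
    # linearize module can stay a downstream consumer of this one
    for attr in ("r_lin", "g_lin", "F_lin", "params", "variant"):
        if not hasattr(params, attr):
            raise ConfigurationError(
                f"linearized variant {variant.value} requires a LinearizedSystem"
            )
    if ModelVariant.coerce(params.variant) is not variant:
        raise ConfigurationError(
            f"system was built for {params.variant}, not {variant.value}"
        )
    p = params.params
    return _Dynamics(
        p=p,
        logistic="logistic" in kept,
        holling2="hollingII" in kept,
        holling3=False,
        chemostat=variant.has_chemostat,
        r_eff=p.r if "logistic" in kept else params.r_lin,
        g_eff=p.g if "hollingII" in kept else params.g_lin,
        f_eff=params.F_lin if variant.has_chemostat else 0.0,
    )


def _rhs_resolved(d: _Dynamics, A: float, Z: float) -> tuple[float, float]:
    p = d.p
    growth = p.r * A * (1.0 - A / p.K) if d.logistic else d.r_eff * A
    consumption = p.g * Z * A / (A + p.a) if d.holling2 else d.g_eff * Z * A
    if d.holling3:
        top_loss = p.F * Z * Z / (Z * Z + p.z * p.z)
    else:
        top_loss = d.f_eff * Z
    dA = growth - consumption - p.l * A
    if d.chemostat:
        dA += p.l * p.K
    dZ = p.e * consumption - p.m * Z - top_loss
    return dA, dZ


def rhs(variant: ModelVariant, params, state) -> tuple[float, float]:
    """Instantaneous derivatives (dA/dt, dZ/dt) of the selected system.

    ``params`` is a :class:`~crsens.params.NonlinearParams` for the four
    nonlinear variants and a :class:`~crsens.linearize.LinearizedSystem`
    for the six linearized ones.
    """
    A, Z = state
    if not (math.isfinite(A) and math.isfinite(Z)):
        raise DomainError("state must be finite")
    if A < 0 or Z < 0:
        raise DomainError(f"negative density in state ({A}, {Z})")
    return _rhs_resolved(_resolve(variant, params), A, Z)


def make_rhs(variant: ModelVariant, params):
    """Vector field ``f(t, y)`` for ODE integration.

    Unlike :func:`rhs`, the returned callable tolerates the slightly
    negative densities an adaptive integrator may probe.
    """
    d = _resolve(variant, params)

    def f(t, y):
        return _rhs_resolved(d, y[0], y[1])

    return f


# ---------------------------------------------------------------------------
# equilibria


def _interior_closed_form(variant: ModelVariant, p: NonlinearParams) -> Equilibrium:
    # linearized counterparts share their parent's equilibrium by construction
    # (their proportional coefficients are built from it), so the closed forms
    # are always the parent's
    kept = variant.parent.retained_terms
    if "hollingII" in kept:
        denom = p.e * p.g - p.m
        if denom <= 0:
            # consumer cannot sustain itself at any resource density
            return Equilibrium(math.inf, -math.inf, interior=True)
        A_star = p.a * p.m / denom
        Z_star = (p.r * (1.0 - A_star / p.K) - p.l) * (A_star + p.a) / p.g
    else:
        A_star = p.m / (p.e * p.g)
        if "logistic" in kept:
            Z_star = (p.r * (1.0 - A_star / p.K) - p.l) / p.g
        else:  # pure LV
            Z_star = (p.r - p.l) / p.g
    return Equilibrium(A_star, Z_star, interior=True)


def closed_form_equilibria(
    variant: ModelVariant, params: NonlinearParams
) -> list[Equilibrium]:
    """Closed-form equilibria of a non-RMS variant.

    Returns the interior equilibrium (flagged infeasible when Z* <= 0)
    followed by the consumer-free boundary equilibrium.  Linearized
    variants share the interior expressions of their nonlinear parent by
    construction, so they are evaluated from the parent's parameters.
    """
    variant = ModelVariant.coerce(variant)
    if variant.has_chemostat:
        raise UnsupportedVariantError(
            f"{variant.value} has no closed-form equilibria; "
            "use numeric_equilibria_rms"
        )
    if not isinstance(params, NonlinearParams):
        raise ConfigurationError("closed_form_equilibria expects NonlinearParams")
    out = [_interior_closed_form(variant, params)]
    if "logistic" in variant.parent.retained_terms:
        A_b = params.K * (1.0 - params.l / params.r)
        out.append(Equilibrium(max(A_b, 0.0), 0.0, interior=False, branch_id=1))
    else:
        out.append(Equilibrium(0.0, 0.0, interior=False, branch_id=1))
    return out


def _rms_Z_of_A(p: NonlinearParams, A: np.ndarray, influx: bool) -> np.ndarray:
    """Consumer density on the resource nullcline of the RMS model."""
    inflow = p.l * p.K if influx else 0.0
    return (p.r * A * (1.0 - A / p.K) - p.l * A + inflow) * (A + p.a) / (p.g * A)


def _rms_residual(p: NonlinearParams, A: np.ndarray, influx: bool) -> np.ndarray:
    """Per-time consumer net growth along the resource nullcline.

    Scalar reduction of the 2-D fixed-point problem: substitute Z(A) from
    dA/dt = 0 into dZ/dt; interior equilibria are the positive-Z roots.
    """
    Z = _rms_Z_of_A(p, A, influx)
    return p.e * p.g * Z * A / (A + p.a) - p.m * Z - p.F * Z**2 / (Z**2 + p.z**2)


def numeric_equilibria_rms(
    variant: ModelVariant,
    params: NonlinearParams,
    search_interval: tuple[float, float] | None = None,
    *,
    influx: bool = True,
    n_scan: int = 2000,
) -> list[Equilibrium]:
    """Interior equilibria of the RMS family by scan-and-polish root finding.

    The resource equation is solved for Z(A) and substituted into the
    consumer equation, leaving one scalar residual in A.  The residual is
    scanned on ``n_scan`` log-spaced points (plus the same number of
    uniform points, which resolve the near-carrying-capacity root pair
    close to the lower fold), sign changes are bracketed and polished by
    Brent bisection to 1e-10, and near-duplicate roots are merged.

    The consumer-free boundary state (Z = 0) is excluded; see
    :func:`boundary_equilibrium_rms`.  ``influx=False`` drops the
    chemostat term (with F = 0 this reduces the system to RM, a
    cross-check used in the tests).  Returns 1 or 3 equilibria for
    default-like parameters; an empty list (with a logged warning) when
    no sign change is found.
    """
    variant = ModelVariant.coerce(variant)
    if not variant.has_chemostat:
        raise UnsupportedVariantError(
            f"{variant.value} has closed-form equilibria; use closed_form_equilibria"
        )
    p = params if isinstance(params, NonlinearParams) else params.params
    lo, hi = search_interval if search_interval else (1e-6, 1.5 * p.K)
    if lo <= 0 or hi <= lo:
        raise ConfigurationError("search interval must be positive and increasing")
    grid = np.unique(
        np.concatenate([np.geomspace(lo, hi, n_scan), np.linspace(lo, hi, n_scan)])
    )
    Z = _rms_Z_of_A(p, grid, influx)
    res = _rms_residual(p, grid, influx)
    ok = np.isfinite(res) & (Z > 0)

    roots: list[float] = []
    f = lambda A: float(_rms_residual(p, np.asarray(A, dtype=float), influx))
    for i in range(len(grid) - 1):
        if ok[i] and ok[i + 1] and res[i] * res[i + 1] < 0:
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-12))
        elif ok[i] and res[i] == 0.0:
            roots.append(float(grid[i]))

    # dedupe (relative 1e-8) and drop boundary-grazing roots with Z ~ 0
    roots.sort()
    merged: list[float] = []
    for A in roots:
        if merged and abs(A - merged[-1]) <= 1e-8 * max(1.0, abs(A)):
            continue
        merged.append(A)
    out = []
    for k, A in enumerate(merged):
        Zk = float(_rms_Z_of_A(p, np.asarray(A), influx))
        if Zk > 1e-9 * max(1.0, p.K):
            out.append(Equilibrium(float(A), Zk, interior=True, branch_id=len(out)))
    if not out:
        logger.warning(
            "no interior equilibrium found for %s in A-interval (%g, %g)",
            variant.value, lo, hi,
        )
    return out


def boundary_equilibrium_rms(params: NonlinearParams) -> Equilibrium:
    """The consumer-free state (K, 0) of the RMS model.

    With the chemostat influx the resource equation at Z = 0 balances
    exactly at A = K.  Reported separately because bifurcation branches
    track interior equilibria only.
    """
    return Equilibrium(params.K, 0.0, interior=False, branch_id=-1)


def equilibria(variant: ModelVariant, params) -> list[Equilibrium]:
    """All interior equilibria of a variant (closed form or numeric)."""
    variant = ModelVariant.coerce(variant)
    if variant.has_chemostat:
        p = params if isinstance(params, NonlinearParams) else params.params
        return numeric_equilibria_rms(ModelVariant.RMS, p)
    p = params if isinstance(params, NonlinearParams) else params.params
    return [eq for eq in closed_form_equilibria(variant, p) if eq.interior]


# ---------------------------------------------------------------------------
# Jacobian


def residual_norm(variant: ModelVariant, params, eq: Equilibrium) -> float:
    dA, dZ = rhs(variant, params, (eq.A_star, eq.Z_star))
    return max(abs(dA), abs(dZ))


def jacobian(
    variant: ModelVariant,
    params,
    eq: Equilibrium,
    *,
    rtol: float = 1e-8,
) -> JacobianMatrix:
    """Analytic Jacobian of the selected system at an equilibrium.

    Uses the closed-form partial derivatives of each term, never finite
    differences.  Structural zeros are returned exactly: at an interior
    equilibrium the consumer row diagonal ``J22`` vanishes identically
    whenever the consumer equation is linear in Z (every variant except
    the nonlinear RMS), and ``J11`` vanishes for fully proportional
    resource equations without chemostat influx (LV, LVV_LV, RM_LV).

    Raises
    ------
    StaleEquilibriumError
        If the right-hand side at ``eq`` exceeds ``rtol * max(1, A*, Z*)``.
    """
    d = _resolve(variant, params)
    A, Z = eq.A_star, eq.Z_star
    scale = max(1.0, abs(A), abs(Z))
    if residual_norm(variant, params, eq) > rtol * scale:
        raise StaleEquilibriumError(
            f"({A}, {Z}) is not an equilibrium of {ModelVariant.coerce(variant).value}"
        )
    p = d.p
    growth_dA = p.r * (1.0 - 2.0 * A / p.K) if d.logistic else d.r_eff
    if d.holling2:
        cons_dA = p.g * Z * p.a / (A + p.a) ** 2
        cons_dZ = p.g * A / (A + p.a)
    else:
        cons_dA = d.g_eff * Z
        cons_dZ = d.g_eff * A
    if d.holling3:
        top_dZ = 2.0 * p.F * Z * p.z**2 / (Z**2 + p.z**2) ** 2
    else:
        top_dZ = d.f_eff

    J11 = growth_dA - cons_dA - p.l
    J22 = p.e * cons_dZ - p.m - top_dZ
    if eq.interior:
        if not d.holling3:
            # per-capita consumer growth is zero at an interior equilibrium
            J22 = 0.0
        if not (d.logistic or d.chemostat):
            J11 = 0.0
    return JacobianMatrix(J11, -cons_dZ, p.e * cons_dA, J22)
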