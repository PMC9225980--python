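"""Nullclines, trajectories and phase-plane geometry.

Every variant's nullclines have closed forms.  Setting dA/dt = 0 and
solving for Z gives the resource nullcline Z_res(A); setting the
consumer's per-capita growth to zero gives the consumer nullcline --
a vertical line A = const except for the nonlinear RMS, where the
type III loss makes the critical resource level depend on Z.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import models
from .exceptions import ConfigurationError, IntegrationError
from .models import ModelVariant
from .params import NonlinearParams

__all__ = ["Curve", "CurveKind", "nullclines", "trajectory", "default_window"]


class CurveKind(str, enum.Enum):
    RESOURCE_NULLCLINE = "resource_nullcline"
    CONSUMER_NULLCLINE = "consumer_nullcline"
    TRAJECTORY = "trajectory"


@dataclass(frozen=True)
class Curve:
    """An ordered polyline in the (A, Z) plane."""

    which: CurveKind
    points: np.ndarray  # shape (n, 2)
    t: np.ndarray | None = None  # sampling times, trajectories only

    @property
    def A(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def Z(self) -> np.ndarray:
        return self.points[:, 1]


def _resolved(variant: ModelVariant, params):
    """(base params, g_eff, r_eff, F_eff-linear, flags) for nullcline algebra."""
    variant = ModelVariant.coerce(variant)
    kept = variant.retained_terms
    if variant.is_nonlinear:
        p = params
        r_eff, g_eff, f_eff = p.r, p.g, 0.0
    else:
        p = params.params
        r_eff = p.r if "logistic" in kept else params.r_lin
        g_eff = p.g if "hollingII" in kept else params.g_lin
        f_eff = params.F_lin
    return p, kept, r_eff, g_eff, f_eff


def default_window(variant: ModelVariant, params) -> tuple[float, float]:
    """Plotting window (A_max, Z_max) scaled to the equilibria and K."""
    p = params if isinstance(params, NonlinearParams) else params.params
    eqs = models.equilibria(variant, params)
    A_max = 1.2 * max([p.K] + [e.A_star for e in eqs])
    Z_max = 1.5 * max([1.0] + [e.Z_star for e in eqs])
    return A_max, Z_max


def nullclines(
    variant: ModelVariant,
    params,
    window: tuple[float, float] | None = None,
    resolution: int = 400,
) -> list[Curve]:
    """Both nontrivial nullclines inside the plotting window.

    The trivial axis nullclines (A = 0 without chemostat influx, Z = 0)
    are not emitted.
    """
    variant = ModelVariant.coerce(variant)
    if window is None:
        window = default_window(variant, params)
    A_max, Z_max = window
    if A_max <= 0 or Z_max <= 0:
        raise ConfigurationError("window bounds must be positive")
    p, kept, r_eff, g_eff, f_eff = _resolved(variant, params)

    # resource nullcline: Z as a function of A
    A = np.linspace(A_max / resolution, A_max, resolution)
    growth = p.r * A * (1.0 - A / p.K) if "logistic" in kept else r_eff * A
    influx = p.l * p.K if variant.has_chemostat else 0.0
    per_Z = p.g * A / (A + p.a) if "hollingII" in kept else g_eff * A
    Z_res = (growth - p.l * A + influx) / per_Z
    mask = (Z_res >= 0) & (Z_res <= Z_max)
    curves = [
        Curve(CurveKind.RESOURCE_NULLCLINE, np.column_stack([A[mask], Z_res[mask]]))
    ]

    # consumer nullcline: critical resource level, possibly Z-dependent
    Z = np.linspace(0.0, Z_max, resolution)
    if "hollingIII" in kept:
        q = p.m + p.F * Z / (Z * Z + p.z * p.z)
    else:
        q = np.full_like(Z, p.m + (f_eff if variant.has_chemostat else 0.0))
    if "hollingII" in kept:
        with np.errstate(divide="ignore", invalid="ignore"):
            A_con = p.a * q / (p.e * p.g - q)
        good = (q < p.e * p.g) & np.isfinite(A_con)
    else:
        A_con = q / (p.e * g_eff)
        good = np.isfinite(A_con)
    good &= (A_con >= 0) & (A_con <= A_max)
    curves.append(
        Curve(CurveKind.CONSUMER_NULLCLINE, np.column_stack([A_con[good], Z[good]]))
    )
    return curves


def trajectory(
    variant: ModelVariant,
    params,
    initial,
    horizon: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_sample: int = 4000,
) -> Curve:
    """Integrate one orbit with a stiff-capable adaptive integrator."""
    A0, Z0 = initial
    if A0 < 0 or Z0 < 0:
        raise ConfigurationError("initial state must be nonnegative")
    t_eval = np.linspace(0.0, horizon, n_sample)
    sol = solve_ivp(
        models.make_rhs(variant, params),
        (0.0, horizon),
        [A0, Z0],
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    return Curve(CurveKind.TRAJECTORY, np.column_stack([sol.y[0], sol.y[1]]), sol.t)
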