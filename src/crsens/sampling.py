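"""Virtual observations: equilibria treated as field data.

Empirical food-web models are parameterized from observed biomass
densities and material fluxes under the assumption of proportional
interactions.  This module emulates that construction inside the model
world: an equilibrium of a nonlinear model is "sampled" as an
observation of standing stocks and fluxes, optionally blurred with
multiplicative lognormal observation noise, and a Lotka-Volterra-type
system is fitted back from the observation alone.  At zero noise the
fit coincides exactly with the analytic equilibrium-preserving
linearization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DomainError
from .linearize import LinearizedSystem
from .models import Equilibrium, ModelVariant
from .params import NonlinearParams

__all__ = ["FluxObservation", "sample_observation", "fit_linear_from_observation"]


@dataclass(frozen=True)
class FluxObservation:
    """Observed equilibrium densities and per-time material fluxes.

    ``production_flux`` is the resource's gross growth, ``consumption_flux``
    the resource-to-consumer flow, ``top_loss_flux`` the consumer's loss to
    the (implicit) top consumer.  ``noise_sigma = 0`` means the observation
    equals the model's term values exactly.
    """

    parent_variant: ModelVariant
    A_obs: float
    Z_obs: float
    production_flux: float
    consumption_flux: float
    top_loss_flux: float
    noise_sigma: float = 0.0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "parent_variant": self.parent_variant.value,
            "A_obs": self.A_obs,
            "Z_obs": self.Z_obs,
            "production_flux": self.production_flux,
            "consumption_flux": self.consumption_flux,
            "top_loss_flux": self.top_loss_flux,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path: str) -> "FluxObservation":
        with open(path) as fh:
            d = json.load(fh)
        d["parent_variant"] = ModelVariant.coerce(d["parent_variant"])
        return cls(**d)


def sample_observation(
    variant: ModelVariant,
    params: NonlinearParams,
    eq: Equilibrium,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> FluxObservation:
    """Evaluate each model term at an interior equilibrium as an observation.

    With ``noise_sigma > 0`` each observed quantity is multiplied by an
    independent lognormal factor ``exp(sigma * N(0, 1))``; the draws are a
    fixed-order function of ``seed`` (quantity order: A, Z, production,
    consumption, top loss), so observations are reproducible.
    """
    variant = ModelVariant.coerce(variant)
    if not variant.is_nonlinear:
        raise ConfigurationError("observations are sampled from the nonlinear models")
    if not eq.interior or eq.Z_star <= 0:
        raise DomainError("observations require a feasible interior equilibrium")
    p = params
    A, Z = eq.A_star, eq.Z_star
    kept = variant.retained_terms
    production = p.r * A * (1.0 - A / p.K) if "logistic" in kept else p.r * A
    consumption = p.g * Z * A / (A + p.a) if "hollingII" in kept else p.g * Z * A
    top_loss = p.F * Z * Z / (Z * Z + p.z * p.z) if "hollingIII" in kept else 0.0

    values = np.array([A, Z, production, consumption, top_loss])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values * np.exp(noise_sigma * rng.standard_normal(5))
    return FluxObservation(
        parent_variant=variant,
        A_obs=float(values[0]),
        Z_obs=float(values[1]),
        production_flux=float(values[2]),
        consumption_flux=float(values[3]),
        top_loss_flux=float(values[4]),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def fit_linear_from_observation(
    obs: FluxObservation,
    carried: NonlinearParams,
) -> LinearizedSystem:
    """Recover a fully linear (LV-dynamics) system from one observation.

    The proportional coefficients are flux-per-stock ratios::

        r_lin = production / A_obs
        g_lin = consumption / (A_obs * Z_obs)
        F_lin = top_loss / Z_obs

    which at zero noise reproduce the analytic linearization exactly.
    ``carried`` supplies the parameters that survive unchanged
    (l, e, m, K, ...).
    """
    if obs.A_obs <= 0 or obs.Z_obs <= 0:
        raise DomainError("observed biomasses must be positive")
    parent = obs.parent_variant
    if parent is ModelVariant.LV:
        raise ConfigurationError("the LV model is already fully linear")
    variant = ModelVariant.coerce(f"{parent.value}_LV")
    return LinearizedSystem(
        variant=variant,
        parent_variant=parent,
        params=carried,
        r_lin=obs.production_flux / obs.A_obs,
        g_lin=obs.consumption_flux / (obs.A_obs * obs.Z_obs),
        F_lin=obs.top_loss_flux / obs.Z_obs,
        retained_terms=frozenset(),
        parent_equilibrium=Equilibrium(obs.A_obs, obs.Z_obs, interior=True),
    )
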