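"""Parameter sets for the consumer-resource models.

The default parameterization is the classical algae-zooplankton set used
throughout the shallow-lake literature (Scheffer et al. 1997), shipped with
the package as a small TOML fixture.  Densities are in resource/consumer
units, rates per unit time.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from importlib import resources

from .exceptions import ConfigurationError

__all__ = ["NonlinearParams", "default_params", "default_gradient_range", "load_params"]


@dataclass(frozen=True)
class NonlinearParams:
    """Parameters of the nonlinear consumer-resource models.

    Attributes
    ----------
    r : float
        Maximum per-capita growth rate of the resource (time^-1).
    K : float
        Carrying capacity of the resource (resource units).
    g : float
        Maximum intake rate of the consumer.  For mass-action (type I)
        interaction this is per consumer unit per time; with a Holling
        type II response it is resource units per consumer unit per time.
    a : float
        Half-saturation density of the consumer on the resource
        (resource units).
    l : float
        Resource loss rate (time^-1); also sets the chemostat influx
        ``l*K`` of the RMS model.
    e : float
        Consumer-resource conversion efficiency (consumer unit per
        resource unit), in (0, 1].
    m : float
        Consumer loss rate (time^-1).
    F : float
        Maximum intake rate of the (implicit) top-consumer
        (consumer units time^-1), >= 0.
    z : float
        Half-saturation density of the top-consumer on the consumer
        (consumer units).
    """

    r: float
    K: float
    g: float
    a: float
    l: float
    e: float
    m: float
    F: float = 0.0
    z: float = 0.5

    def __post_init__(self) -> None:
        for name in ("r", "g", "a", "l", "e", "m", "z"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"parameter {name!r} must be strictly positive")
        if self.K < 0 or self.F < 0:
            raise ConfigurationError("K and F must be >= 0")
        if self.e > 1:
            raise ConfigurationError("conversion efficiency e must be <= 1")

    def replace(self, **changes: float) -> "NonlinearParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


def _read_fixture() -> dict:
    text = resources.files("crsens.data").joinpath("table1.toml").read_bytes()
    return tomllib.loads(text.decode())


def default_params(**overrides: float) -> NonlinearParams:
    """The packaged default (algae-zooplankton) parameter set.

    Keyword overrides replace individual fields, e.g.
    ``default_params(K=5.0)``.
    """
    cfg = _read_fixture()["params"]
    cfg.update(overrides)
    return NonlinearParams(**cfg)


def default_gradient_range(parameter: str) -> tuple[float, float]:
    """Default sweep range for an environmental gradient parameter (K or F)."""
    cfg = _read_fixture()["gradients"]
    if parameter not in cfg:
        raise ConfigurationError(f"no default gradient range for parameter {parameter!r}")
    lo, hi = cfg[parameter]
    return float(lo), float(hi)


def load_params(path: str) -> NonlinearParams:
    """Load a parameter set from a TOML file with a ``[params]`` table."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return NonlinearParams(**cfg["params"])
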