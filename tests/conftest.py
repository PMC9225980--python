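import numpy as np
import pytest

from crsens import GradientSpec, ModelVariant, default_params

NONLINEAR = [ModelVariant.LV, ModelVariant.LVV, ModelVariant.RM, ModelVariant.RMS]
LINEARIZED = [
    ModelVariant.LVV_LV,
    ModelVariant.RM_LV,
    ModelVariant.RM_LVV,
    ModelVariant.RMS_LV,
    ModelVariant.RMS_LVV,
    ModelVariant.RMS_RM,
]


@pytest.fixture(scope="session")
def table1():
    """Default algae-zooplankton parameter set."""
    return default_params()


@pytest.fixture(scope="session")
def grad_K():
    return GradientSpec.default("K")


@pytest.fixture(scope="session")
def grad_F():
    return GradientSpec.default("F")


def random_params(rng: np.random.Generator, variant: ModelVariant):
    """A random parameter draw in the neighbourhood of the default set,
    resampled until the variant has a feasible interior equilibrium."""
    from crsens import equilibria

    base = default_params()
    for _ in range(200):
        scale = rng.uniform(0.7, 1.4, size=7)
        p = base.replace(
            r=base.r * scale[0],
            g=base.g * scale[1],
            a=base.a * scale[2],
            l=base.l * scale[3],
            e=min(base.e * scale[4], 1.0),
            m=base.m * scale[5],
            z=base.z * scale[6],
            K=rng.uniform(2.0, 10.0),
            F=rng.uniform(0.01, 0.3) if variant.has_chemostat else 0.0,
        )
        eqs = [e for e in equilibria(variant.parent, p) if e.Z_star > 0]
        if eqs:
            return p, eqs
    raise RuntimeError("could not draw feasible parameters")
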