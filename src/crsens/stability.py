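"""Eigenvalues and local-stability regimes of 2x2 community matrices.

The eigenvalues of a 2x2 Jacobian are the roots of
``lambda^2 - tr(J) lambda + det(J)``; the real part of the dominant root
is the recovery rate after a small perturbation (engineering
resilience, with sign flipped).  Regimes follow the classical
trace-determinant classification: node/focus by the discriminant sign,
stable/unstable by the dominant real part, saddle for a negative
determinant, and a neutral center when a conjugate pair sits on the
imaginary axis (the structural case for conservative Lotka-Volterra
dynamics).
"""

from __future__ import annotations

import cmath
import enum
from dataclasses import dataclass

from .models import JacobianMatrix

__all__ = ["EigenPair", "RegimeLabel", "eigen", "classify", "NEUTRAL_TOL"]

#: Default absolute tolerance (time^-1) for calling a conjugate pair neutral.
NEUTRAL_TOL = 1e-9


@dataclass(frozen=True)
class EigenPair:
    """The two eigenvalues of a 2x2 Jacobian, conjugate-closed when complex."""

    lambda1: complex
    lambda2: complex

    @property
    def dominant_real(self) -> float:
        """Real part of the dominant eigenvalue, Re(lambda)."""
        return max(self.lambda1.real, self.lambda2.real)

    @property
    def oscillatory(self) -> bool:
        return self.lambda1.imag != 0.0 or self.lambda2.imag != 0.0


class RegimeLabel(str, enum.Enum):
    STABLE_NODE = "stable_node"
    STABLE_FOCUS = "stable_focus"
    NEUTRAL_CENTER = "neutral_center"
    UNSTABLE_FOCUS = "unstable_focus"
    UNSTABLE_NODE = "unstable_node"
    SADDLE = "saddle"


def eigen(J: JacobianMatrix) -> EigenPair:
    """Closed-form eigenvalues of ``J`` from the characteristic quadratic."""
    tr, det = J.trace, J.det
    disc = tr * tr - 4.0 * det
    if disc >= 0.0:
        s = disc**0.5
        return EigenPair(complex((tr + s) / 2.0), complex((tr - s) / 2.0))
    s = cmath.sqrt(complex(disc))
    return EigenPair((tr + s) / 2.0, (tr - s) / 2.0)


def classify(eig: EigenPair, neutral_tol: float = NEUTRAL_TOL) -> RegimeLabel:
    """Trace-determinant regime of an eigenvalue pair.

    A conjugate pair within ``neutral_tol`` of the imaginary axis is a
    neutral center.  Real eigenvalues near zero are *not* reported as
    neutral -- they sit on the stable or unstable side of a transcritical
    exchange, and neutrality is structural only for conservative
    Lotka-Volterra dynamics.
    """
    l1, l2 = eig.lambda1, eig.lambda2
    if eig.oscillatory:
        re = eig.dominant_real
        if abs(re) <= neutral_tol:
            return RegimeLabel.NEUTRAL_CENTER
        return RegimeLabel.STABLE_FOCUS if re < 0 else RegimeLabel.UNSTABLE_FOCUS
    if l1.real * l2.real < 0:
        return RegimeLabel.SADDLE
    return RegimeLabel.STABLE_NODE if eig.dominant_real <= 0 else RegimeLabel.UNSTABLE_NODE
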