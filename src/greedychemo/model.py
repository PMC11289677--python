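"""Physical parameters of the greedy-chemotaxis model.

A spherical cell of radius ``a`` moves at constant speed ``v`` toward the
direction of the most recently absorbed cue particle.  Cues are released
from a point source at Poissonian rate ``alpha`` and diffuse with
diffusivity ``D``; the cell absorbs every cue touching its surface.

Two derived quantities control the behaviour:

* ``epsilon = alpha * a / v`` — ratio of the cue release rate to the
  inverse time the cell needs to travel one radius.  Mean run statistics
  are finite only for ``epsilon > 1``.
* ``rh = alpha * a**2 / v`` — the homing radius, the distance at which
  the mean per-run radial displacement changes sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


class DivergentStatisticsError(ValueError):
    """Raised when a mean run statistic is requested at epsilon <= 1.

    Individual runs remain well defined in this regime, but their
    expectation values diverge (power-law tail with exponent -1-epsilon).
    """


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the model, all strictly positive.

    Parameters
    ----------
    a : float
        Cell radius (length).
    v : float
        Cell speed (length / time).
    alpha : float
        Cue release rate of the point source (1 / time).
    D : float
        Cue diffusivity (length**2 / time).
    """

    a: float
    v: float
    alpha: float
    D: float

    def __post_init__(self) -> None:
        for name in ("a", "v", "alpha", "D"):
            value = getattr(self, name)
            if not (value > 0.0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    @property
    def epsilon(self) -> float:
        """Dimensionless release rate, alpha*a/v."""
        return self.alpha * self.a / self.v

    @property
    def rh(self) -> float:
        """Homing radius alpha*a**2/v (== epsilon * a)."""
        return self.alpha * self.a**2 / self.v

    def require_finite_statistics(self) -> None:
        """Raise :class:`DivergentStatisticsError` unless epsilon > 1."""
        if self.epsilon <= 1.0:
            raise DivergentStatisticsError(
                f"mean run statistics diverge for epsilon <= 1 (epsilon = {self.epsilon:g})"
            )


@dataclass(frozen=True)
class ImageCharge:
    """Fictitious negative source enforcing absorption on the cell surface.

    For a real source of strength ``alpha`` at distance ``rs`` from the
    centre of an absorbing sphere of radius ``a``, the image has strength
    ``-alpha*a/rs`` and sits at distance ``a**2/rs`` from the centre, on
    the centre-to-source axis.
    """

    strength: float
    position: float


def homing_radius(p: ModelParams) -> float:
    """Homing radius rh = alpha*a**2/v.

    Beyond rh the mean per-run radial displacement is positive (cells
    retreat on average); inside it is negative.  The interpretation as a
    sign-change radius requires epsilon > 1; otherwise rh <= a and a
    warning is emitted (the cell radius would exceed the homing radius,
    outside the validity regime of the mean-run formulas).
    """
    rh = p.alpha * p.a**2 / p.v
    if p.epsilon <= 1.0:
        warnings.warn(
            "epsilon <= 1: homing radius does not exceed the cell radius; "
            "mean run statistics diverge in this regime",
            stacklevel=2,
        )
    return rh
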