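"""Closed-form reference solutions for the transport solver.

These are independent of the finite-volume solver and serve as test oracles:

* a semi-infinite drift-diffusion first-passage solution, valid while the
  depletion layer above the absorbing bottom is thin compared to the media
  height;
* the eigenfunction series for pure diffusion in a slab with an absorbing
  bottom and reflecting top, valid at all times when sedimentation is
  negligible;
* the plug-flow limit for pure sedimentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import erfc, erfcx


@dataclass(frozen=True)
class OracleResult:
    """A closed-form delivered fraction plus a validity flag."""

    fraction_delivered: float
    valid: bool


def _absorbed_probability(x: float, v: float, d: float, t: float) -> float:
    """Probability that a particle starting at height x above an absorbing
    plane, drifting toward it at speed v with diffusivity d, has been
    absorbed by time t.

    The second term e^{vx/D} erfc((x+vt)/(2 sqrt(Dt))) overflows at high
    Peclet number; it is evaluated in scaled form via erfcx, for which the
    combined exponent collapses to -((x-vt)^2/(4Dt)).
    """
    s = 2.0 * math.sqrt(d * t)
    a = (x - v * t) / s
    b = (x + v * t) / s
    return 0.5 * erfc(a) + 0.5 * erfcx(b) * math.exp(-a * a)


def semi_infinite_first_passage(
    velocity: float, diffusivity: float, media_height: float, t: float
) -> OracleResult:
    """Delivered fraction from the semi-infinite first-passage solution.

    For a uniform initial suspension the delivered fraction is the
    column-average absorption probability, (1/L) * int_0^inf P(x, t) dx.
    Valid while the depleted layer is thin: 2 sqrt(Dt) + Vt <= 0.2 L
    (otherwise the missing top boundary matters and the result only bounds
    the true fraction from above).

    Parameters are SI; ``velocity`` must be >= 0 (toward the bottom) and
    ``diffusivity`` > 0.
    """
    if velocity < 0:
        raise ValueError("first-passage oracle requires velocity >= 0")
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    if t < 0:
        raise ValueError("time must be non-negative")
    if t == 0:
        return OracleResult(0.0, True)
    # integrand is ~1 for x << vt and decays like a Gaussian beyond
    x_max = velocity * t + 28.0 * math.sqrt(diffusivity * t)
    integral, _ = quad(
        _absorbed_probability,
        0.0,
        x_max,
        args=(velocity, diffusivity, t),
        limit=200,
        epsabs=1e-13,
        epsrel=1e-11,
    )
    valid = (2.0 * math.sqrt(diffusivity * t) + velocity * t) <= 0.2 * media_height
    return OracleResult(integral / media_height, valid)


def pure_diffusion_series(
    diffusivity: float, media_height: float, t: float, terms: int = 200
) -> float:
    """Fraction *remaining* in suspension for pure diffusion (V = 0).

    Eigenfunction series for a slab of height L with absorbing bottom and
    reflecting top:

        remaining(t) = sum_k 8/((2k+1)^2 pi^2) exp(-D ((2k+1) pi / 2L)^2 t)

    The delivered fraction is 1 - remaining.
    """
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    if terms < 1:
        raise ValueError("need at least one series term")
    k = np.arange(terms)
    odd = 2 * k + 1
    rates = diffusivity * (odd * math.pi / (2.0 * media_height)) ** 2
    coeffs = 8.0 / (odd**2 * math.pi**2)
    return float(np.sum(coeffs * np.exp(-rates * t)))


def sedimentation_only_fraction(velocity: float, media_height: float, t: float) -> float:
    """Plug-flow delivered fraction for pure sedimentation: min(Vt/L, 1)."""
    if velocity <= 0:
        raise ValueError("plug-flow limit requires velocity > 0")
    return min(velocity * t / media_height, 1.0)
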