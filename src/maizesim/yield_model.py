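"""Quadratic yield-density model for maize stands.

The yield of a maize stand is modelled as a downward parabola in planting
density, written in vertex form

    Y(D) = A * (D - Dm)**2 + Ym

where ``D`` is density in plants/m^2, ``Dm`` is the optimum density at which
the maximum yield ``Ym`` (t/hm^2) is attained, and ``A < 0`` (t/hm^2 per
(plants/m^2)^2) controls how steeply yield falls away from the optimum.

Instead of choosing ``A`` directly, varieties are often characterised by a
*density sensitivity*: the angle (degrees) between the two tangents to the
parabola at unit density offsets from the optimum, where the slopes are
``dY/dD = +/- 2A``.  A larger angle means a steeper yield penalty per unit
density deviation.

Unit conventions, centralised here:

* model densities are plants/m^2; field densities are plants/hm^2
  (factor ``10^4`` m^2/hm^2),
* stand yields are t/hm^2; per-plant yields are t/plant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: square metres per hectare, the single density/area conversion factor
M2_PER_HM2 = 1e4


@dataclass(frozen=True)
class YieldDensityModel:
    """Vertex-form parabola linking stand density to stand yield.

    Parameters
    ----------
    A : float
        Quadratic coefficient, t/hm^2 per (plants/m^2)^2.  Must be negative.
    Dm : float
        Optimum density, plants/m^2.  Must be positive.
    Ym : float
        Maximum yield, attained at ``Dm``, t/hm^2.  Must be positive.
    """

    A: float
    Dm: float
    Ym: float

    def __post_init__(self) -> None:
        if not self.A < 0:
            raise ValueError(f"A must be negative (downward parabola), got {self.A}")
        if not self.Dm > 0:
            raise ValueError(f"Dm must be positive, got {self.Dm}")
        if not self.Ym > 0:
            raise ValueError(f"Ym must be positive, got {self.Ym}")

    @property
    def B(self) -> float:
        """Linear coefficient of the expanded form Y = A*D^2 + B*D + C."""
        return -2.0 * self.A * self.Dm

    @property
    def C(self) -> float:
        """Constant coefficient of the expanded form (the yield at D=0)."""
        return self.A * self.Dm**2 + self.Ym

    @classmethod
    def from_expanded(cls, A: float, B: float, C: float) -> "YieldDensityModel":
        """Build the model from expanded coefficients ``Y = A*D^2 + B*D + C``.

        The vertex is ``Dm = -B/(2A)``, ``Ym = C - B^2/(4A)``.
        """
        if A == 0:
            raise ValueError("A must be nonzero")
        return cls(A=A, Dm=-B / (2.0 * A), Ym=C - B**2 / (4.0 * A))


@dataclass(frozen=True)
class SensitivitySpec:
    """Density sensitivity expressed as a tangent angle.

    ``theta_degrees`` is the angle between the two tangents of slope
    ``+/- 2A`` drawn at unit density offsets from the optimum; it must lie
    strictly between 0 and 180 degrees.
    """

    theta_degrees: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_degrees < 180.0:
            raise ValueError(
                f"sensitivity angle must lie in (0, 180) degrees, got {self.theta_degrees}"
            )


def sensitivity_to_coefficient(spec: SensitivitySpec | float) -> float:
    """Convert a density-sensitivity angle to the quadratic coefficient ``A``.

    The two tangents at unit offsets from the optimum have slopes ``+2|A|``
    and ``-2|A|``; by symmetry each makes an angle of ``theta/2`` with the
    horizontal, so ``tan(theta/2) = 2|A|`` and

        A = -tan(theta/2) / 2      (theta in radians)

    Parameters
    ----------
    spec : SensitivitySpec or float
        The tangent angle; a bare number is interpreted as degrees.

    Returns
    -------
    float
        The (negative) quadratic coefficient.
    """
    if not isinstance(spec, SensitivitySpec):
        spec = SensitivitySpec(float(spec))
    return -math.tan(math.radians(spec.theta_degrees) / 2.0) / 2.0


def yield_at_density(model: YieldDensityModel, D):
    """Stand yield (t/hm^2) at density ``D`` (plants/m^2), vertex form.

    Accepts scalars or arrays.  The raw parabola is returned unclamped; it
    may be negative far from the optimum (see :func:`per_plant_yield` for
    the clamped per-plant quantity).
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("density must be non-negative")
    out = model.A * (D - model.Dm) ** 2 + model.Ym
    return float(out) if out.ndim == 0 else out


def yield_derivative(model: YieldDensityModel, D):
    """Marginal yield dY/dD = 2A(D - Dm), t/hm^2 per plants/m^2.

    Zero at the optimum; equals ``+/- 2A`` one plant/m^2 below/above it.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("density must be non-negative")
    out = 2.0 * model.A * (D - model.Dm)
    return float(out) if out.ndim == 0 else out


def per_plant_yield(model: YieldDensityModel, area):
    """Yield of an individual plant (t) from its nutrition area (m^2).

    A plant occupying ``area`` square metres is treated as growing at its
    *equivalent density* ``d = 1/area`` plants/m^2; the stand parabola is
    evaluated at that density and converted to a per-plant mass:

        y = max(0, Y(d)) / (d * 10^4)  =  max(0, Y(1/area)) * area / 10^4

    The zero clamp encodes that a plant cannot produce negative mass even
    where the raw parabola dips below zero (very large areas).

    Accepts scalars or arrays of areas.
    """
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("nutrition area must be positive")
    d = 1.0 / area
    out = np.maximum(0.0, yield_at_density(model, d)) * area / M2_PER_HM2
    return float(out) if out.ndim == 0 else out
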