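"""Hansen-space geometry: the Ra distance, RED ratios and compatibility verdicts.

Hansen solubility parameters (HSP) split the square root of a substance's
cohesive energy density into three components, all in MPa^1/2:

* ``delta_d`` — dispersion (London) forces,
* ``delta_p`` — polar (dipole) interactions,
* ``delta_hb`` — hydrogen bonding.

Two substances that sit close together in this three-dimensional space tend
to be mutually compatible ("like dissolves like").  Distance is measured with
the conventional Hansen metric in which the dispersion axis is compressed by
a factor of two:

    Ra = sqrt( 4*(dD1-dD2)^2 + (dP1-dP2)^2 + (dHb1-dHb2)^2 )

Dividing Ra by an interaction radius Ro gives the Relative Energy Difference
RED = Ra/Ro; RED < 1 predicts high affinity, RED > 1 poor compatibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterator

import numpy as np

from .errors import ValidationError

#: Sanity cap on a single HSP component, MPa^1/2 (comfortably above water's
#: hydrogen-bonding value of 42.3, the largest commonly tabulated).
MAX_COMPONENT = 60.0

#: Default half-width of the "borderline" band around RED = 1.
DEFAULT_BORDERLINE_BAND = 0.05


@dataclass(frozen=True)
class HSPVector:
    """A point in Hansen space.

    Parameters
    ----------
    delta_d, delta_p, delta_hb : float
        Dispersion, polar and hydrogen-bonding solubility parameters,
        MPa^1/2.  Each must be finite, non-negative and below
        :data:`MAX_COMPONENT`.
    """

    delta_d: float
    delta_p: float
    delta_hb: float

    def __post_init__(self) -> None:
        for name in ("delta_d", "delta_p", "delta_hb"):
            try:
                object.__setattr__(self, name, float(getattr(self, name)))
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"{name} must be a number: {exc}") from exc
        for name, value in zip(("delta_d", "delta_p", "delta_hb"), self):
            if not math.isfinite(value):
                raise ValidationError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
            if value > MAX_COMPONENT:
                raise ValidationError(
                    f"{name}={value} exceeds the sanity cap of {MAX_COMPONENT} MPa^1/2"
                )

    def __iter__(self) -> Iterator[float]:
        yield self.delta_d
        yield self.delta_p
        yield self.delta_hb

    def as_array(self) -> np.ndarray:
        return np.array([self.delta_d, self.delta_p, self.delta_hb], dtype=float)

    def round(self, ndigits: int = 2) -> "HSPVector":
        return HSPVector(*(round(c, ndigits) for c in self))


@dataclass(frozen=True)
class RoSpec:
    """How the interaction radius Ro of a polymer is obtained.

    Either a fixed numeric value, or "distance to a named reference solvent":
    the Ra between the polymer and its worst swelling (poorest) solvent is a
    natural experimental choice of Ro, since anything farther away than that
    solvent interacts even more weakly.
    """

    mode: str  # "reference_solvent" | "numeric"
    reference_solvent_name: str | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "numeric":
            if self.value is None or not math.isfinite(self.value) or self.value <= 0:
                raise ValidationError(f"numeric Ro must be > 0, got {self.value!r}")
        elif self.mode == "reference_solvent":
            if not self.reference_solvent_name:
                raise ValidationError("reference_solvent mode requires a solvent name")
        else:
            raise ValidationError(f"unknown RoSpec mode {self.mode!r}")

    @classmethod
    def numeric(cls, value: float) -> "RoSpec":
        return cls(mode="numeric", value=float(value))

    @classmethod
    def from_solvent(cls, name: str) -> "RoSpec":
        return cls(mode="reference_solvent", reference_solvent_name=name)


class Verdict(str, Enum):
    """Qualitative compatibility call derived from a RED value."""

    COMPATIBLE = "compatible"
    INCOMPATIBLE = "incompatible"
    BORDERLINE = "borderline"


def ra_distance(a: HSPVector, b: HSPVector) -> float:
    """Hansen distance Ra between two HSP vectors, MPa^1/2.

    The dispersion difference is weighted by 4 (equivalently, the dispersion
    axis is stretched by 2 before taking the Euclidean norm).  Symmetric in
    its arguments and zero iff ``a == b``.
    """
    dd = a.delta_d - b.delta_d
    dp = a.delta_p - b.delta_p
    dhb = a.delta_hb - b.delta_hb
    return math.sqrt(4.0 * dd * dd + dp * dp + dhb * dhb)


def ra_distance_many(candidate: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Vectorized Ra between candidate point(s) and a set of HSP triples.

    Parameters
    ----------
    candidate : ndarray, shape (..., 3)
    others : ndarray, shape (m, 3)

    Returns
    -------
    ndarray, shape (..., m)
    """
    candidate = np.asarray(candidate, dtype=float)
    others = np.asarray(others, dtype=float)
    diff = candidate[..., None, :] - others
    return np.sqrt(
        4.0 * diff[..., 0] ** 2 + diff[..., 1] ** 2 + diff[..., 2] ** 2
    )


def red(ra: float, ro: float) -> float:
    """Relative Energy Difference, RED = Ra / Ro (dimensionless)."""
    if not math.isfinite(ro) or ro <= 0:
        raise ValidationError(f"Ro must be > 0, got {ro!r}")
    if not math.isfinite(ra) or ra < 0:
        raise ValidationError(f"Ra must be >= 0, got {ra!r}")
    return ra / ro


def verdict(red_value: float, band: float = DEFAULT_BORDERLINE_BAND) -> Verdict:
    """Classify a RED value against the unit threshold.

    ``compatible`` below ``1 - band``, ``incompatible`` above ``1 + band``,
    ``borderline`` in between.  The band exists to avoid over-claiming right
    at RED = 1, where the uncertainty of tabulated HSPs dominates.
    """
    if not math.isfinite(red_value) or red_value < 0:
        raise ValidationError(f"RED must be >= 0, got {red_value!r}")
    if band < 0:
        raise ValidationError(f"borderline band must be >= 0, got {band}")
    if red_value < 1.0 - band:
        return Verdict.COMPATIBLE
    if red_value > 1.0 + band:
        return Verdict.INCOMPATIBLE
    return Verdict.BORDERLINE
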