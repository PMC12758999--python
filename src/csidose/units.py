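"""Absorbed-dose values with explicit units.

Imaging doses are naturally quoted in mGy, OSL calibration in cGy and plan
doses in Gy; mixing them silently is the classic accounting bug this type
prevents.  Conversion is exact scaling by powers of ten, so round trips are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: Exact scale factor from each supported unit to gray.
_TO_GY: dict[str, float] = {"mGy": 1e-3, "cGy": 1e-2, "Gy": 1.0}

DOSE_UNITS = tuple(_TO_GY)


@dataclass(frozen=True)
class DoseValue:
    """A nonnegative absorbed dose tagged with its unit.

    Parameters
    ----------
    value
        Magnitude, must be >= 0.
    unit
        One of ``"mGy"``, ``"cGy"``, ``"Gy"``.
    """

    value: float
    unit: str = "Gy"

    def __post_init__(self) -> None:
        if self.unit not in _TO_GY:
            raise ValidationError(
                f"unknown dose unit {self.unit!r}; expected one of {DOSE_UNITS}"
            )
        if not (self.value >= 0.0):  # also rejects NaN
            raise ValidationError(f"dose must be nonnegative, got {self.value!r}")

    # -- conversions -----------------------------------------------------
    def to(self, unit: str) -> "DoseValue":
        """Return the same dose expressed in *unit* (power-of-ten scaling).

        Scaling down divides by the exact integer power of ten rather than
        multiplying by its inexact binary reciprocal, so round trips agree
        to the last floating-point digit.
        """
        if unit == self.unit:
            return self
        if unit not in _TO_GY:
            raise ValidationError(f"unknown dose unit {unit!r}")
        ratio = _TO_GY[self.unit] / _TO_GY[unit]
        if ratio >= 1.0:
            return DoseValue(self.value * ratio, unit)
        return DoseValue(self.value / (1.0 / ratio), unit)

    @property
    def gy(self) -> float:
        return self.value * _TO_GY[self.unit]

    @property
    def cgy(self) -> float:
        return self.value * _TO_GY[self.unit] / 1e-2

    @property
    def mgy(self) -> float:
        return self.value * _TO_GY[self.unit] / 1e-3

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other: "DoseValue") -> "DoseValue":
        if not isinstance(other, DoseValue):
            return NotImplemented
        return DoseValue(self.value + other.to(self.unit).value, self.unit)

    def __mul__(self, k: float) -> "DoseValue":
        return DoseValue(self.value * float(k), self.unit)

    __rmul__ = __mul__

    # -- ordering on the physical quantity -------------------------------
    def __lt__(self, other: "DoseValue") -> bool:
        return self.gy < other.gy

    def __le__(self, other: "DoseValue") -> bool:
        return self.gy <= other.gy

    def __gt__(self, other: "DoseValue") -> bool:
        return self.gy > other.gy

    def __ge__(self, other: "DoseValue") -> bool:
        return self.gy >= other.gy

    def __str__(self) -> str:
        return f"{self.value:g} {self.unit}"


def as_dose(x: "DoseValue | float", unit: str = "Gy") -> DoseValue:
    """Coerce a bare number (interpreted in *unit*) or a DoseValue to DoseValue."""
    if isinstance(x, DoseValue):
        return x
    return DoseValue(float(x), unit)
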