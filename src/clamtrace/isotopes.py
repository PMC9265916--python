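"""Stable-isotope δ-notation arithmetic.

Isotope abundance ratios R = heavy/light (13C/12C, 15N/14N) are reported in
per-mil (‰) deviation from an international reference material:

    δ = (R_sample / R_standard − 1) × 1000

Carbon is referenced to Vienna Pee Dee Belemnite (VPDB), nitrogen to
atmospheric N2.  δ values measured against different references are not
commensurable, so :class:`DeltaValue` carries its reference as metadata and
refuses mixed-reference arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "R_VPDB_13C",
    "R_AIR_15N",
    "IsotopeRatio",
    "DeltaValue",
    "delta_from_ratio",
    "ratio_from_delta",
]

#: 13C/12C of Vienna Pee Dee Belemnite (IAEA consensus value).
R_VPDB_13C = 0.0111802
#: 15N/14N of atmospheric N2.
R_AIR_15N = 0.0036765

_REFERENCES = {"C": "VPDB", "N": "air-N2"}


@dataclass(frozen=True)
class IsotopeRatio:
    """A heavy/light isotope abundance ratio paired with its reference.

    Parameters
    ----------
    r_sample
        Measured heavy/light ratio of the sample (dimensionless, > 0).
    r_standard
        Ratio of the reference material (dimensionless, > 0).
    element
        ``"C"`` or ``"N"``.
    reference_name
        ``"VPDB"`` for carbon, ``"air-N2"`` for nitrogen.
    """

    r_sample: float
    r_standard: float
    element: str = "C"
    reference_name: str = "VPDB"

    def __post_init__(self) -> None:
        if self.r_sample <= 0:
            raise ValueError(f"r_sample must be > 0, got {self.r_sample}")
        if self.r_standard <= 0:
            raise ValueError(f"r_standard must be > 0, got {self.r_standard}")
        if self.element not in _REFERENCES:
            raise ValueError(f"element must be one of {sorted(_REFERENCES)}")


@dataclass(frozen=True)
class DeltaValue:
    """A δ value (‰) tagged with element and reference.

    Addition/subtraction across different references is refused: a δ13C vs
    VPDB and a δ15N vs air-N2 live on incompatible scales.
    """

    permil: float
    element: str = "C"
    reference_name: str = "VPDB"

    def _check_compatible(self, other: "DeltaValue") -> None:
        if not isinstance(other, DeltaValue):
            raise TypeError("can only combine DeltaValue with DeltaValue")
        if (self.element, self.reference_name) != (other.element, other.reference_name):
            raise ValueError(
                "refusing arithmetic across references: "
                f"{self.element}/{self.reference_name} vs "
                f"{other.element}/{other.reference_name}"
            )

    def __add__(self, other: "DeltaValue") -> "DeltaValue":
        self._check_compatible(other)
        return DeltaValue(self.permil + other.permil, self.element, self.reference_name)

    def __sub__(self, other: "DeltaValue") -> "DeltaValue":
        self._check_compatible(other)
        return DeltaValue(self.permil - other.permil, self.element, self.reference_name)


def delta_from_ratio(ir: IsotopeRatio) -> float:
    """Convert an isotope ratio to δ-notation (‰).

    Returns ``(r_sample / r_standard − 1) × 1000``.
    """
    return (ir.r_sample / ir.r_standard - 1.0) * 1000.0


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Invert δ-notation: recover ``r_sample`` from a δ value (‰).

    Returns ``r_standard × (1 + δ/1000)``.  A δ of −1000‰ or below would
    imply a nonpositive ratio and is rejected.
    """
    if delta <= -1000.0:
        raise ValueError(f"delta must be > -1000 permil, got {delta}")
    if r_standard <= 0:
        raise ValueError(f"r_standard must be > 0, got {r_standard}")
    return r_standard * (1.0 + delta / 1000.0)
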