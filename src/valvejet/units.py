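"""Shared quantity conventions, physical constants and formulation labels.

Everything downstream of this module works in SI base/derived units
(m, kg, s, Pa·s, N/m, m³).  Input tables and configs may use the bench
units common in droplet bioprinting (µm nozzles, nl droplet volumes,
µs dwell times, mPa·s viscosities); :func:`convert_to_si` maps them to
SI with exact rational scale factors.  Display layers re-scale back.

Concentration units (mg/mL, %w/v, %v/v) are deliberately carried as
opaque labels: the formulations compared here are never converted
between mass-per-volume and percent conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "BIOINK_NAMES",
    "Formulation",
    "PhysicalConstants",
    "UnknownUnitError",
    "convert_to_si",
    "SI_FACTORS",
]

#: Bioink families supported as formulation labels.
BIOINK_NAMES = frozenset(
    {"fibrinogen", "collagen_I", "matrigel", "alginate", "agarose", "gelma", "other"}
)

_CONCENTRATION_UNITS = frozenset({"mg/mL", "%w/v", "%v/v"})

#: Exact multiplicative factors taking a tagged value to its SI unit.
SI_FACTORS: dict[str, float] = {
    # viscosity -> Pa·s
    "mPa·s": 1e-3,
    "Pa·s": 1.0,
    # surface tension -> N/m
    "mN/m": 1e-3,
    "N/m": 1.0,
    # length -> m
    "µm": 1e-6,
    "mm": 1e-3,
    "m": 1.0,
    # volume -> m³
    "nl": 1e-12,
    "µl": 1e-9,
    "m³": 1.0,
    # time -> s
    "µs": 1e-6,
    "ms": 1e-3,
    "s": 1.0,
    # mass -> kg
    "mg": 1e-6,
    "g": 1e-3,
    "kg": 1.0,
}

# ASCII aliases so configs do not need the micro sign.
_ALIASES = {"um": "µm", "ul": "µl", "us": "µs", "nL": "nl", "uL": "µl",
            "mPa.s": "mPa·s", "Pa.s": "Pa·s", "m3": "m³"}


class UnknownUnitError(ValueError):
    """Raised when a unit tag is not in the supported set."""


def convert_to_si(value: float, unit: str) -> float:
    """Convert ``value`` tagged with ``unit`` to the corresponding SI unit.

    The conversion is an exact rational scaling; converting back with the
    inverse factor recovers the input to better than 1e-12 relative.

    Raises
    ------
    UnknownUnitError
        If ``unit`` is not a supported tag; the message names the tag.
    """
    tag = _ALIASES.get(unit, unit)
    try:
        return value * SI_FACTORS[tag]
    except KeyError:
        raise UnknownUnitError(
            f"unknown unit tag {unit!r}; supported: {sorted(SI_FACTORS)}"
        ) from None


@dataclass(frozen=True)
class Formulation:
    """A bioink formulation label carried through every report.

    Parameters
    ----------
    bioink_name
        One of :data:`BIOINK_NAMES`.
    concentration
        Numeric concentration, interpreted under ``concentration_unit``.
    concentration_unit
        ``"mg/mL"``, ``"%w/v"`` or ``"%v/v"`` — opaque label, never converted.
    surfactant_fraction
        Tween-20 volume fraction (fraction, not percent); 0 if absent.
        Trace surfactant (≤0.001 %v/v here, i.e. ≤1e-5) lowers surface
        tension without changing bulk viscosity.
    cell_density
        Encapsulated cells per mL; 0 for acellular inks.  Covariate only.
    """

    bioink_name: str
    concentration: float
    concentration_unit: str = "mg/mL"
    surfactant_fraction: float = 0.0
    cell_density: float = 0.0

    def __post_init__(self) -> None:
        if self.bioink_name not in BIOINK_NAMES:
            raise ValueError(
                f"bioink_name {self.bioink_name!r} not in {sorted(BIOINK_NAMES)}"
            )
        if self.concentration_unit not in _CONCENTRATION_UNITS:
            raise ValueError(
                f"concentration unit {self.concentration_unit!r} not in "
                f"{sorted(_CONCENTRATION_UNITS)}"
            )
        if not self.concentration > 0:
            raise ValueError("concentration must be > 0")
        if not 0.0 <= self.surfactant_fraction <= 0.01:
            raise ValueError("surfactant fraction must lie in [0, 0.01]")
        if self.cell_density < 0:
            raise ValueError("cell_density must be >= 0")

    @property
    def has_surfactant(self) -> bool:
        return self.surfactant_fraction > 0.0

    def label(self) -> str:
        t20 = " +T20" if self.has_surfactant else ""
        return f"{self.bioink_name} {self.concentration:g} {self.concentration_unit}{t20}"


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants entering the dimensionless groups (only g)."""

    g: float = 9.80665  # standard gravity, m/s²

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise ValueError("g must be > 0")
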