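"""Dimensionless jetting numbers, splash parameter and pinch-off timescales.

For a liquid ligament of velocity v ejected from a nozzle of orifice
diameter D, with fluid density ρ, surface tension σ and characteristic
viscosity µ, the groups used throughout droplet-on-demand printing are

    We = ρ v² D / σ          inertia vs capillarity
    Re = ρ v D / µ           inertia vs viscous dissipation
    Oh = µ / √(ρ σ D) = √We / Re
    Fr = v / √(g D)          inertia vs gravity
    Z  = 1 / Oh              (1 ≤ Z ≤ 10 is the canonical printable band)
    Bo = We / Fr² = ρ g D² / σ
    K_splash = Oh · Re^1.25  deposition/splash impact parameter

The characteristic length is the nozzle orifice diameter and the
characteristic velocity is the measured ligament velocity.  For
shear-thinning inks the characteristic viscosity should be an apparent
viscosity at a jet-relevant shear rate (default γ̇_c = v/D), not the
zero-shear plateau; :func:`characteristic_viscosity` implements that
selection from a power-law fit.

The maximum jetting frequency is bounded by ligament pinch-off: the
capillary time τ_c = √(ρR³/σ) sets the inviscid breakup scale, and the
pinch-off time is modelled as t_p = τ_c (1 + α·Oh), a viscous retardation
that grows linearly with Oh (α defaults to 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import PhysicalConstants

__all__ = [
    "FluidProperties",
    "JetConditions",
    "DimensionlessSet",
    "FrequencyEstimate",
    "dimensionless_numbers",
    "oh_from_we_re",
    "splash_parameter",
    "invert_dimensionless",
    "capillary_time",
    "pinch_off_time",
    "characteristic_viscosity",
    "DEFAULT_VISCOUS_FACTOR_ALPHA",
]

#: Default coefficient of the viscous retardation factor in t_p = τc(1 + α·Oh).
DEFAULT_VISCOUS_FACTOR_ALPHA = 2.0


@dataclass(frozen=True)
class FluidProperties:
    """Bulk fluid properties entering the dimensionless set (all SI)."""

    density: float  # ρ, kg/m³
    surface_tension: float  # σ, N/m
    characteristic_viscosity: float  # µ, Pa·s

    def __post_init__(self) -> None:
        for name in ("density", "surface_tension", "characteristic_viscosity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class JetConditions:
    """Actuation/jetting conditions for one printing condition (SI units)."""

    jet_velocity: float  # v, m/s — measured ligament velocity
    nozzle_diameter: float  # D, m
    dwell_time: float = 1e-3  # valve-open duration, s
    jetting_frequency: float = 200.0  # f, Hz
    back_pressure: float | None = None  # metadata only (never enters a formula)

    def __post_init__(self) -> None:
        for name in ("jet_velocity", "nozzle_diameter", "dwell_time", "jetting_frequency"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def nozzle_radius(self) -> float:
        return self.nozzle_diameter / 2.0


@dataclass(frozen=True)
class DimensionlessSet:
    """The dimensionless jetting numbers for one formulation/condition."""

    weber: float
    reynolds: float
    ohnesorge: float
    froude: float
    z_number: float
    splash_parameter: float
    bond: float

    def __post_init__(self) -> None:
        for name in ("weber", "reynolds", "ohnesorge", "froude",
                     "z_number", "splash_parameter", "bond"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class FrequencyEstimate:
    """Pinch-off timescales and the jetting-frequency ceiling they imply."""

    capillary_time: float  # τc, s
    pinch_off_time: float  # t_p ≥ τc, s
    max_frequency: float  # f_max = 1/t_p, Hz
    viscous_factor_coefficient: float  # α


def dimensionless_numbers(
    fluid: FluidProperties,
    jet: JetConditions,
    constants: PhysicalConstants = PhysicalConstants(),
) -> DimensionlessSet:
    """Compute (We, Re, Oh, Fr, Z, K_splash, Bo) for one condition.

    Oh is computed from µ/√(ρσD) and cross-checked against the identity
    √We/Re to 1e-12 relative (the two agree by construction; the check
    guards unit mistakes in the inputs).
    """
    rho, sigma, mu = fluid.density, fluid.surface_tension, fluid.characteristic_viscosity
    v, D = jet.jet_velocity, jet.nozzle_diameter
    we = rho * v * v * D / sigma
    re = rho * v * D / mu
    oh = mu / np.sqrt(rho * sigma * D)
    fr = v / np.sqrt(constants.g * D)
    if abs(oh - np.sqrt(we) / re) > 1e-12 * oh:
        raise AssertionError("Oh identity sqrt(We)/Re violated — inconsistent inputs")
    return DimensionlessSet(
        weber=we,
        reynolds=re,
        ohnesorge=oh,
        froude=fr,
        z_number=1.0 / oh,
        splash_parameter=splash_parameter(oh, re),
        bond=we / fr**2,
    )


def oh_from_we_re(weber: float, reynolds: float) -> float:
    """Ohnesorge number from the identity Oh = √We / Re."""
    if not (weber > 0 and reynolds > 0):
        raise ValueError("We and Re must be > 0")
    return float(np.sqrt(weber) / reynolds)


def splash_parameter(ohnesorge: float, reynolds: float) -> float:
    """Impact splash parameter K = Oh · Re^1.25 (Mundo-type).

    High K predicts spreading/splash on substrate impact; low K predicts
    contained deposition.
    """
    if not (ohnesorge > 0 and reynolds > 0):
        raise ValueError("Oh and Re must be > 0")
    return float(ohnesorge * reynolds**1.25)


def invert_dimensionless(
    weber: float,
    reynolds: float,
    froude: float,
    density: float,
    diameter: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> tuple[float, float, float]:
    """Recover (v, σ, µ) from printed (We, Re, Fr) given ρ and D.

    Closure of the definition set:  v = Fr·√(gD);  σ = ρv²D/We;
    µ = ρvD/Re.  Forward recomputation of the three inputs from the
    returned properties matches to 1e-9 relative.
    """
    for name, val in (("weber", weber), ("reynolds", reynolds), ("froude", froude),
                      ("density", density), ("diameter", diameter)):
        if not val > 0:
            raise ValueError(f"{name} must be > 0")
    v = froude * np.sqrt(constants.g * diameter)
    sigma = density * v * v * diameter / weber
    mu = density * v * diameter / reynolds
    return float(v), float(sigma), float(mu)


def capillary_time(density: float, surface_tension: float, radius: float) -> float:
    """Inertio-capillary (Rayleigh) time τc = √(ρR³/σ).

    For aqueous inks and a 250 µm nozzle this is a few tenths of a
    millisecond, which is what caps drop-on-demand jetting at tens to a
    few hundred hertz.
    """
    for name, val in (("density", density), ("surface_tension", surface_tension),
                      ("radius", radius)):
        if not val > 0:
            raise ValueError(f"{name} must be > 0")
    return float(np.sqrt(density * radius**3 / surface_tension))


def pinch_off_time(
    tau_c: float,
    ohnesorge: float,
    alpha: float = DEFAULT_VISCOUS_FACTOR_ALPHA,
) -> FrequencyEstimate:
    """Pinch-off time t_p = τc·(1 + α·Oh) and the frequency ceiling 1/t_p.

    The viscous factor (1 + α·Oh) reduces to the inviscid capillary limit
    as Oh → 0 and retards breakup linearly in Oh; α is configurable
    (default 2) since only the scaling, not the coefficient, is fixed by
    breakup phenomenology.
    """
    if not tau_c > 0:
        raise ValueError("tau_c must be > 0")
    if not ohnesorge > 0:
        raise ValueError("ohnesorge must be > 0")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    t_p = tau_c * (1.0 + alpha * ohnesorge)
    return FrequencyEstimate(
        capillary_time=tau_c,
        pinch_off_time=t_p,
        max_frequency=1.0 / t_p,
        viscous_factor_coefficient=alpha,
    )


def characteristic_viscosity(fit, jet: JetConditions, shear_rate: float | None = None) -> float:
    """Apparent viscosity at the jet-characteristic shear rate.

    ``fit`` is a :class:`~valvejet.rheology.PowerLawFit`; the shear rate
    defaults to γ̇_c = v/D, the nominal deformation rate of the jet.  A
    measured high-shear viscosity may be supplied directly to
    :class:`FluidProperties` instead — the two paths are equivalent for a
    Newtonian ink and the chosen path should be logged with the result.
    """
    gdot_c = jet.jet_velocity / jet.nozzle_diameter if shear_rate is None else shear_rate
    if not gdot_c > 0:
        raise ValueError("characteristic shear rate must be > 0")
    return float(fit.K * gdot_c ** (fit.n - 1.0))
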