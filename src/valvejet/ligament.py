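"""Ligament and droplet metrology.

Gravimetric volume calibration (per-drop volume from the net mass of a
1000-droplet burst), session acceptance rules (CV ≤ 5% across bursts and
R² ≥ 0.99 for volume-vs-dwell linearity), ligament velocity from
leading-edge displacement sweeps, and geometric descriptors (ligament
length, aspect ratio L_ar = L_l/D, volume-equivalent sphere diameter).

"Ligament volume" and "per-drop volume" name the same gravimetric
quantity mass/(count·ρ); both aliases are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DropMassSeries",
    "CalibrationResult",
    "DisplacementSeries",
    "VelocityEstimate",
    "LigamentMetrics",
    "density_from_mass",
    "calibrate_drop_volume",
    "estimate_velocity",
    "aspect_ratio",
    "equivalent_diameter",
    "CV_MAX_PERCENT",
    "R2_MIN",
]

#: Session acceptance thresholds for gravimetric calibration.
CV_MAX_PERCENT = 5.0
R2_MIN = 0.99


@dataclass
class DropMassSeries:
    """Net burst masses from gravimetric calibration (SI units)."""

    burst_masses: np.ndarray  # net mass per burst, kg
    drops_per_burst: int  # pulses per burst (default protocol: 1000)
    dwell_times: np.ndarray  # valve dwell per burst group, s
    solution_density: float  # ρ, kg/m³

    def __post_init__(self) -> None:
        self.burst_masses = np.atleast_1d(np.asarray(self.burst_masses, dtype=float))
        self.dwell_times = np.atleast_1d(np.asarray(self.dwell_times, dtype=float))
        if self.burst_masses.shape != self.dwell_times.shape:
            raise ValueError("burst_masses and dwell_times must have equal length")
        if not np.all(self.burst_masses > 0):
            raise ValueError("burst masses must be > 0")
        if self.drops_per_burst < 1:
            raise ValueError("drops_per_burst must be >= 1")
        if not self.solution_density > 0:
            raise ValueError("solution density must be > 0")

    @property
    def volumes(self) -> np.ndarray:
        """Per-drop volume of each burst: mass / (count · ρ), m³."""
        return self.burst_masses / (self.drops_per_burst * self.solution_density)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the gravimetric calibration acceptance check.

    ``accepted`` is exactly the conjunction (cv ≤ 5%) ∧ (R² ≥ 0.99), with
    both boundaries inclusive.  R² is NaN (and acceptance fails) when fewer
    than three distinct dwell times are available for the linearity fit.
    """

    per_drop_volume: float  # mean V over bursts at the operating dwell, m³
    cv: float  # coefficient of variation, percent
    linearity_r2: float  # R² of volume vs dwell (NaN if undefined)
    accepted: bool
    n_bursts: int
    operating_dwell: float  # s


@dataclass
class DisplacementSeries:
    """Leading-edge ligament displacement sampled during an actuation sweep."""

    times: np.ndarray  # s, strictly increasing (protocol: 50 µs steps)
    positions: np.ndarray  # m

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.shape != self.positions.shape:
            raise ValueError("times and positions must have equal length")
        if self.times.size < 3:
            raise ValueError("displacement series needs at least 3 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class VelocityEstimate:
    velocity: float  # m/s, slope of position vs time
    standard_error: float  # m/s, from fit residuals
    n_points: int
    method: str  # "ols" | "theil_sen"


@dataclass(frozen=True)
class LigamentMetrics:
    """Geometric/kinematic descriptors of one printing condition."""

    volume: float  # V_lig, m³
    length: float  # L_l, m
    aspect_ratio: float  # L_ar = L_l / D
    equivalent_diameter: float  # d_eq = (6V/π)^(1/3), m
    velocity: float  # v, m/s

    def __post_init__(self) -> None:
        for name in ("volume", "length", "aspect_ratio", "equivalent_diameter", "velocity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def density_from_mass(net_mass: float, known_volume: float) -> float:
    """Solution density ρ = net mass / known pipetted volume."""
    if not (net_mass > 0 and known_volume > 0):
        raise ValueError("net_mass and known_volume must be > 0")
    return net_mass / known_volume


def calibrate_drop_volume(
    series: DropMassSeries,
    operating_dwell: float | None = None,
) -> CalibrationResult:
    """Gravimetric per-drop volume with CV and linearity acceptance.

    Per-burst volume is mass/(count·ρ).  The reported mean and CV
    (sample SD / mean × 100%) are computed over the bursts at the
    operating dwell (default: the most frequent dwell in the series).
    Linearity R² is from an ordinary least-squares line of burst-mean
    volume vs dwell across the distinct dwell times; with fewer than
    three distinct dwells R² is NaN and acceptance fails.  The session is
    accepted iff CV ≤ 5% and R² ≥ 0.99 (boundaries inclusive).
    """
    if series.burst_masses.size < 3:
        raise ValueError("calibration requires at least 3 bursts")
    volumes = series.volumes
    dwells = series.dwell_times

    if operating_dwell is None:
        uniq, counts = np.unique(dwells, return_counts=True)
        operating_dwell = float(uniq[np.argmax(counts)])
    at_op = np.isclose(dwells, operating_dwell)
    if at_op.sum() < 1:
        raise ValueError(f"no bursts at operating dwell {operating_dwell}")
    v_op = volumes[at_op]
    mean_v = float(np.mean(v_op))
    cv = float(np.std(v_op, ddof=1) / mean_v * 100.0) if v_op.size >= 2 else 0.0

    uniq_dwells = np.unique(dwells)
    if uniq_dwells.size >= 3:
        # burst means per dwell, then OLS volume vs dwell
        means = np.array([volumes[np.isclose(dwells, d)].mean() for d in uniq_dwells])
        if np.allclose(means, means[0]):
            # zero-variance response: a flat line fits exactly
            r2 = 1.0
        else:
            lr = stats.linregress(uniq_dwells, means)
            r2 = float(lr.rvalue**2)
    else:
        r2 = float("nan")

    accepted = bool(cv <= CV_MAX_PERCENT and np.isfinite(r2) and r2 >= R2_MIN)
    return CalibrationResult(
        per_drop_volume=mean_v,
        cv=cv,
        linearity_r2=r2,
        accepted=accepted,
        n_bursts=int(series.burst_masses.size),
        operating_dwell=operating_dwell,
    )


def estimate_velocity(series: DisplacementSeries, robust: bool = False) -> VelocityEstimate:
    """Average ligament velocity as the slope of position vs time.

    Ordinary least squares by default; ``robust=True`` switches to the
    Theil–Sen median-of-slopes estimator for sweeps with outlier frames.
    The standard error comes from the OLS residuals (zero for an exact
    line); invariant under shifts of the time and position origins.
    """
    t, x = series.times, series.positions
    if np.ptp(t) <= 0:
        raise ValueError("zero time span")
    if robust:
        ts = stats.theilslopes(x, t)
        slope = float(ts.slope)
        # slope SE from the residuals about the Theil–Sen line
        resid = x - (ts.intercept + slope * t)
        dof = max(t.size - 2, 1)
        se = float(np.sqrt((resid @ resid / dof) / np.sum((t - t.mean()) ** 2)))
        return VelocityEstimate(slope, se, int(t.size), "theil_sen")
    lr = stats.linregress(t, x)
    se = float(lr.stderr) if np.isfinite(lr.stderr) else 0.0
    return VelocityEstimate(float(lr.slope), se, int(t.size), "ols")


def aspect_ratio(length: float, nozzle_diameter: float) -> float:
    """Ligament aspect ratio L_ar = L_l / D (nozzle orifice diameter)."""
    if not (length > 0 and nozzle_diameter > 0):
        raise ValueError("length and nozzle_diameter must be > 0")
    return length / nozzle_diameter


def equivalent_diameter(volume: float) -> float:
    """Diameter of the sphere with the given volume: d_eq = (6V/π)^(1/3)."""
    if not volume > 0:
        raise ValueError("volume must be > 0")
    return float((6.0 * volume / np.pi) ** (1.0 / 3.0))
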