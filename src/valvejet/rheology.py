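"""Flow-curve ingestion and power-law viscosity fitting.

Steady-shear flow curves (apparent viscosity µ vs shear rate γ̇) are fitted
to the two-parameter power-law (Ostwald–de Waele) model

    µ(γ̇) = K · γ̇^(n-1)

with K the consistency index (Pa·s^n) and n the flow-behaviour index
(n = 1 Newtonian, n < 1 shear-thinning).  The fit minimises the weighted
sum of squares  Σ wᵢ (µᵢ − K γ̇ᵢ^(n−1))²  with inverse-square weights
wᵢ = 1/µᵢ² by default, which makes the objective a relative-residual
least squares and keeps decade-spanning curves from being dominated by
the low-shear plateau.  Optimisation is damped (Levenberg–Marquardt-type)
least squares seeded from an ordinary log–log regression.

Oscillatory amplitude sweeps (G′, G″) are summarised over the linear
viscoelastic region; no model is fitted to them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .units import Formulation

__all__ = [
    "FlowCurve",
    "ModuliSweep",
    "PowerLawFit",
    "ModuliSummary",
    "load_flow_curve",
    "fit_power_law",
    "apparent_viscosity",
    "summarize_moduli",
    "DEFAULT_SHEAR_FLOOR",
]

#: Default regularisation floor for the shear rate, 1/s.  The power-law
#: viscosity diverges as γ̇ → 0 for n < 1; evaluations clamp γ̇ below this.
DEFAULT_SHEAR_FLOOR = 1e-2

#: Floor below which flow-curve rows are considered unmeasurable and dropped.
DEFAULT_CLEANING_FLOOR = 1e-3

# Optimiser bounds; fits pinned at a bound are flagged, not rejected.
_K_BOUNDS = (1e-8, 1e4)
_N_BOUNDS = (0.05, 1.5)


@dataclass
class FlowCurve:
    """A cleaned steady-shear flow curve (one sweep direction)."""

    shear_rates: np.ndarray  # 1/s, strictly increasing, > 0
    viscosities: np.ndarray  # Pa·s, > 0
    temperature: float | None = None  # °C, metadata only
    direction: str = "up"  # "up" | "down"
    formulation: Formulation | None = None
    n_dropped: int = 0  # rows removed during cleaning

    def __post_init__(self) -> None:
        self.shear_rates = np.asarray(self.shear_rates, dtype=float)
        self.viscosities = np.asarray(self.viscosities, dtype=float)
        if self.shear_rates.shape != self.viscosities.shape:
            raise ValueError("shear_rates and viscosities must have equal length")
        if self.shear_rates.size < 5:
            raise ValueError("flow curve needs at least 5 usable points")
        if not np.all(self.shear_rates > 0):
            raise ValueError("shear rates must be strictly positive after cleaning")
        if not np.all(np.diff(self.shear_rates) > 0):
            raise ValueError("shear rates must be strictly increasing within a sweep")
        if not np.all(self.viscosities > 0):
            raise ValueError("viscosities must be strictly positive")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")

    def __len__(self) -> int:
        return int(self.shear_rates.size)


@dataclass
class ModuliSweep:
    """Strain-amplitude sweep of storage and loss moduli at fixed frequency."""

    strains: np.ndarray  # dimensionless amplitude
    storage_modulus: np.ndarray  # G′, Pa
    loss_modulus: np.ndarray  # G″, Pa
    angular_frequency: float = 1.0  # rad/s
    formulation: Formulation | None = None

    def __post_init__(self) -> None:
        self.strains = np.asarray(self.strains, dtype=float)
        self.storage_modulus = np.asarray(self.storage_modulus, dtype=float)
        self.loss_modulus = np.asarray(self.loss_modulus, dtype=float)
        if not (
            self.strains.shape
            == self.storage_modulus.shape
            == self.loss_modulus.shape
        ):
            raise ValueError("sweep arrays must have equal length")
        if np.any(self.storage_modulus < 0) or np.any(self.loss_modulus < 0):
            raise ValueError("moduli must be non-negative")
        if not self.angular_frequency > 0:
            raise ValueError("angular_frequency must be > 0")


@dataclass
class PowerLawFit:
    """Result of a power-law viscosity fit µ = K γ̇^(n−1)."""

    consistency_index: float  # K, Pa·s^n
    flow_index: float  # n, dimensionless
    weighting: str = "inverse_square"  # "inverse_square" | "none"
    rss: float = float("nan")  # weighted residual sum of squares
    n_points: int = 0
    converged: bool = True
    at_bounds: bool = False  # optimum pinned at a parameter bound

    def __post_init__(self) -> None:
        if not self.consistency_index > 0:
            raise ValueError("consistency index K must be > 0")
        if not 0 < self.flow_index <= _N_BOUNDS[1]:
            raise ValueError("flow index n must lie in (0, 1.5]")

    # short aliases used throughout the literature
    @property
    def K(self) -> float:
        return self.consistency_index

    @property
    def n(self) -> float:
        return self.flow_index


@dataclass(frozen=True)
class ModuliSummary:
    """Linear-viscoelastic-region summary of an amplitude sweep."""

    mean_storage: float  # ⟨G′⟩, Pa
    mean_loss: float  # ⟨G″⟩, Pa
    tan_delta: float  # ⟨G″⟩ / ⟨G′⟩
    n_points: int
    lve_strain_max: float


def load_flow_curve(
    table: str | Path | io.IOBase | pd.DataFrame,
    column_map: dict[str, str] | None = None,
    *,
    shear_floor: float = DEFAULT_CLEANING_FLOOR,
    temperature: float | None = None,
    direction: str = "up",
    formulation: Formulation | None = None,
) -> FlowCurve:
    """Read a flow-curve CSV (or DataFrame) into a validated :class:`FlowCurve`.

    ``column_map`` maps the logical names ``shear_rate`` and ``viscosity``
    to the file's column headers (defaults ``shear_rate_1_per_s`` and
    ``viscosity_Pa_s``).  Rows with γ̇ ≤ ``shear_floor`` or non-finite /
    non-positive viscosity are dropped and counted; remaining rows are
    sorted by shear rate.  Fewer than 5 usable rows is an error, as is a
    missing column (named in the message).
    """
    cmap = {"shear_rate": "shear_rate_1_per_s", "viscosity": "viscosity_Pa_s"}
    if column_map:
        cmap.update(column_map)

    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    for logical, col in cmap.items():
        if col not in df.columns:
            raise ValueError(
                f"missing {logical} column {col!r} (have: {list(df.columns)})"
            )

    gdot = pd.to_numeric(df[cmap["shear_rate"]], errors="coerce").to_numpy(float)
    mu = pd.to_numeric(df[cmap["viscosity"]], errors="coerce").to_numpy(float)
    keep = np.isfinite(gdot) & np.isfinite(mu) & (gdot > shear_floor) & (mu > 0)
    n_dropped = int(len(df) - keep.sum())
    gdot, mu = gdot[keep], mu[keep]
    order = np.argsort(gdot, kind="stable")
    gdot, mu = gdot[order], mu[order]
    # collapse duplicate shear rates (averaging) so the sweep is strictly increasing
    if gdot.size and np.any(np.diff(gdot) <= 0):
        uniq, inv = np.unique(gdot, return_inverse=True)
        mu = np.bincount(inv, weights=mu) / np.bincount(inv)
        gdot = uniq
    if gdot.size < 5:
        raise ValueError(
            f"only {gdot.size} usable rows after cleaning (need >= 5); "
            f"{n_dropped} dropped"
        )
    return FlowCurve(
        shear_rates=gdot,
        viscosities=mu,
        temperature=temperature,
        direction=direction,
        formulation=formulation,
        n_dropped=n_dropped,
    )


def _power_law(gdot: np.ndarray, K: float, n: float) -> np.ndarray:
    return K * gdot ** (n - 1.0)


def fit_power_law(
    curve: FlowCurve,
    weighting: str = "inverse_square",
    *,
    max_iterations: int = 200,
) -> PowerLawFit:
    """Fit µ = K γ̇^(n−1) by weighted damped least squares.

    With ``weighting="inverse_square"`` the objective is
    Σ (µᵢ − K γ̇ᵢ^(n−1))² / µᵢ² — identical to an unweighted fit of the
    relative residuals.  ``weighting="none"`` uses unit weights.  The
    initial guess comes from an ordinary least-squares line in
    log µ – log γ̇ space, which is near-global for power-law data; a
    bounded trust-region Levenberg–Marquardt-type refinement follows.
    Non-convergence within ``max_iterations`` returns the best point
    found with ``converged=False``.
    """
    if weighting not in ("inverse_square", "none"):
        raise ValueError("weighting must be 'inverse_square' or 'none'")
    gdot = curve.shear_rates
    mu = curve.viscosities
    sqrt_w = 1.0 / mu if weighting == "inverse_square" else np.ones_like(mu)

    # log–log OLS initial guess: log µ = log K + (n−1) log γ̇
    slope, intercept = np.polyfit(np.log(gdot), np.log(mu), 1)
    K0 = float(np.exp(intercept))
    n0 = float(slope + 1.0)
    K0 = min(max(K0, _K_BOUNDS[0] * 10), _K_BOUNDS[1] / 10)
    n0 = min(max(n0, _N_BOUNDS[0] + 1e-3), _N_BOUNDS[1] - 1e-3)

    def residuals(theta: np.ndarray) -> np.ndarray:
        K, n = theta
        return sqrt_w * (mu - _power_law(gdot, K, n))

    result = least_squares(
        residuals,
        x0=[K0, n0],
        bounds=([_K_BOUNDS[0], _N_BOUNDS[0]], [_K_BOUNDS[1], _N_BOUNDS[1]]),
        method="trf",
        x_scale=[max(K0, 1e-8), 1.0],
        max_nfev=max_iterations * 2,
    )
    K_hat, n_hat = map(float, result.x)
    tol = 1e-6
    at_bounds = (
        K_hat <= _K_BOUNDS[0] * (1 + tol)
        or K_hat >= _K_BOUNDS[1] * (1 - tol)
        or n_hat <= _N_BOUNDS[0] + tol
        or n_hat >= _N_BOUNDS[1] - tol
    )
    return PowerLawFit(
        consistency_index=K_hat,
        flow_index=n_hat,
        weighting=weighting,
        rss=float(2.0 * result.cost),
        n_points=len(curve),
        converged=bool(result.status > 0),
        at_bounds=at_bounds,
    )


def apparent_viscosity(
    fit: PowerLawFit,
    shear_rate: float | np.ndarray,
    floor: float = DEFAULT_SHEAR_FLOOR,
) -> float | np.ndarray:
    """Evaluate µ = K·max(γ̇, floor)^(n−1).

    The floor regularises the n < 1 singularity at γ̇ = 0, mirroring the
    finite minimum shear rate used to keep the centerline viscosity finite
    in nozzle-flow calculations.  Total on any non-negative shear rate.
    """
    if not floor > 0:
        raise ValueError("floor must be > 0")
    gdot = np.maximum(np.asarray(shear_rate, dtype=float), floor)
    out = fit.K * gdot ** (fit.n - 1.0)
    return float(out) if np.isscalar(shear_rate) or out.ndim == 0 else out


def summarize_moduli(sweep: ModuliSweep, lve_strain_max: float) -> ModuliSummary:
    """Average G′ and G″ over the linear viscoelastic window (strain ≤ max).

    tan δ is taken as the ratio of the window means.  Fewer than 3 points
    inside the window is an error.
    """
    mask = sweep.strains <= lve_strain_max
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} points with strain <= {lve_strain_max} "
            "(need >= 3 in the linear viscoelastic window)"
        )
    g1 = float(np.mean(sweep.storage_modulus[mask]))
    g2 = float(np.mean(sweep.loss_modulus[mask]))
    return ModuliSummary(
        mean_storage=g1,
        mean_loss=g2,
        tan_delta=g2 / g1 if g1 > 0 else float("inf"),
        n_points=int(mask.sum()),
        lve_strain_max=lve_strain_max,
    )
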