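"""Deterministic synthetic measurement generators.

Seeded generators producing every input the toolbox consumes, emulating
the bench protocols: log-spaced rheometer flow curves with optional
multiplicative lognormal noise, leading-edge ligament displacement
series on a 50 µs imaging grid with Gaussian position jitter, and
gravimetric burst-mass series with a stated coefficient of variation and
a linear volume-vs-dwell response.  All generators are pure functions of
(parameters, seed): the same spec yields byte-identical arrays.

These fixtures emulate the statistical structure of the measurements
(noise scale, grid, series lengths), not instrument artifacts such as
inertial ring-up, edge fracture or evaporation drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ligament import DisplacementSeries, DropMassSeries
from .rheology import FlowCurve
from .units import Formulation

__all__ = [
    "SynthSpec",
    "gen_flow_curve",
    "gen_displacement",
    "gen_drop_masses",
    "write_fixture_tree",
]

_NOISE_MODELS = ("none", "multiplicative_lognormal", "additive_gaussian")

#: Imaging frame interval of the displacement sweep protocol, s.
DEFAULT_FRAME_DT = 50e-6


@dataclass(frozen=True)
class SynthSpec:
    """Seed and noise model for one generated artifact."""

    seed: int = 0
    noise_model: str = "none"
    noise_level: float = 0.0  # relative SD (fraction, not percent)

    def __post_init__(self) -> None:
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {_NOISE_MODELS}")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.noise_model != "none" and self.noise_level == 0:
            object.__setattr__(self, "noise_model", "none")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(values: np.ndarray, spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "none" or spec.noise_level == 0:
        return values
    if spec.noise_model == "multiplicative_lognormal":
        # lognormal with relative SD ~ noise_level and unit median
        return values * np.exp(rng.normal(0.0, spec.noise_level, size=values.shape))
    return values + rng.normal(0.0, spec.noise_level * np.abs(values), size=values.shape)


def gen_flow_curve(
    K: float,
    n: float,
    grid: tuple[float, float, int] = (0.1, 1000.0, 30),
    spec: SynthSpec = SynthSpec(),
    formulation: Formulation | None = None,
) -> FlowCurve:
    """Synthetic power-law flow curve µᵢ = K γ̇ᵢ^(n−1)·noiseᵢ.

    Shear rates are log-spaced over ``grid`` (default 0.1–1000 1/s, the
    steady-shear sweep range of a cone-plate rheometer protocol).
    """
    if not K > 0:
        raise ValueError("K must be > 0")
    if not 0.05 < n <= 1.5:
        raise ValueError("n must lie in (0.05, 1.5]")
    lo, hi, count = grid
    gdot = np.geomspace(lo, hi, int(count))
    mu = K * gdot ** (n - 1.0)
    mu = _apply_noise(mu, spec, spec.rng())
    return FlowCurve(shear_rates=gdot, viscosities=mu, formulation=formulation)


def gen_displacement(
    v: float,
    frame_dt: float = DEFAULT_FRAME_DT,
    frames: int = 37,
    jitter_sd: float = 0.0,
    spec: SynthSpec = SynthSpec(),
) -> DisplacementSeries:
    """Synthetic leading-edge displacement sweep: x = v·t + Gaussian jitter."""
    if v < 0:
        raise ValueError("v must be >= 0")
    if frames < 3:
        raise ValueError("frames must be >= 3")
    t = frame_dt * np.arange(1, frames + 1)
    x = v * t
    if jitter_sd > 0:
        x = x + spec.rng().normal(0.0, jitter_sd, size=x.shape)
    return DisplacementSeries(times=t, positions=x)


def gen_drop_masses(
    V: float,
    rho: float,
    cv: float = 0.0,
    bursts: int = 3,
    drops: int = 1000,
    dwell_set: tuple[float, ...] = (1e-3,),
    slope: float = 0.0,
    spec: SynthSpec = SynthSpec(),
) -> DropMassSeries:
    """Synthetic gravimetric burst masses for volume calibration.

    Per-burst mass = drops·ρ·(V + slope·(dwell − dwell₀))·(1 + ε) with
    ε ~ N(0, cv/100) — ``cv`` is the coefficient of variation in percent.
    ``bursts`` repetitions are generated at every dwell in ``dwell_set``
    (dwell₀ is the first entry, the operating point); ``slope`` is the
    volume-per-dwell response used to emulate the linearity check.
    """
    if not (V > 0 and rho > 0):
        raise ValueError("V and rho must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = spec.rng()
    dwell0 = dwell_set[0]
    dwells, masses = [], []
    for dwell in dwell_set:
        v_true = V + slope * (dwell - dwell0)
        if not v_true > 0:
            raise ValueError("slope drives per-drop volume non-positive")
        for _ in range(bursts):
            eps = rng.normal(0.0, cv / 100.0) if cv > 0 else 0.0
            masses.append(drops * rho * v_true * (1.0 + eps))
            dwells.append(dwell)
    return DropMassSeries(
        burst_masses=np.array(masses),
        drops_per_burst=drops,
        dwell_times=np.array(dwells),
        solution_density=rho,
    )


def write_fixture_tree(
    directory: str | Path,
    seed: int = 0,
    K: float = 0.05,
    n: float = 0.6,
    rho: float = 1000.0,
    V: float = 6.0e-11,
    v: float = 4.0,
) -> dict[str, Path]:
    """Write a CSV fixture bundle matching the loaders' dialects.

    Produces ``flow_curve.csv``, ``displacement.csv`` and ``bursts.csv``
    under ``directory`` and returns their paths.  Used by the ``synth``
    CLI subcommand and by end-to-end tests.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    curve = gen_flow_curve(K, n, spec=SynthSpec(seed=seed, noise_model="multiplicative_lognormal", noise_level=0.01))
    disp = gen_displacement(v, frames=37, jitter_sd=1e-5, spec=SynthSpec(seed=seed + 1))
    masses = gen_drop_masses(
        V, rho, cv=1.0, dwell_set=(1e-3, 0.8e-3, 1.2e-3), slope=V / 1e-3 * 0.5,
        spec=SynthSpec(seed=seed + 2),
    )
    paths = {
        "flow_curve": directory / "flow_curve.csv",
        "displacement": directory / "displacement.csv",
        "bursts": directory / "bursts.csv",
    }
    pd.DataFrame(
        {"shear_rate_1_per_s": curve.shear_rates, "viscosity_Pa_s": curve.viscosities}
    ).to_csv(paths["flow_curve"], index=False)
    pd.DataFrame({"time_s": disp.times, "position_m": disp.positions}).to_csv(
        paths["displacement"], index=False
    )
    pd.DataFrame(
        {
            "dwell_s": masses.dwell_times,
            "mass_kg": masses.burst_masses,
            "drops": masses.drops_per_burst,
        }
    ).to_csv(paths["bursts"], index=False)
    return paths
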