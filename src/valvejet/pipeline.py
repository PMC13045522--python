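"""Run configuration, pipeline orchestration and report I/O.

A :class:`RunConfig` (JSON or YAML) names the measurement tables and the
fluid/nozzle parameters for each printing condition plus any threshold
overrides; :func:`run_pipeline` chains the stages — flow-curve fit →
ligament metrology → dimensionless set → nozzle flow → regime label —
producing one self-contained :class:`ConditionReport` per condition and
the six printability-map datasets.  A failing stage marks that
condition's report failed and the pipeline continues with the others.

Conditions may alternatively come from a pre-computed "dimensionless
table" CSV (columns formulation, t20, We, Re, Oh, Fr and optionally
L_l_mm, L_ar), in which case fit/ligament fields are absent but maps are
still produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .jetting import (
    DimensionlessSet,
    FluidProperties,
    JetConditions,
    characteristic_viscosity,
    dimensionless_numbers,
    oh_from_we_re,
    splash_parameter,
)
from .ligament import (
    DropMassSeries,
    LigamentMetrics,
    aspect_ratio,
    calibrate_drop_volume,
    DisplacementSeries,
    equivalent_diameter,
    estimate_velocity,
)
from .nozzle_flow import NozzleGeometry, flow_rate_from_ligament, solve_nozzle_flow
from .regimes import (
    DEFAULT_FREQUENCY_TABLE,
    DEFAULT_SPLASH_THRESHOLD,
    MAP_TYPES,
    MapDataset,
    RegimeLabel,
    build_map,
    classify,
)
from .rheology import DEFAULT_SHEAR_FLOOR, PowerLawFit, fit_power_law, load_flow_curve
from .units import Formulation, PhysicalConstants

__all__ = [
    "RunConfig",
    "ConditionSpec",
    "ConditionReport",
    "load_config",
    "run_pipeline",
    "write_report",
    "load_dimensionless_table",
]

logger = logging.getLogger(__name__)


@dataclass
class ConditionSpec:
    """Inputs for one printing condition (paths relative to the config file)."""

    name: str
    formulation: Formulation
    density: float  # kg/m³
    surface_tension: float  # N/m
    flow_curve_csv: str | None = None
    displacement_csv: str | None = None
    bursts_csv: str | None = None
    viscosity: float | None = None  # measured high-shear viscosity, Pa·s (overrides fit path)
    contact_angle_deg: float | None = None  # stored measurement; never computed


@dataclass
class RunConfig:
    conditions: list[ConditionSpec]
    nozzle_diameter: float = 250e-6  # m
    nozzle_length: float = 8.4e-4  # m
    dwell_time: float = 1e-3  # s
    jetting_frequency: float = 200.0  # Hz
    g: float = 9.80665
    shear_floor: float = DEFAULT_SHEAR_FLOOR  # 1/s
    splash_threshold: float = DEFAULT_SPLASH_THRESHOLD
    alpha: float = 2.0  # viscous pinch-off factor coefficient
    frequency_table: tuple = DEFAULT_FREQUENCY_TABLE
    output_dir: str = "."
    base_dir: Path = field(default_factory=Path)

    def resolve(self, p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else self.base_dir / path


@dataclass
class ConditionReport:
    """Self-contained per-condition result mirroring one summary-table row."""

    name: str
    formulation: Formulation
    t20: bool
    cell_density: float
    ok: bool = True
    failed_stage: str | None = None
    error: str | None = None
    fit: PowerLawFit | None = None
    numbers: DimensionlessSet | None = None
    metrics: LigamentMetrics | None = None
    label: RegimeLabel | None = None
    wall_shear_rate: float | None = None  # 1/s
    wall_viscosity: float | None = None  # Pa·s
    contact_angle_deg: float | None = None
    viscosity_source: str | None = None  # "measured" | "power_law_fit at v/D"
    provenance: dict[str, Any] = field(default_factory=dict)


def _formulation_from_dict(d: dict[str, Any]) -> Formulation:
    return Formulation(
        bioink_name=d["bioink_name"],
        concentration=float(d["concentration"]),
        concentration_unit=d.get("concentration_unit", "mg/mL"),
        surfactant_fraction=float(d.get("surfactant_fraction", 0.0)),
        cell_density=float(d.get("cell_density", 0.0)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a run configuration from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    conditions = [
        ConditionSpec(
            name=c["name"],
            formulation=_formulation_from_dict(c["formulation"]),
            density=float(c["density"]),
            surface_tension=float(c["surface_tension"]),
            flow_curve_csv=c.get("flow_curve_csv"),
            displacement_csv=c.get("displacement_csv"),
            bursts_csv=c.get("bursts_csv"),
            viscosity=c.get("viscosity"),
            contact_angle_deg=c.get("contact_angle_deg"),
        )
        for c in raw.get("conditions", [])
    ]
    cfg = RunConfig(conditions=conditions, base_dir=path.parent)
    for key in ("nozzle_diameter", "nozzle_length", "dwell_time", "jetting_frequency",
                "g", "shear_floor", "splash_threshold", "alpha", "output_dir"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "frequency_table" in raw:
        cfg.frequency_table = tuple(tuple(row) for row in raw["frequency_table"])
    for cond in conditions:
        for attr in ("flow_curve_csv", "displacement_csv", "bursts_csv"):
            p = getattr(cond, attr)
            if p is not None and not cfg.resolve(p).exists():
                raise FileNotFoundError(f"{cond.name}: {attr} {p!r} does not exist")
    return cfg


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        dataclasses.asdict(config), default=str, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _process_condition(cond: ConditionSpec, config: RunConfig) -> ConditionReport:
    report = ConditionReport(
        name=cond.name,
        formulation=cond.formulation,
        t20=cond.formulation.has_surfactant,
        cell_density=cond.formulation.cell_density,
        contact_angle_deg=cond.contact_angle_deg,
    )
    stage = "init"
    try:
        stage = "rheology"
        if cond.flow_curve_csv is not None:
            curve = load_flow_curve(
                config.resolve(cond.flow_curve_csv), formulation=cond.formulation
            )
            report.fit = fit_power_law(curve)

        stage = "velocity"
        velocity = None
        if cond.displacement_csv is not None:
            df = pd.read_csv(config.resolve(cond.displacement_csv))
            series = DisplacementSeries(
                times=df["time_s"].to_numpy(float),
                positions=df["position_m"].to_numpy(float),
            )
            velocity = estimate_velocity(series).velocity

        stage = "calibration"
        v_lig = None
        if cond.bursts_csv is not None:
            df = pd.read_csv(config.resolve(cond.bursts_csv))
            series = DropMassSeries(
                burst_masses=df["mass_kg"].to_numpy(float),
                drops_per_burst=int(df["drops"].iloc[0]),
                dwell_times=df["dwell_s"].to_numpy(float),
                solution_density=cond.density,
            )
            calib = calibrate_drop_volume(series)
            v_lig = calib.per_drop_volume
            report.provenance["calibration"] = {
                "cv_percent": calib.cv,
                "linearity_r2": calib.linearity_r2,
                "accepted": calib.accepted,
            }

        stage = "dimensionless"
        if velocity is not None:
            jet = JetConditions(
                jet_velocity=velocity,
                nozzle_diameter=config.nozzle_diameter,
                dwell_time=config.dwell_time,
                jetting_frequency=config.jetting_frequency,
            )
            if cond.viscosity is not None:
                mu = cond.viscosity
                report.viscosity_source = "measured"
            elif report.fit is not None:
                mu = characteristic_viscosity(report.fit, jet)
                report.viscosity_source = "power_law_fit at gamma_c=v/D"
            else:
                raise ValueError("no viscosity path: need viscosity or flow_curve_csv")
            fluid = FluidProperties(
                density=cond.density,
                surface_tension=cond.surface_tension,
                characteristic_viscosity=mu,
            )
            report.numbers = dimensionless_numbers(
                fluid, jet, PhysicalConstants(g=config.g)
            )

        stage = "ligament"
        if v_lig is not None and velocity is not None:
            # ligament length from kinematics: distance travelled over the dwell
            length = velocity * config.dwell_time
            report.metrics = LigamentMetrics(
                volume=v_lig,
                length=length,
                aspect_ratio=aspect_ratio(length, config.nozzle_diameter),
                equivalent_diameter=equivalent_diameter(v_lig),
                velocity=velocity,
            )

        stage = "nozzle_flow"
        if v_lig is not None and report.fit is not None:
            q = flow_rate_from_ligament(v_lig, config.dwell_time)
            profile = solve_nozzle_flow(
                report.fit,
                q,
                NozzleGeometry(radius=config.nozzle_diameter / 2, length=config.nozzle_length),
                floor=config.shear_floor,
            )
            report.wall_shear_rate = profile.wall_shear_rate
            report.wall_viscosity = profile.wall_viscosity

        stage = "regimes"
        if report.numbers is not None:
            report.label = classify(
                report.numbers, config.splash_threshold, config.frequency_table
            )
    except Exception as exc:  # isolation: one bad condition must not kill the run
        report.ok = False
        report.failed_stage = stage
        report.error = f"{type(exc).__name__}: {exc}"
        logger.error("condition %s failed at stage %s: %s", cond.name, stage, exc)
    return report


def run_pipeline(config: RunConfig) -> tuple[list[ConditionReport], dict[str, MapDataset]]:
    """Run every condition through the full analysis and build all six maps."""
    if not config.conditions:
        raise ValueError("config has no conditions")
    cfg_hash = _config_hash(config)
    reports = []
    for cond in config.conditions:
        report = _process_condition(cond, config)
        report.provenance.update(
            {
                "config_hash": cfg_hash,
                "software_version": __version__,
                "inputs": {
                    k: v
                    for k, v in (
                        ("flow_curve_csv", cond.flow_curve_csv),
                        ("displacement_csv", cond.displacement_csv),
                        ("bursts_csv", cond.bursts_csv),
                    )
                    if v is not None
                },
                "thresholds": {
                    "splash_threshold": config.splash_threshold,
                    "shear_floor": config.shear_floor,
                    "alpha": config.alpha,
                    "frequency_table": [list(r) for r in config.frequency_table],
                },
            }
        )
        reports.append(report)

    records = [(r.numbers, r.metrics, r.formulation) for r in reports]
    names = [r.name for r in reports]
    freqs = [config.jetting_frequency] * len(reports)
    maps = {
        mt: build_map(records, mt, frequencies=freqs, names=names,
                      splash_threshold=config.splash_threshold)
        for mt in MAP_TYPES
    }
    return reports, maps


def load_dimensionless_table(path: str | Path, nozzle_diameter: float = 250e-6):
    """Load a pre-computed dimensionless table CSV into map-ready records.

    Expected columns: ``formulation``, ``concentration``, ``t20`` (0/1),
    ``We``, ``Re``, ``Fr`` and optionally ``Oh``, ``L_l_mm``.  A missing
    Oh column is filled from √We/Re; L_ar is L_l/D when lengths are given.
    Returns ``(records, names)`` suitable for :func:`~valvejet.regimes.build_map`.
    """
    df = pd.read_csv(path)
    for col in ("We", "Re", "Fr"):
        if col not in df.columns:
            raise ValueError(f"dimensionless table missing column {col!r}")
    records, names = [], []
    for _, row in df.iterrows():
        oh = float(row["Oh"]) if "Oh" in df.columns and np.isfinite(row.get("Oh", np.nan)) \
            else oh_from_we_re(float(row["We"]), float(row["Re"]))
        we, re, fr = float(row["We"]), float(row["Re"]), float(row["Fr"])
        numbers = DimensionlessSet(
            weber=we, reynolds=re, ohnesorge=oh, froude=fr,
            z_number=1.0 / oh, splash_parameter=splash_parameter(oh, re),
            bond=we / fr**2,
        )
        form = None
        if "formulation" in df.columns:
            try:
                form = Formulation(
                    bioink_name=str(row["formulation"]),
                    concentration=float(row.get("concentration", 1.0)),
                    concentration_unit=str(row.get("concentration_unit", "mg/mL")),
                    surfactant_fraction=1e-5 if int(row.get("t20", 0)) else 0.0,
                )
            except ValueError:
                form = None
        metrics = None
        if "L_l_mm" in df.columns and np.isfinite(row["L_l_mm"]):
            length = float(row["L_l_mm"]) * 1e-3
            metrics = LigamentMetrics(
                volume=6e-11, length=length,
                aspect_ratio=aspect_ratio(length, nozzle_diameter),
                equivalent_diameter=equivalent_diameter(6e-11),
                velocity=1.0,
            )
        records.append((numbers, metrics, form))
        names.append(str(row.get("formulation", f"row{len(names)}")))
    return records, names


def _report_to_dict(report: ConditionReport) -> dict[str, Any]:
    d: dict[str, Any] = {
        "name": report.name,
        "formulation": dataclasses.asdict(report.formulation),
        "t20": report.t20,
        "cell_density": report.cell_density,
        "ok": report.ok,
        "failed_stage": report.failed_stage,
        "error": report.error,
        "contact_angle_deg": report.contact_angle_deg,
        "viscosity_source": report.viscosity_source,
        "wall_shear_rate_1_per_s": report.wall_shear_rate,
        "wall_viscosity_Pa_s": report.wall_viscosity,
        "provenance": report.provenance,
    }
    if report.fit is not None:
        d["fit"] = {
            "K_Pa_sn": report.fit.K,
            "n": report.fit.n,
            "weighting": report.fit.weighting,
            "rss": report.fit.rss,
            "n_points": report.fit.n_points,
            "converged": report.fit.converged,
        }
    if report.numbers is not None:
        d["dimensionless"] = dataclasses.asdict(report.numbers)
    if report.metrics is not None:
        d["ligament"] = dataclasses.asdict(report.metrics)
    if report.label is not None:
        d["regime"] = {
            "z_class": report.label.z_class,
            "splash_class": report.label.splash_class,
            "frequency_band_hz": list(report.label.frequency_band),
            "rationale": report.label.rationale,
        }
    return d


def write_report(
    reports: list[ConditionReport], path: str | Path, format: str = "json"
) -> Path:
    """Write condition reports as JSON (lossless) or a flattened CSV.

    The CSV flattening keeps one row per condition with dotted column
    names for nested fields; column order is deterministic across runs.
    """
    path = Path(path)
    dicts = [_report_to_dict(r) for r in reports]
    if format == "json":
        path.write_text(json.dumps(dicts, indent=2, sort_keys=True, default=float))
    elif format == "csv":
        flat = [pd.json_normalize(d, sep=".").iloc[0].to_dict() for d in dicts]
        df = pd.DataFrame(flat)
        df = df.reindex(sorted(df.columns), axis=1)
        df.to_csv(path, index=False)
    else:
        raise ValueError("format must be 'json' or 'csv'")
    return path
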