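"""Regime classification and printability-map construction.

Classification follows the canonical drop-on-demand bands in the
Z = 1/Oh coordinate: robust single-drop ("printable") operation for
1 ≤ Z ≤ 10 (both boundaries printable), satellite-prone breakup for
Z > 10, and viscous/energy-limited behaviour for Z < 1.  Substrate
impact is classed by the splash parameter K = Oh·Re^1.25 against a
configurable threshold K_c (default 57.7, the classical deposition/
splash limit from the droplet-impact literature — not a value fitted
here).  Actuation-frequency recommendations are a piecewise band table
in Z, clipped to the 20–200 Hz operating window of a solenoid
microvalve, encoding the practical guidance that high-Z (low-Oh) inks
need low frequencies to suppress satellites while mid-Z inks tolerate
the upper band.

Printability maps place each condition in one of six dimensionless
planes (L_ar–Oh, We–Fr, We–Oh, We–Re, Oh–Re, Oh–f) together with the
Z = 1 and Z = 10 regime boundaries expressed in that plane's
coordinates (Re = Z·√We in We–Re space; vertical/horizontal Oh lines
elsewhere; the 20/200 Hz operating lines on Oh–f).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .jetting import DimensionlessSet
from .ligament import LigamentMetrics
from .units import Formulation

__all__ = [
    "RegimeLabel",
    "MapDataset",
    "MapPoint",
    "ZoneBoundary",
    "classify_z",
    "classify_splash",
    "recommend_frequency",
    "classify",
    "build_map",
    "plot_map",
    "MAP_TYPES",
    "DEFAULT_SPLASH_THRESHOLD",
    "DEFAULT_FREQUENCY_TABLE",
    "OPERATING_BAND_HZ",
]

logger = logging.getLogger(__name__)

#: Classical deposition/splash threshold for K = Oh·Re^1.25 (literature
#: default, configurable; not derived from the measurements analysed here).
DEFAULT_SPLASH_THRESHOLD = 57.7

#: Global microvalve operating window, Hz.
OPERATING_BAND_HZ = (20.0, 200.0)

#: Piecewise frequency-band table: (z_low, z_high, f_low, f_high).
#: Rows are closed intervals [z_low, z_high]; where a Z value falls on a
#: shared edge the band with the higher upper frequency wins, which puts
#: Z = 1 and Z = 5 in the upper band and keeps Z = 30 at 100–200 Hz.
DEFAULT_FREQUENCY_TABLE: tuple[tuple[float, float, float, float], ...] = (
    (0.0, 1.0, 20.0, 50.0),  # viscous/energy-limited: slow, let ligaments pinch off
    (1.0, 5.0, 50.0, 150.0),  # lower printable band
    (5.0, 30.0, 100.0, 200.0),  # upper printable band and moderately high Z
    (30.0, float("inf"), 20.0, 100.0),  # very high Z: damp the impulse, avoid satellites
)

MAP_TYPES = ("Lar_Oh", "We_Fr", "We_Oh", "We_Re", "Oh_Re", "Oh_f")

_Z_CLASSES = ("viscous_limited", "printable", "satellite_prone")
_SPLASH_CLASSES = ("deposition", "splash")


@dataclass(frozen=True)
class RegimeLabel:
    """Classification of one printing condition."""

    z_class: str  # viscous_limited | printable | satellite_prone
    splash_class: str  # deposition | splash
    frequency_band: tuple[float, float]  # (f_low, f_high), Hz
    rationale: str  # text trace of the thresholds applied


@dataclass(frozen=True)
class MapPoint:
    x: float
    y: float
    formulation: Formulation | None
    label: RegimeLabel | None
    name: str = ""


@dataclass(frozen=True)
class ZoneBoundary:
    """A named boundary curve in map coordinates.

    ``kind`` is ``"vline"``/``"hline"`` (constant x/y) or ``"curve"``
    (sampled (x, y) arrays).
    """

    name: str
    kind: str
    value: float | None = None
    x: np.ndarray | None = None
    y: np.ndarray | None = None


@dataclass
class MapDataset:
    map_type: str
    points: list[MapPoint] = field(default_factory=list)
    zone_boundaries: list[ZoneBoundary] = field(default_factory=list)
    x_label: str = ""
    y_label: str = ""
    n_skipped: int = 0


def classify_z(z: float) -> str:
    """Z-band label with closed boundaries: printable iff 1 ≤ Z ≤ 10."""
    if not z > 0:
        raise ValueError("Z must be > 0")
    if z < 1.0:
        return "viscous_limited"
    if z <= 10.0:
        return "printable"
    return "satellite_prone"


def classify_splash(k_splash: float, threshold: float = DEFAULT_SPLASH_THRESHOLD) -> str:
    """Splash iff K strictly exceeds the threshold; K = K_c is deposition."""
    if not (k_splash > 0 and threshold > 0):
        raise ValueError("k_splash and threshold must be > 0")
    return "splash" if k_splash > threshold else "deposition"


def recommend_frequency(
    z: float,
    oh: float | None = None,
    table: tuple[tuple[float, float, float, float], ...] = DEFAULT_FREQUENCY_TABLE,
    operating_band: tuple[float, float] = OPERATING_BAND_HZ,
) -> tuple[float, float]:
    """Recommended actuation-frequency band (f_low, f_high) for a given Z.

    Rows of ``table`` are closed intervals in Z; when Z sits exactly on
    an edge shared by two rows, the row with the higher upper frequency
    wins (so the default table sends Z = 1 to 50–150 Hz, Z = 5 and
    Z = 30 to 100–200 Hz).  The result is clipped to the global
    operating window.  ``oh`` is accepted for symmetry with the maps but
    the default table is a function of Z alone.
    """
    if not z > 0:
        raise ValueError("Z must be > 0")
    matches = [(f_lo, f_hi) for z_lo, z_hi, f_lo, f_hi in table if z_lo <= z <= z_hi]
    if not matches:  # above every row: fall back to the last row's band
        band = table[-1][2:]
    else:
        band = max(matches, key=lambda b: b[1])
    f_lo = min(max(band[0], operating_band[0]), operating_band[1])
    f_hi = min(max(band[1], operating_band[0]), operating_band[1])
    if not f_lo < f_hi:
        raise ValueError("degenerate frequency band after clipping")
    return (f_lo, f_hi)


def classify(
    numbers: DimensionlessSet,
    splash_threshold: float = DEFAULT_SPLASH_THRESHOLD,
    frequency_table: tuple[tuple[float, float, float, float], ...] = DEFAULT_FREQUENCY_TABLE,
) -> RegimeLabel:
    """Full regime label (Z band, splash class, frequency band) with trace."""
    z = numbers.z_number
    zc = classify_z(z)
    sc = classify_splash(numbers.splash_parameter, splash_threshold)
    band = recommend_frequency(z, numbers.ohnesorge, frequency_table)
    rationale = (
        f"Z={z:.4g} -> {zc} (printable band 1<=Z<=10); "
        f"K_splash={numbers.splash_parameter:.4g} vs K_c={splash_threshold:g} -> {sc}; "
        f"frequency band {band[0]:g}-{band[1]:g} Hz from Z table, "
        f"clipped to {OPERATING_BAND_HZ[0]:g}-{OPERATING_BAND_HZ[1]:g} Hz"
    )
    return RegimeLabel(z_class=zc, splash_class=sc, frequency_band=band, rationale=rationale)


_AXIS_LABELS = {
    "Lar_Oh": ("Oh", "L_ar"),
    "We_Fr": ("We", "Fr"),
    "We_Oh": ("We", "Oh"),
    "We_Re": ("We", "Re"),
    "Oh_Re": ("Oh", "Re"),
    "Oh_f": ("Oh", "f (Hz)"),
}


def _coordinates(
    map_type: str,
    numbers: DimensionlessSet | None,
    metrics: LigamentMetrics | None,
    frequency: float | None,
) -> tuple[float, float] | None:
    """(x, y) for one record on one map, or None if a coordinate is missing."""
    if map_type == "Lar_Oh":
        if numbers is None or metrics is None:
            return None
        return (numbers.ohnesorge, metrics.aspect_ratio)
    if numbers is None:
        return None
    if map_type == "We_Fr":
        return (numbers.weber, numbers.froude)
    if map_type == "We_Oh":
        return (numbers.weber, numbers.ohnesorge)
    if map_type == "We_Re":
        return (numbers.weber, numbers.reynolds)
    if map_type == "Oh_Re":
        return (numbers.ohnesorge, numbers.reynolds)
    if map_type == "Oh_f":
        if frequency is None:
            return None
        return (numbers.ohnesorge, frequency)
    raise ValueError(f"unknown map_type {map_type!r}; valid: {MAP_TYPES}")


def _boundaries(map_type: str, points: list[MapPoint]) -> list[ZoneBoundary]:
    """Z = 1 and Z = 10 loci in this map's coordinates, plus f lines on Oh–f."""
    bounds: list[ZoneBoundary] = []
    if map_type in ("We_Oh",):
        bounds += [
            ZoneBoundary("Z=1 (Oh=1)", "hline", 1.0),
            ZoneBoundary("Z=10 (Oh=0.1)", "hline", 0.1),
        ]
    elif map_type in ("Lar_Oh", "Oh_Re", "Oh_f"):
        bounds += [
            ZoneBoundary("Z=1 (Oh=1)", "vline", 1.0),
            ZoneBoundary("Z=10 (Oh=0.1)", "vline", 0.1),
        ]
    elif map_type == "We_Re":
        # Oh = sqrt(We)/Re = 1/Z  =>  Re = Z·sqrt(We)
        we_lo = min((p.x for p in points), default=0.1)
        we_hi = max((p.x for p in points), default=1e3)
        we = np.geomspace(max(we_lo / 3, 1e-6), we_hi * 3, 64)
        for z in (1.0, 10.0):
            bounds.append(
                ZoneBoundary(f"Z={z:g} (Re={z:g}·√We)", "curve", None, we, z * np.sqrt(we))
            )
    if map_type == "Oh_f":
        bounds += [
            ZoneBoundary("f=20 Hz", "hline", OPERATING_BAND_HZ[0]),
            ZoneBoundary("f=200 Hz", "hline", OPERATING_BAND_HZ[1]),
        ]
    return bounds


def build_map(
    records: list[tuple[DimensionlessSet | None, LigamentMetrics | None, Formulation | None]],
    map_type: str,
    frequencies: list[float] | None = None,
    names: list[str] | None = None,
    splash_threshold: float = DEFAULT_SPLASH_THRESHOLD,
) -> MapDataset:
    """Place condition records on one printability map.

    Each record is (numbers, ligament metrics, formulation); records
    lacking a coordinate needed by ``map_type`` are skipped and counted.
    Every placed point carries the regime label recomputed from its own
    dimensionless set, so maps never relabel.
    """
    if map_type not in MAP_TYPES:
        raise ValueError(f"unknown map_type {map_type!r}; valid: {MAP_TYPES}")
    if not records:
        raise ValueError("need at least one record")
    x_label, y_label = _AXIS_LABELS[map_type]
    ds = MapDataset(map_type=map_type, x_label=x_label, y_label=y_label)
    for i, (numbers, metrics, formulation) in enumerate(records):
        freq = frequencies[i] if frequencies is not None else None
        coords = _coordinates(map_type, numbers, metrics, freq)
        if coords is None:
            ds.n_skipped += 1
            logger.warning("record %d skipped on %s map: missing coordinate", i, map_type)
            continue
        label = classify(numbers, splash_threshold) if numbers is not None else None
        ds.points.append(
            MapPoint(
                x=coords[0],
                y=coords[1],
                formulation=formulation,
                label=label,
                name=names[i] if names is not None else (
                    formulation.label() if formulation else f"record {i}"
                ),
            )
        )
    ds.zone_boundaries = _boundaries(map_type, ds.points)
    return ds


def plot_map(dataset: MapDataset, path=None, ax=None):
    """Render a map dataset with matplotlib (log axes where data span >2 decades)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    xs = np.array([p.x for p in dataset.points])
    ys = np.array([p.y for p in dataset.points])
    colors = {"viscous_limited": "tab:red", "printable": "tab:green",
              "satellite_prone": "tab:orange", None: "tab:gray"}
    for p in dataset.points:
        zc = p.label.z_class if p.label else None
        marker = "^" if (p.formulation and p.formulation.has_surfactant) else "o"
        ax.scatter(p.x, p.y, c=colors.get(zc, "tab:gray"), marker=marker, edgecolors="k",
                   zorder=3)
    for b in dataset.zone_boundaries:
        if b.kind == "vline":
            ax.axvline(b.value, ls="--", lw=1, color="k", alpha=0.6)
        elif b.kind == "hline":
            ax.axhline(b.value, ls="--", lw=1, color="k", alpha=0.6)
        else:
            ax.plot(b.x, b.y, ls="--", lw=1, color="k", alpha=0.6)
    for arr, setter in ((xs, ax.set_xscale), (ys, ax.set_yscale)):
        if arr.size and arr.min() > 0 and arr.max() / arr.min() > 100:
            setter("log")
    ax.set_xlabel(dataset.x_label)
    ax.set_ylabel(dataset.y_label)
    ax.set_title(f"{dataset.map_type} printability map")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
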