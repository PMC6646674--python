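"""Soil water bucket accounting, irrigation triggering, and shelter accounting.

The plant-available soil water is a single bucket of capacity WHC (water
holding capacity, mm over the rooted profile, = sum over horizons of
thickness x (theta_fc - theta_wp)).  Each day

    storage' = clamp(storage + rain + irrigation - ET, 0, WHC)

with the excess routed to drainage; mass balance closes exactly every day.
A Sinclair-style response maps the available fraction storage/WHC to a
stress factor in [0, 1] (1 = no stress) that crop models use to slow
potential growth and transpiration.  This bucket is a deliberately simple
stand-in for a full daily carbon/water/nitrogen soil-crop model: it
reproduces the platform's water accounting, not its crop physiology.

Irrigation triggering follows tensiometer thresholds (Irrinov-style, deep
soil / wheat): 100 cbar at 30 cm; 80 cbar at 60 cm before flag-leaf
emergence (Z39) and 100 cbar after; well-watered management overrides to
80 cbar throughout; 120 cbar at 60 cm marks actual water stress.  Watermark
probes saturate at 200 cbar, so readings there are censored.

Shelter side-effect accounting compares cumulative PAR and degree-days
(base 0 C, mean of daily min/max) inside vs outside the protected area, and
rain-interception efficiency compares pluviometer totals under the shelter
with those outside.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SoilProfile",
    "Horizon",
    "WaterLedger",
    "TensionSeries",
    "whc",
    "step_budget",
    "run_budget",
    "sinclair_stress_factor",
    "irrigation_triggers",
    "interception_efficiency",
    "shelter_side_effects",
    "degree_day",
    "calibrate_tdr",
    "TdrCalibration",
]

PLATFORM_WHC_RANGE_MM = (102.0, 275.0)
TENSION_CAP_CBAR = 200.0
WATER_STRESS_THRESHOLD_CBAR = 120.0
HORIZON_LABELS = ("LA", "S", "C1", "C2")

#: Irrinov-style trigger thresholds (cbar) by depth and growth period.
DEFAULT_THRESHOLDS = {
    (30, "pre-Z39"): 100.0,
    (30, "post-Z39"): 100.0,
    (60, "pre-Z39"): 80.0,
    (60, "post-Z39"): 100.0,
}
WW_OVERRIDE_CBAR = 80.0


@dataclass(frozen=True)
class Horizon:
    """One soil layer: thickness (cm) and volumetric water contents at field
    capacity and wilting point (m3/m3)."""

    label: str
    thickness_cm: float
    theta_fc: float
    theta_wp: float

    def __post_init__(self) -> None:
        if self.thickness_cm <= 0:
            raise ValueError(f"horizon {self.label}: thickness must be > 0")
        if self.theta_fc <= self.theta_wp:
            raise ValueError(
                f"horizon {self.label}: theta_fc ({self.theta_fc}) must exceed theta_wp ({self.theta_wp})"
            )


@dataclass
class SoilProfile:
    """Ordered soil horizons (plowed LA, cambic S, calcaric C1/C2)."""

    horizons: Sequence[Horizon]

    def __post_init__(self) -> None:
        if not self.horizons:
            raise ValueError("profile needs at least one horizon")


def whc(profile: SoilProfile, warn_range: bool = True) -> float:
    """Water holding capacity in mm: sum of thickness_cm x 10 x (fc - wp).

    Platform soils span roughly 102-275 mm; values outside that envelope
    raise a range warning (the profile is still accepted).
    """
    total = sum(h.thickness_cm * 10.0 * (h.theta_fc - h.theta_wp) for h in profile.horizons)
    if warn_range and not PLATFORM_WHC_RANGE_MM[0] <= total <= PLATFORM_WHC_RANGE_MM[1]:
        import warnings

        warnings.warn(
            f"WHC {total:.0f} mm outside the platform's {PLATFORM_WHC_RANGE_MM} mm envelope",
            stacklevel=2,
        )
    return total


@dataclass
class WaterLedger:
    """Daily bucket state and flows (all mm)."""

    whc_mm: float
    storage_mm: float
    rows: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.storage_mm <= self.whc_mm:
            raise ValueError("initial storage must lie in [0, WHC]")

    @property
    def deficit_mm(self) -> float:
        return self.whc_mm - self.storage_mm

    @property
    def available_fraction(self) -> float:
        return self.storage_mm / self.whc_mm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def step_budget(
    ledger: WaterLedger,
    rain_mm: float,
    irrigation_mm: float,
    et_mm: float,
    date=None,
) -> WaterLedger:
    """Advance the bucket one day; mutates and returns the ledger.

    storage' = clamp(storage + rain + irrigation - ET, 0, WHC); overflow
    goes to drainage, so storage(t) - storage(t-1) = rain + irrigation - ET
    actual - drainage exactly.
    """
    for name, v in (("rain", rain_mm), ("irrigation", irrigation_mm), ("et", et_mm)):
        if v < 0:
            raise ValueError(f"negative {name}: {v}")
    raw = ledger.storage_mm + rain_mm + irrigation_mm - et_mm
    drainage = max(raw - ledger.whc_mm, 0.0)
    new_storage = min(max(raw, 0.0), ledger.whc_mm)
    # ET actually extracted (cannot draw below an empty bucket)
    et_actual = ledger.storage_mm + rain_mm + irrigation_mm - drainage - new_storage
    ledger.rows.append(
        {
            "date": date,
            "rain_mm": rain_mm,
            "irrigation_mm": irrigation_mm,
            "et_mm": et_actual,
            "et_demand_mm": et_mm,
            "drainage_mm": drainage,
            "storage_mm": new_storage,
            "deficit_mm": ledger.whc_mm - new_storage,
        }
    )
    ledger.storage_mm = new_storage
    return ledger


def run_budget(
    whc_mm: float, initial_storage_mm: float, weather: pd.DataFrame
) -> WaterLedger:
    """Run the daily bucket over a weather frame (date, rain_mm,
    irrigation_mm, et_mm columns)."""
    ledger = WaterLedger(whc_mm, initial_storage_mm)
    for _, row in weather.iterrows():
        step_budget(
            ledger,
            float(row.get("rain_mm", 0.0)),
            float(row.get("irrigation_mm", 0.0)),
            float(row.get("et_mm", 0.0)),
            date=row.get("date"),
        )
    return ledger


def sinclair_stress_factor(available_fraction: float, breakpoint: float = 0.4) -> float:
    """Stress factor in [0, 1] from the available-water fraction.

    1 (no stress) above the breakpoint fraction, declining linearly to 0 at
    an empty bucket.  Default breakpoint 0.4.
    """
    if not 0.0 <= available_fraction <= 1.0:
        raise ValueError(f"available fraction {available_fraction} outside [0, 1]")
    if not 0.0 < breakpoint <= 1.0:
        raise ValueError("breakpoint must lie in (0, 1]")
    if available_fraction >= breakpoint:
        return 1.0
    return available_fraction / breakpoint


@dataclass
class TensionSeries:
    """Soil water tension (cbar) at one probe depth over dates.

    Readings above the 200 cbar probe cap are stored censored at the cap.
    """

    depth_cm: int
    dates: list
    tension_cbar: np.ndarray
    censored: np.ndarray = None

    def __post_init__(self) -> None:
        if self.depth_cm not in (30, 60, 90):
            raise ValueError("probe depths are 30, 60 or 90 cm")
        t = np.asarray(self.tension_cbar, dtype=float)
        if np.any(t < 0):
            raise ValueError("tension must be >= 0")
        self.censored = t >= TENSION_CAP_CBAR
        self.tension_cbar = np.minimum(t, TENSION_CAP_CBAR)


def irrigation_triggers(
    tension: TensionSeries,
    stage_of_date,
    thresholds: Mapping[tuple[int, str], float] = DEFAULT_THRESHOLDS,
    well_watered: bool = False,
) -> pd.DataFrame:
    """Dates on which measured tension reaches the active irrigation threshold.

    ``stage_of_date(date)`` must return "pre-Z39" or "post-Z39".  Under
    well-watered management the threshold is 80 cbar at every depth and
    stage.  Censored (>= 200 cbar) readings trigger and carry a censoring
    warning flag.
    """
    rows = []
    for date, t, cens in zip(tension.dates, tension.tension_cbar, tension.censored):
        stage = stage_of_date(date)
        if stage not in ("pre-Z39", "post-Z39"):
            raise ValueError(f"unknown growth period {stage!r} for {date}")
        key = (tension.depth_cm, stage)
        if key not in thresholds:
            raise ValueError(f"no threshold configured for depth/stage {key}")
        thr = WW_OVERRIDE_CBAR if well_watered else thresholds[key]
        if t >= thr:
            rows.append(
                {
                    "date": date,
                    "depth_cm": tension.depth_cm,
                    "tension_cbar": t,
                    "threshold_cbar": thr,
                    "water_stress": t >= WATER_STRESS_THRESHOLD_CBAR,
                    "censored": bool(cens),
                }
            )
    return pd.DataFrame(rows, columns=["date", "depth_cm", "tension_cbar", "threshold_cbar", "water_stress", "censored"])


def interception_efficiency(
    under_mm: Sequence[float], outside_mm: Sequence[float], reference: str = "max"
) -> tuple[float, np.ndarray]:
    """Rain-interception efficiency of the shelter, percent.

    100 x (1 - mean(under)/reference(outside)), with the reference the max
    (default) or mean of the outside pluviometer totals.  Also returns the
    per-position efficiency profile along the transect.
    """
    under = np.asarray(under_mm, dtype=float)
    outside = np.asarray(outside_mm, dtype=float)
    if outside.size == 0 or np.all(outside <= 0):
        raise ValueError("outside pluviometers recorded no rain")
    ref = outside.max() if reference == "max" else outside.mean()
    eff = 100.0 * (1.0 - under.mean() / ref)
    profile = 100.0 * (1.0 - under / ref)
    return float(eff), profile


def degree_day(tmax: float, tmin: float, base: float = 0.0) -> float:
    """Daily degree-days: mean of max and min temperature above the base
    (base 0 C by default)."""
    return max((tmax + tmin) / 2.0 - base, 0.0)


def shelter_side_effects(
    par_in: Sequence[float],
    par_out: Sequence[float],
    tmax_in: Sequence[float],
    tmin_in: Sequence[float],
    tmax_out: Sequence[float],
    tmin_out: Sequence[float],
) -> dict[str, float]:
    """Percent change in cumulative PAR and degree-days, inside vs outside.

    Series are aligned daily records over the protection period.  Negative
    d_cum_par_pct means the shelter reduced light; positive
    d_degree_days_pct means it warmed the crop.
    """
    arrays = [np.asarray(a, dtype=float) for a in (par_in, par_out, tmax_in, tmin_in, tmax_out, tmin_out)]
    n = {a.size for a in arrays}
    if len(n) != 1:
        raise ValueError("daily series are misaligned")
    par_i, par_o = arrays[0].sum(), arrays[1].sum()
    dd_i = sum(degree_day(a, b) for a, b in zip(arrays[2], arrays[3]))
    dd_o = sum(degree_day(a, b) for a, b in zip(arrays[4], arrays[5]))
    if par_o <= 0 or dd_o <= 0:
        raise ValueError("outside reference sums must be positive")
    return {
        "d_cum_par_pct": 100.0 * (par_i - par_o) / par_o,
        "d_degree_days_pct": 100.0 * (dd_i - dd_o) / dd_o,
    }


@dataclass
class TdrCalibration:
    """Linear map from raw TDR readings to gravimetric water content."""

    slope: float
    intercept: float
    r_squared: float

    def __call__(self, reading):
        return self.slope * np.asarray(reading, dtype=float) + self.intercept


def calibrate_tdr(tdr_readings: Sequence[float], gravimetric: Sequence[float]) -> TdrCalibration:
    """Ordinary least squares of gravimetric water content on TDR readings.

    Needs >= 3 paired samples (the platform uses five gravimetric campaigns
    per season).  Gravimetric content is (fresh - dry)/dry mass from
    oven-dried samples.
    """
    x = np.asarray(tdr_readings, dtype=float)
    y = np.asarray(gravimetric, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples required")
    if x.size < 3:
        raise ValueError(f"need >= 3 calibration pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("TDR readings have zero variance")
    res = stats.linregress(x, y)
    return TdrCalibration(float(res.slope), float(res.intercept), float(res.rvalue**2))
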