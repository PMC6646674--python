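"""Acquisition-geometry arithmetic for the gantry sensor bay.

Reproduces the printed resolution figures of the platform's standard
configuration: RGB cameras (2044 px over a 60 cm field at 1.5 m -> 0.29
mm/px), the fibre-fed spectroradiometer (NA 0.2 at 1.5 m -> 60 cm full
field), and the line-scanning LiDAR (290 Hz at 0.3 m/s -> 1 mm
longitudinal; 0.2 deg step at 1.5 m -> 5 mm transversal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SensorGeometry",
    "pixel_resolution",
    "lidar_resolutions",
    "fiber_fov",
    "PHENOFIELD_2017",
    "resolution_table",
]


@dataclass(frozen=True)
class SensorGeometry:
    """Acquisition parameters of one sensor head."""

    sensing_distance_m: float = 1.5
    detector_pixels: int | None = None
    fov_extent_m: float | None = None
    numerical_aperture: float | None = None
    scan_frequency_hz: float | None = None
    angular_step_deg: float | None = None
    travel_speed_ms: float | None = None


def pixel_resolution(fov_extent_m: float, detector_pixels: int) -> float:
    """Ground sampling distance in mm/pixel (reported to 2 decimals)."""
    if detector_pixels <= 0:
        raise ValueError("detector_pixels must be > 0")
    if fov_extent_m < 0:
        raise ValueError("fov_extent must be >= 0")
    return round(fov_extent_m * 1000.0 / detector_pixels, 2)


def lidar_resolutions(
    speed_ms: float, frequency_hz: float, distance_m: float, angular_step_deg: float
) -> dict[str, float]:
    """Longitudinal (along travel) and transversal (across scan) sampling, mm.

    longitudinal = speed / scan frequency; transversal = distance x
    tan(angular step).  Both rounded to the nearest mm for reporting.
    """
    if frequency_hz <= 0:
        raise ValueError("scan frequency must be > 0")
    if speed_ms < 0 or distance_m < 0 or angular_step_deg < 0:
        raise ValueError("inputs must be >= 0")
    longitudinal = speed_ms / frequency_hz * 1000.0
    transversal = distance_m * np.tan(np.deg2rad(angular_step_deg)) * 1000.0
    return {"longitudinal_mm": round(longitudinal), "transversal_mm": round(transversal)}


def fiber_fov(distance_m: float, numerical_aperture: float, paraxial: bool = True) -> float:
    """Full field of view (m) of a bare-fibre fore-optic at a sensing distance.

    Paraxial form 2 d NA by default; the exact-trig variant
    2 d tan(asin NA) differs by ~2% at NA 0.2.
    """
    if not 0.0 < numerical_aperture < 1.0:
        raise ValueError("numerical aperture must lie in (0, 1)")
    if distance_m < 0:
        raise ValueError("distance must be >= 0")
    if paraxial:
        return 2.0 * distance_m * numerical_aperture
    return 2.0 * distance_m * float(np.tan(np.arcsin(numerical_aperture)))


#: The platform's 2017 wheat configuration.
PHENOFIELD_2017 = {
    "rgb": SensorGeometry(1.5, detector_pixels=2044, fov_extent_m=0.60),
    "spectro": SensorGeometry(1.5, numerical_aperture=0.2),
    "lidar": SensorGeometry(
        1.5, scan_frequency_hz=290.0, angular_step_deg=0.2, travel_speed_ms=0.3
    ),
}


def resolution_table(preset: dict[str, SensorGeometry] = PHENOFIELD_2017) -> dict[str, float]:
    """Resolution figures for a sensor-bay preset (reporting precision)."""
    rgb, spec, lid = preset["rgb"], preset["spectro"], preset["lidar"]
    lr = lidar_resolutions(
        lid.travel_speed_ms, lid.scan_frequency_hz, lid.sensing_distance_m, lid.angular_step_deg
    )
    return {
        "rgb_mm_per_pixel": pixel_resolution(rgb.fov_extent_m, rgb.detector_pixels),
        "spectro_fov_m": round(fiber_fov(spec.sensing_distance_m, spec.numerical_aperture), 2),
        "lidar_longitudinal_mm": lr["longitudinal_mm"],
        "lidar_transversal_mm": lr["transversal_mm"],
    }
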