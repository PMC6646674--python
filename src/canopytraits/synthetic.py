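"""Seeded synthetic-scene generators with recorded ground truth.

Every input the trait pipeline consumes can be generated here: two-class
green/soil image mosaics with an exact green fraction, turbid-medium gap
fractions from the forward Poisson model, two-endmember reflectance scans,
ground + canopy point clouds with known height, and seasonal trait curves
with treatment-dependent stress onsets.  Each generator is a pure function
of its parameters and seed (identical calls are bit-identical), and returns
the truth alongside the artifact so recovery by the corresponding pipeline
module can be tested without any external data.

The noise models are deliberately simple: multiplicative Gaussian for gap
fractions and spectra, additive Gaussian for point-cloud elevations.  The
endmember spectra are smooth built-in curves (red absorption, red-edge,
NIR plateau for foliage; a gently sloping soil line), not measured
libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .canopy import CanopyObservation, forward_po
from .core import TraitSeries
from .lidar import PointCloud
from .rgb import AnnotatedImage
from .spectral import RawScan

__all__ = [
    "SceneTruth",
    "gen_mosaic",
    "gen_gap_fractions",
    "gen_spectrum",
    "gen_cloud",
    "gen_trait_season",
    "leaf_reflectance",
    "soil_reflectance",
    "SPECTRO_WAVELENGTHS_NM",
]

#: The spectroradiometer's sampling: 380-1100 nm over 256 detector pixels.
SPECTRO_WAVELENGTHS_NM = np.linspace(380.0, 1100.0, 256)

GREEN_RGB = (0.18, 0.46, 0.14)
SOIL_RGB = (0.47, 0.36, 0.24)


@dataclass
class SceneTruth:
    """Ground truth recorded with a generated artifact."""

    seed: int
    gcf: float | None = None
    gai: float | None = None
    ala: float | None = None
    height_m: float | None = None
    mix_fraction: float | None = None
    onset_day: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if v is not None and k != "extra"}
        d.update(self.extra)
        return d


def gen_mosaic(
    gcf_true: float, size: tuple[int, int] = (128, 128), seed: int = 0, color_sd: float = 0.04
) -> tuple[AnnotatedImage, np.ndarray, SceneTruth]:
    """Two-texture green/soil mosaic with an exact green-pixel budget.

    Exactly round(gcf_true * H * W) pixels are green (random positions);
    colours are the two class means plus seeded Gaussian texture.  Returns
    (image, boolean label map, truth); truth.gcf is the realised fraction.
    """
    if not 0.0 <= gcf_true <= 1.0:
        raise ValueError("gcf_true must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = size
    n = h * w
    n_green = int(round(gcf_true * n))
    labels = np.zeros(n, dtype=bool)
    labels[rng.permutation(n)[:n_green]] = True
    px = np.empty((n, 3))
    px[labels] = GREEN_RGB
    px[~labels] = SOIL_RGB
    px = np.clip(px + rng.normal(0.0, color_sd, size=(n, 3)), 0.0, 1.0)
    labels = labels.reshape(h, w)
    img = AnnotatedImage(px.reshape(h, w, 3), gray_panel_rgb=(0.5, 0.5, 0.5))
    truth = SceneTruth(seed=seed, gcf=n_green / n)
    return img, labels, truth


def gen_gap_fractions(
    gai: float,
    ala: float,
    angles: Sequence[float] = (0.0, 45.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CanopyObservation, SceneTruth]:
    """Gap fractions from the forward Poisson model with multiplicative noise.

    Po(theta) = forward model x (1 + eps), eps ~ N(0, noise_sd), clipped to
    (0, 1].  noise_sd = 0 reproduces the forward model exactly.
    """
    rng = np.random.default_rng(seed)
    po = {}
    for th in angles:
        val = float(forward_po(gai, ala, th)) if gai > 0 else 1.0
        if noise_sd > 0:
            val *= 1.0 + rng.normal(0.0, noise_sd)
        po[float(th)] = float(np.clip(val, 1e-9, 1.0))
    obs = CanopyObservation(po)
    return obs, SceneTruth(seed=seed, gai=gai, ala=ala)


def leaf_reflectance(wavelengths: np.ndarray = SPECTRO_WAVELENGTHS_NM) -> np.ndarray:
    """Built-in green-foliage endmember: green bump at 550 nm, strong red
    absorption near 670 nm, red-edge sigmoid, NIR plateau ~0.55."""
    wl = np.asarray(wavelengths, dtype=float)
    red_edge = 0.5 / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    green_bump = 0.09 * np.exp(-0.5 * ((wl - 550.0) / 25.0) ** 2)
    return 0.04 + red_edge + green_bump


def soil_reflectance(wavelengths: np.ndarray = SPECTRO_WAVELENGTHS_NM) -> np.ndarray:
    """Built-in bare-soil endmember: a gently rising near-flat line."""
    wl = np.asarray(wavelengths, dtype=float)
    return 0.15 + 0.18 * (wl - 380.0) / (1100.0 - 380.0)


def gen_spectrum(
    mix_fraction: float, seed: int = 0, noise_sd: float = 0.0, panel_level: float = 20000.0
) -> tuple[RawScan, RawScan, SceneTruth]:
    """Paired canopy/panel raw scans for a two-endmember canopy.

    Canopy digital numbers are panel counts x the mixed reflectance
    mix x leaf + (1 - mix) x soil, with optional multiplicative noise.
    Fully vegetated scenes (mix 1) calibrate to NDVI > 0.7, bare soil
    (mix 0) to NDVI < 0.3.
    """
    if not 0.0 <= mix_fraction <= 1.0:
        raise ValueError("mix_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    wl = SPECTRO_WAVELENGTHS_NM
    # lamp + detector envelope: broad Gaussian peaking in the visible-NIR
    envelope = np.exp(-0.5 * ((wl - 700.0) / 260.0) ** 2)
    panel_counts = panel_level * envelope
    refl = mix_fraction * leaf_reflectance(wl) + (1.0 - mix_fraction) * soil_reflectance(wl)
    canopy_counts = panel_counts * refl
    if noise_sd > 0:
        canopy_counts = canopy_counts * (1.0 + rng.normal(0.0, noise_sd, size=wl.shape))
        canopy_counts = np.clip(canopy_counts, 0.0, None)
    canopy = RawScan(wl, canopy_counts, role="canopy")
    panel = RawScan(wl, panel_counts, role="panel")
    return canopy, panel, SceneTruth(seed=seed, mix_fraction=mix_fraction)


def gen_cloud(
    height_true: float,
    gai_density: float = 2.0,
    n_points: int = 20000,
    seed: int = 0,
    ground_sd: float = 0.005,
    ground_z: float = 0.0,
) -> tuple[PointCloud, np.ndarray, SceneTruth]:
    """Ground + canopy LiDAR cloud over a 1 m x 6 m plot.

    Ground returns are N(ground_z, ground_sd); canopy elevations follow a
    top-weighted Beta(5, 1) profile scaled to ``height_true`` (its 99.5 %
    quantile sits at 0.999 x the true height).  The ground-return fraction
    is the nadir gap fraction exp(-0.5 x gai_density) of a spherical
    canopy.  Returns (cloud, boolean canopy labels, truth).
    """
    if height_true < 0:
        raise ValueError("height_true must be >= 0")
    rng = np.random.default_rng(seed)
    po_ground = np.exp(-0.5 * gai_density) if height_true > 0 else 1.0
    n_ground = int(round(n_points * po_ground))
    n_canopy = n_points - n_ground
    xy = np.column_stack([rng.uniform(0, 6.0, n_points), rng.uniform(0, 1.0, n_points)])
    z = np.empty(n_points)
    labels = np.zeros(n_points, dtype=bool)
    z[:n_ground] = ground_z + rng.normal(0.0, ground_sd, n_ground)
    if n_canopy:
        z[n_ground:] = ground_z + height_true * rng.beta(5.0, 1.0, n_canopy)
        labels[n_ground:] = True
    order = rng.permutation(n_points)
    cloud = PointCloud(np.column_stack([xy, z])[order])
    truth = SceneTruth(
        seed=seed,
        height_m=height_true,
        extra={"gai_density": gai_density, "quantile_height_m": height_true * 0.995 ** (1 / 5.0)},
    )
    return cloud, labels[order], truth


#: Treatment-dependent season shape: (plateau GF, senescence-onset day,
#: max height m).  Days count from sowing; stressed treatments senesce
#: earlier and nitrogen-deficient ones plateau lower.
SEASON_DEFAULTS = {
    "WW N+": {"plateau": 0.95, "onset_day": 230, "height_max": 0.90},
    "WW N0": {"plateau": 0.76, "onset_day": 222, "height_max": 0.83},
    "WD N+": {"plateau": 0.93, "onset_day": 200, "height_max": 0.75},
    "WD N0": {"plateau": 0.75, "onset_day": 200, "height_max": 0.73},
}


def gen_trait_season(
    treatment: str = "WW N+",
    onset_day: float | None = None,
    seed: int = 0,
    plot_id: str = "P0001",
    noise_sd: float = 0.01,
    dates: Sequence[float] | None = None,
) -> tuple[TraitSeries, SceneTruth]:
    """Seasonal green-fraction and height curves for one plot.

    Green fraction rises logistically to the treatment plateau and decays
    logistically from the senescence onset day; height is a saturating
    logistic with a treatment-scaled maximum.  ``onset_day`` overrides the
    treatment default, so a stressed series can be made to senesce an exact
    number of days earlier than its control.  Observations every 4 days
    from day 60 to day 270 after sowing, with additive Gaussian noise.
    """
    if treatment not in SEASON_DEFAULTS:
        raise ValueError(f"unknown treatment {treatment!r}; have {sorted(SEASON_DEFAULTS)}")
    params = dict(SEASON_DEFAULTS[treatment])
    if onset_day is not None:
        params["onset_day"] = float(onset_day)
    rng = np.random.default_rng(seed)
    t = np.asarray(dates if dates is not None else np.arange(60.0, 271.0, 4.0))
    rise = 1.0 / (1.0 + np.exp(-(t - 120.0) / 10.0))
    decay = 1.0 / (1.0 + np.exp((t - (params["onset_day"] + 12.0)) / 4.0))
    gf = params["plateau"] * rise * decay
    gf = np.clip(gf + rng.normal(0.0, noise_sd, t.shape), 0.0, 1.0)
    height = params["height_max"] / (1.0 + np.exp(-(t - 150.0) / 12.0))
    height = np.clip(height + rng.normal(0.0, noise_sd * params["height_max"], t.shape), 0.0, None)
    series = TraitSeries.single(plot_id, "GF", t.tolist(), gf).concat(
        TraitSeries.single(plot_id, "height", t.tolist(), height)
    )
    truth = SceneTruth(
        seed=seed,
        onset_day=params["onset_day"],
        extra={"plateau": params["plateau"], "height_max": params["height_max"], "treatment": treatment},
    )
    return series, truth
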