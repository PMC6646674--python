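"""Reflectance calibration and vegetation indices from spectroradiometer scans.

Raw scans are digital-number spectra over 380-1100 nm (256 detector pixels).
Canopy reflectance is obtained by ratioing each canopy scan against a scan of
a characterised reference panel taken in the same session:

    R(lambda) = (DN_canopy / DN_panel) * R_panel(lambda)

Only 450-820 nm is usable: outside that window the signal-to-noise ratio of
the sensing chain falls below 20.  Band reflectances are sampled with
Gaussian responses (3 nm FWHM by default) at the index band centres, and
three indices are computed:

    NDVI   = (R800 - R670) / (R800 + R670)
    MTCI   = (R754 - R709) / (R709 - R681)
    MCARI2 = 1.5 * [2.5 (R800 - R670) - 1.3 (R800 - R550)]
             / ( sqrt((2 R800 + 1)^2 - (6 R800 - 5 sqrt(R670))) - 0.5 )

NDVI and MTCI are ratio indices, invariant to a uniform scaling of the
spectrum; MCARI2 is non-normalised and intensity-sensitive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RawScan",
    "Spectrum",
    "BandSet",
    "CalibrationError",
    "BandUnusableError",
    "calibrate_reflectance",
    "average_scans",
    "sample_band",
    "ndvi",
    "mtci",
    "mcari2",
]

SNR_USABLE_RANGE_NM = (450.0, 820.0)
SNR_THRESHOLD = 20.0
DEFAULT_FWHM_NM = 3.0
INDEX_BAND_CENTERS_NM = (550.0, 670.0, 681.0, 709.0, 754.0, 800.0)


class CalibrationError(ValueError):
    pass


class BandUnusableError(ValueError):
    pass


@dataclass
class RawScan:
    """One spectroradiometer acquisition: digital numbers on a wavelength grid."""

    wavelengths: np.ndarray
    counts: np.ndarray
    role: str = "canopy"  # "canopy" | "panel"
    integration_ms: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.wavelengths.shape != self.counts.shape:
            raise ValueError("wavelengths and counts must align")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")


@dataclass
class Spectrum:
    """Calibrated reflectance with a usable-band mask."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    snr_mask: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.snr_mask = np.asarray(self.snr_mask, dtype=bool)
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance must be finite")


@dataclass(frozen=True)
class BandSet:
    """Index band centres (nm) and their common Gaussian FWHM."""

    centers: tuple[float, ...] = INDEX_BAND_CENTERS_NM
    fwhm: float = DEFAULT_FWHM_NM

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")


def _session_snr(repeat_counts: np.ndarray) -> np.ndarray:
    """Per-wavelength mean/std SNR over a session's repeat scans."""
    mean = repeat_counts.mean(axis=0)
    std = repeat_counts.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(std > 0, mean / std, np.inf)
    return snr


def average_scans(scans: Sequence[RawScan], mad_sigma: float = 3.0) -> RawScan:
    """Average repeat acquisitions after median-absolute-deviation rejection.

    A repeat is discarded at a given wavelength when it deviates from the
    per-wavelength median by more than ``mad_sigma`` scaled MADs.  The
    platform takes three acquisitions per plot pass.
    """
    if not scans:
        raise ValueError("no scans")
    wl = scans[0].wavelengths
    for s in scans[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise CalibrationError("repeat scans on different wavelength grids")
    stack = np.stack([s.counts for s in scans])
    if len(scans) < 3:
        return RawScan(wl, stack.mean(axis=0), role=scans[0].role)
    med = np.median(stack, axis=0)
    mad = np.median(np.abs(stack - med), axis=0)
    scale = 1.4826 * mad
    with np.errstate(divide="ignore", invalid="ignore"):
        # zero MAD (repeats identical up to one outlier): keep only the median
        keep = np.where(scale > 0, np.abs(stack - med) <= mad_sigma * scale, stack == med)
    counts = np.where(keep, stack, np.nan)
    return RawScan(wl, np.nanmean(counts, axis=0), role=scans[0].role)


def calibrate_reflectance(
    canopy: RawScan,
    panel: RawScan,
    panel_reflectance: float | np.ndarray = 0.99,
    canopy_repeats: np.ndarray | None = None,
) -> Spectrum:
    """Ratio a canopy scan against the session's reference-panel scan.

    ``panel_reflectance`` is the panel's characterised reflectance (scalar or
    per-wavelength).  The usable mask is true only inside 450-820 nm; when
    ``canopy_repeats`` (n_repeats x n_wavelengths DN array) is supplied the
    mean/std SNR >= 20 criterion is applied on top.
    """
    if not np.array_equal(canopy.wavelengths, panel.wavelengths):
        raise CalibrationError("canopy and panel scans on different wavelength grids")
    wl = canopy.wavelengths
    usable = (wl >= SNR_USABLE_RANGE_NM[0]) & (wl <= SNR_USABLE_RANGE_NM[1])
    if np.any(usable & (panel.counts <= 0)):
        raise CalibrationError("zero panel counts inside the usable range")
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.where(panel.counts > 0, canopy.counts / panel.counts, 0.0)
    refl = refl * np.asarray(panel_reflectance, dtype=float)
    mask = usable.copy()
    if canopy_repeats is not None:
        snr = _session_snr(np.asarray(canopy_repeats, dtype=float))
        mask &= snr >= SNR_THRESHOLD
    return Spectrum(wl, refl, mask)


def sample_band(spec: Spectrum, center: float, fwhm: float = DEFAULT_FWHM_NM) -> float:
    """Gaussian-weighted band reflectance, sigma = fwhm / (2 sqrt(2 ln 2)).

    Weights are renormalised over the samples available inside the +-2 sigma
    support; the band is unusable if any of that support is masked out or
    falls outside the wavelength grid.
    """
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    lo, hi = center - 2 * sigma, center + 2 * sigma
    wl = spec.wavelengths
    if lo < wl[0] or hi > wl[-1]:
        raise BandUnusableError(f"band {center} nm outside wavelength support")
    in_support = (wl >= lo) & (wl <= hi)
    if not np.any(in_support):
        # grid coarser than the band: use the bracketing samples
        in_support = np.zeros_like(wl, dtype=bool)
        in_support[np.searchsorted(wl, center) - 1 : np.searchsorted(wl, center) + 1] = True
    if not np.all(spec.snr_mask[in_support]):
        raise BandUnusableError(f"band {center} nm falls on masked wavelengths")
    w = np.exp(-0.5 * ((wl[in_support] - center) / sigma) ** 2)
    return float(np.sum(w * spec.reflectance[in_support]) / np.sum(w))


def _bands(spec: Spectrum, centers: Sequence[float], fwhm: float) -> dict[float, float]:
    return {c: sample_band(spec, c, fwhm) for c in centers}


def ndvi(spec: Spectrum, fwhm: float = DEFAULT_FWHM_NM) -> float:
    """Normalised Difference Vegetation Index, (R800 - R670)/(R800 + R670)."""
    b = _bands(spec, (670.0, 800.0), fwhm)
    denom = b[800.0] + b[670.0]
    if denom == 0:
        raise BandUnusableError("NDVI undefined: R800 + R670 = 0")
    return (b[800.0] - b[670.0]) / denom


def mtci(spec: Spectrum, fwhm: float = DEFAULT_FWHM_NM) -> float:
    """MERIS Terrestrial Chlorophyll Index, (R754 - R709)/(R709 - R681)."""
    b = _bands(spec, (681.0, 709.0, 754.0), fwhm)
    denom = b[709.0] - b[681.0]
    if denom == 0:
        raise BandUnusableError("MTCI undefined: R709 = R681")
    return (b[754.0] - b[709.0]) / denom


def mcari2(spec: Spectrum, fwhm: float = DEFAULT_FWHM_NM, literal_denominator: bool = False) -> float:
    """Modified Chlorophyll Absorption Ratio Index 2 (green-LAI index).

    The default uses the original published closed form with the square root
    in the denominator.  ``literal_denominator=True`` drops the square root,
    for comparison with transcriptions that omit it.
    """
    b = _bands(spec, (550.0, 670.0, 800.0), fwhm)
    r800, r670, r550 = b[800.0], b[670.0], b[550.0]
    num = 1.5 * (2.5 * (r800 - r670) - 1.3 * (r800 - r550))
    inner = (2 * r800 + 1) ** 2 - (6 * r800 - 5 * np.sqrt(r670))
    if literal_denominator:
        denom = inner - 0.5
    else:
        if inner < 0:
            raise BandUnusableError("MCARI2 undefined: negative discriminant")
        denom = np.sqrt(inner) - 0.5
    if denom == 0:
        raise BandUnusableError("MCARI2 undefined: zero denominator")
    return float(num / denom)


def plot_index(
    spectra: Sequence[Spectrum],
    index: str = "ndvi",
    fwhm: float = DEFAULT_FWHM_NM,
    average_first: bool = True,
) -> float:
    """Plot-level vegetation index from several calibrated scans.

    Default computes the index on the average of the normalised reflectances
    (the platform convention); ``average_first=False`` averages per-scan
    indices instead.
    """
    fn = {"ndvi": ndvi, "mtci": mtci, "mcari2": mcari2}[index]
    if not spectra:
        raise ValueError("no spectra")
    if average_first:
        wl = spectra[0].wavelengths
        for s in spectra[1:]:
            if not np.array_equal(s.wavelengths, wl):
                raise CalibrationError("spectra on different wavelength grids")
        refl = np.mean([s.reflectance for s in spectra], axis=0)
        mask = np.logical_and.reduce([s.snr_mask for s in spectra])
        return fn(Spectrum(wl, refl, mask), fwhm)
    return float(np.mean([fn(s, fwhm) for s in spectra]))
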