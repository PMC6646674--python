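"""Green area index and leaf angle from multi-angle gap fractions.

The canopy is treated as a turbid medium: a ray at view zenith angle
``theta_p`` misses all foliage with probability

    Po(theta_p) = exp(-G(theta_p, theta_l) * GAI / cos(theta_p))

where GAI is the green area index (m2 green area per m2 ground) and
G the projection function of an ellipsoidal leaf angle distribution with
shape parameter chi (chi = 1 is the spherical canopy).  Writing
G = K(theta_p, chi) * cos(theta_p) with Campbell's extinction coefficient

    K = sqrt(chi^2 + tan^2 theta_p) / (chi + 1.774 * (chi + 1.182)^-0.733)

gives Po = exp(-K * GAI).  The average leaf angle (ALA, degrees from
horizontal) relates to chi through ALA[rad] = 9.65 * (3 + chi)^-1.65, a
monotone decreasing map: planophile canopies (large chi) have small ALA.

Inversion is a look-up-table search: gap fractions observed at the
platform's view angles (0 deg nadir and 45 deg) are compared with
precomputed Po over a dense (GAI, ALA) grid and the root-mean-square-error
minimiser is returned, ties broken toward smaller GAI then smaller ALA.
When the inverted quantity is fed green-only gap fractions (1 - green cover
fraction) it is conventionally labelled GPAI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "g_function",
    "extinction_k",
    "ala_from_chi",
    "chi_from_ala",
    "forward_po",
    "build_lut",
    "invert_gai_ala",
    "CanopyObservation",
    "CanopyEstimate",
    "LookupTable",
]

_CAMPBELL_A = 1.774
_CAMPBELL_B = 1.182
_CAMPBELL_C = -0.733
_ALA_COEF = 9.65
_ALA_EXP = -1.65


def extinction_k(theta_p: float, chi: float) -> float:
    """Campbell extinction coefficient K(theta_p, chi) for an ellipsoidal LAD.

    Parameters
    ----------
    theta_p : view zenith angle, degrees, 0 <= theta_p < 90.
    chi : ellipsoidal shape parameter, > 0.
    """
    if np.any(np.asarray(chi) <= 0):
        raise ValueError(f"chi must be > 0, got {chi}")
    th = np.asarray(theta_p, dtype=float)
    if np.any(th < 0) or np.any(th >= 90):
        raise ValueError(f"theta_p must lie in [0, 90), got {theta_p}")
    t = np.tan(np.deg2rad(th))
    num = np.sqrt(chi**2 + t**2)
    den = chi + _CAMPBELL_A * (chi + _CAMPBELL_B) ** _CAMPBELL_C
    return num / den


def g_function(theta_p: float, chi: float):
    """Projection function G(theta_p, chi) = K * cos(theta_p).

    The mean projected area of unit foliage area onto the plane normal to
    the view direction.  Near theta_p = 57.5 deg G is close to 0.5 for any
    leaf inclination, which is why that angle is inclination-insensitive.
    """
    k = extinction_k(theta_p, chi)
    return k * np.cos(np.deg2rad(np.asarray(theta_p, dtype=float)))


def ala_from_chi(chi: float) -> float:
    """Average leaf angle (degrees from horizontal) of the ellipsoidal LAD."""
    if np.any(np.asarray(chi) <= 0):
        raise ValueError(f"chi must be > 0, got {chi}")
    return np.rad2deg(_ALA_COEF * (3.0 + np.asarray(chi, dtype=float)) ** _ALA_EXP)


def chi_from_ala(ala: float) -> float:
    """Numerical inverse of :func:`ala_from_chi` (0 < ala < 90 degrees)."""
    ala = float(ala)
    if not 0.0 < ala < 90.0:
        raise ValueError(f"ala must lie in (0, 90) degrees, got {ala}")
    lo, hi = 1e-6, 1e6
    if ala >= ala_from_chi(lo) or ala <= ala_from_chi(hi):
        raise ValueError(f"ala {ala} outside representable range")
    return brentq(lambda c: ala_from_chi(c) - ala, lo, hi, xtol=1e-12)


def forward_po(gai: float, ala: float, theta_p: float):
    """Gap fraction of a turbid-medium canopy seen at zenith angle theta_p.

    Po = exp(-G * GAI / cos theta_p) = exp(-K * GAI), in (0, 1].
    """
    if np.any(np.asarray(gai) < 0):
        raise ValueError(f"gai must be >= 0, got {gai}")
    chi = chi_from_ala(ala)
    k = extinction_k(theta_p, chi)
    return np.exp(-k * np.asarray(gai, dtype=float))


@dataclass
class CanopyObservation:
    """Gap fractions by view zenith angle for one plot and date.

    Po = 1 - GCF (green cover fraction) at each angle; all Po in [0, 1],
    angles within [0, 75] degrees.
    """

    po_by_angle: Mapping[float, float]
    plot_id: str | None = None
    date: object | None = None

    def __post_init__(self) -> None:
        if not self.po_by_angle:
            raise ValueError("at least one view angle required")
        for ang, po in self.po_by_angle.items():
            if not 0.0 <= ang <= 75.0:
                raise ValueError(f"view angle {ang} outside [0, 75] degrees")
            if not 0.0 <= po <= 1.0:
                raise ValueError(f"gap fraction {po} at {ang} deg outside [0, 1]")


@dataclass
class CanopyEstimate:
    """Inversion result: (gai, ala) grid minimiser with fit residual."""

    gai: float
    ala: float
    chi: float
    cost: float
    ala_identifiable: bool = True


@dataclass
class LookupTable:
    """Forward-model Po precomputed on a dense (GAI, ALA) grid.

    ``po`` has shape (n_gai, n_ala, n_angles); every value lies in (0, 1].
    """

    angles: tuple[float, ...]
    gai_grid: np.ndarray
    ala_grid: np.ndarray
    po: np.ndarray
    ala_identifiable: bool = True

    def angle_index(self, angles: Sequence[float]) -> np.ndarray:
        idx = []
        for a in angles:
            matches = [i for i, la in enumerate(self.angles) if abs(la - a) < 1e-9]
            if not matches:
                raise ValueError(f"angle {a} not tabulated (have {self.angles})")
            idx.append(matches[0])
        return np.asarray(idx)


def build_lut(
    angles: Sequence[float] = (0.0, 45.0),
    gai_range: tuple[float, float] = (0.0, 8.0),
    ala_range: tuple[float, float] = (10.0, 80.0),
    gai_step: float = 0.05,
    ala_step: float = 1.0,
) -> LookupTable:
    """Tabulate forward-model gap fractions over a (GAI, ALA) grid.

    Defaults: GAI 0-8 step 0.05, ALA 10-80 deg step 1 deg, view angles
    {0, 45} deg — the platform's standard camera configuration.  A LUT with a
    single view angle is valid but ALA is then weakly identifiable and the
    table is flagged accordingly.
    """
    angles = tuple(float(a) for a in angles)
    if not angles:
        raise ValueError("empty angle set")
    if gai_range[1] < gai_range[0] or ala_range[1] < ala_range[0]:
        raise ValueError("empty grid range")
    n_gai = int(round((gai_range[1] - gai_range[0]) / gai_step)) + 1
    n_ala = int(round((ala_range[1] - ala_range[0]) / ala_step)) + 1
    gai_grid = gai_range[0] + gai_step * np.arange(n_gai)
    ala_grid = ala_range[0] + ala_step * np.arange(n_ala)
    chis = np.array([chi_from_ala(a) for a in ala_grid])
    ks = np.stack([extinction_k(th, chis) for th in angles], axis=-1)  # (n_ala, n_angles)
    po = np.exp(-gai_grid[:, None, None] * ks[None, :, :])
    identifiable = len(angles) >= 2
    if not identifiable:
        warnings.warn("single-angle LUT: ALA weakly identifiable", stacklevel=2)
    return LookupTable(angles, gai_grid, ala_grid, po, ala_identifiable=identifiable)


def invert_gai_ala(obs: CanopyObservation, lut: LookupTable) -> CanopyEstimate:
    """Retrieve the (GAI, ALA) grid point whose forward gap fractions best
    match the observation (unweighted RMSE over the available view angles).

    Ties are broken toward smaller GAI, then smaller ALA (parsimony).  A
    fully open canopy (Po = 1 everywhere) returns GAI 0 with ALA pinned at
    the grid minimum and flagged non-identifiable.
    """
    angles = sorted(obs.po_by_angle)
    idx = lut.angle_index(angles)
    target = np.array([obs.po_by_angle[a] for a in angles])
    resid = lut.po[:, :, idx] - target[None, None, :]
    cost = np.sqrt(np.mean(resid**2, axis=-1))
    # argmin on C-ordered flat index implements the (smaller GAI, smaller ALA)
    # tie-break because gai varies slowest and both grids ascend
    flat = int(np.argmin(cost))
    i, j = np.unravel_index(flat, cost.shape)
    gai = float(lut.gai_grid[i])
    ala = float(lut.ala_grid[j])
    identifiable = lut.ala_identifiable and gai > 0
    return CanopyEstimate(
        gai=gai,
        ala=ala,
        chi=chi_from_ala(ala),
        cost=float(cost[i, j]),
        ala_identifiable=identifiable,
    )
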