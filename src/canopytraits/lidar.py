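"""Canopy height from LiDAR point clouds.

The per-plot pipeline: (1) split the cloud into ground and vegetation by an
Otsu threshold on the elevation histogram, (2) take the ground level as the
mode of the non-vegetation cluster's z histogram (1 cm bins, lowest-bin
tie-break), (3) subtract it from the vegetation points and report the
99.5 % linear-interpolation quantile of the resulting height distribution,
in centimetres.  Sensor range measurements (distance below the scanner,
valid 70-300 cm) are converted to upward elevation on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = [
    "PointCloud",
    "HeightEstimate",
    "split_ground_vegetation",
    "ground_level",
    "plot_height",
    "read_cloud",
]

MIN_CLOUD_POINTS = 50
DEFAULT_QUANTILE = 0.995
GROUND_BIN_M = 0.01
SENSOR_RANGE_M = (0.70, 3.00)


@dataclass
class PointCloud:
    """Per-plot LiDAR returns: x along travel, y transverse, z elevation (m)."""

    points: np.ndarray  # N x 3
    reflectance: np.ndarray | None = None
    plot_id: str | None = None
    date: object | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be N x 3")
        if len(self.points) < 1:
            raise ValueError("empty cloud")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates")

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class HeightEstimate:
    height_cm: float
    ground_z: float
    n_vegetation_points: int
    quantile: float = DEFAULT_QUANTILE
    empty_vegetation: bool = False


def read_cloud(
    path: str | Path,
    plot_id: str | None = None,
    sensor_height_m: float | None = None,
) -> PointCloud:
    """Read a PLY or CSV (x,y,z[,intensity]) point cloud.

    When ``sensor_height_m`` is given, the file's z column is interpreted as
    range below the scanner: returns outside the 70-300 cm valid window are
    dropped and z is converted to elevation ``sensor_height - range``.
    """
    path = Path(path)
    refl = None
    if path.suffix.lower() == ".ply":
        import trimesh

        mesh = trimesh.load(str(path), process=False)
        pts = np.asarray(mesh.vertices, dtype=float)
    else:
        df = pd.read_csv(path)
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        if not {"x", "y", "z"} <= set(cols):
            raise ValueError(f"cloud CSV needs x,y,z columns, got {cols}")
        pts = df[["x", "y", "z"]].to_numpy(dtype=float)
        if "intensity" in cols:
            refl = df["intensity"].to_numpy(dtype=float)
    if sensor_height_m is not None:
        rng = pts[:, 2]
        keep = (rng >= SENSOR_RANGE_M[0]) & (rng <= SENSOR_RANGE_M[1])
        pts = pts[keep].copy()
        if refl is not None:
            refl = refl[keep]
        pts[:, 2] = sensor_height_m - pts[:, 2]
    return PointCloud(pts, reflectance=refl, plot_id=plot_id)


def split_ground_vegetation(cloud: PointCloud) -> tuple[np.ndarray, np.ndarray]:
    """Two-cluster split of the z distribution (ground below, vegetation above).

    Otsu's threshold on the z histogram: robust and parameter-free for the
    bimodal soil/canopy distributions a cereal plot produces.  A unimodal
    (bare-soil) cloud yields an empty vegetation cluster.
    """
    if len(cloud) < MIN_CLOUD_POINTS:
        raise ValueError(f"need >= {MIN_CLOUD_POINTS} points, got {len(cloud)}")
    z = cloud.z
    if np.ptp(z) == 0:
        return cloud.points, cloud.points[:0]
    thresh = threshold_otsu(z, nbins=256)
    below, above = cloud.points[z <= thresh], cloud.points[z > thresh]
    # Otsu on a unimodal pile splits it in half; treat clusters whose means
    # are closer than 3x the ground roughness as a single ground cluster
    if len(above) and len(below):
        spread = max(z[z <= thresh].std(), 1e-6)
        if above[:, 2].mean() - below[:, 2].mean() < 3 * spread:
            return cloud.points, cloud.points[:0]
    return below, above


def ground_level(ground_points: np.ndarray, bin_m: float = GROUND_BIN_M) -> float:
    """Mode of the ground cluster's z histogram, returned as the bin centre.

    Bin width defaults to 1 cm; ties break toward the lowest bin.
    """
    pts = np.asarray(ground_points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty ground cluster")
    z = pts[:, 2] if pts.ndim == 2 else pts
    lo, hi = z.min(), z.max()
    if hi - lo < bin_m:
        return float(z.mean())
    edges = np.arange(lo, hi + bin_m, bin_m)
    counts, edges = np.histogram(z, bins=edges)
    i = int(np.argmax(counts))  # argmax takes the first = lowest bin on ties
    return float(0.5 * (edges[i] + edges[i + 1]))


def plot_height(
    cloud: PointCloud, quantile: float = DEFAULT_QUANTILE, bin_m: float = GROUND_BIN_M
) -> HeightEstimate:
    """Per-plot canopy height: vegetation heights above ground level, summarised
    by the ``quantile`` (default 99.5 %) of their cumulated distribution, in cm.

    Negative heights are clamped to zero.  A cloud with no vegetation cluster
    returns height 0 with ``empty_vegetation`` set.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must lie in (0, 1]")
    ground, veg = split_ground_vegetation(cloud)
    gz = ground_level(ground if len(ground) else cloud.points, bin_m=bin_m)
    if len(veg) == 0:
        return HeightEstimate(0.0, gz, 0, quantile, empty_vegetation=True)
    heights = np.clip(veg[:, 2] - gz, 0.0, None)
    h = float(np.quantile(heights, quantile, method="linear"))
    return HeightEstimate(h * 100.0, gz, len(veg), quantile)
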