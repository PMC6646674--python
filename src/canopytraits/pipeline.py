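"""Run configuration and the end-to-end per-plot trait pipeline.

One acquisition pass over a plot directory tree produces, per plot: green
cover fraction at each view angle, GAI/ALA (labelled GPAI when computed
from green-only gap fractions), vegetation indices, and LiDAR height —
written as a tidy trait table plus a JSON run manifest (seeds, parameters,
per-plot errors).  A failing plot is recorded and skipped; the run
continues (a corrupt file must not kill a 768-plot campaign).

Expected per-plot layout (as written by :func:`simulate_trial`)::

    <inputs>/<plot_id>/image_00.png      nadir RGB
                       image_45.png      45-degree RGB
                       canopy.csv        canopy scan (wavelength_nm,value)
                       panel.csv         panel scan
                       cloud.csv         x,y,z point cloud
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import canopy, lidar, rgb, spectral, synthetic
from .core import TraitSeries

__all__ = ["RunConfig", "run_pipeline", "simulate_trial"]


@dataclass
class RunConfig:
    """All pipeline parameters with their documented defaults.

    Unknown keys in a YAML config are rejected so typos fail loudly.
    """

    inputs: str = "inputs"
    output_dir: str = "outputs"
    seed: int = 0
    view_angles: tuple[float, ...] = (0.0, 45.0)
    lut_gai_range: tuple[float, float] = (0.0, 8.0)
    lut_ala_range: tuple[float, float] = (10.0, 80.0)
    lut_gai_step: float = 0.05
    lut_ala_step: float = 1.0
    height_quantile: float = 0.995
    band_fwhm_nm: float = 3.0
    panel_reflectance: float = 0.99
    border_margin_px: int = 0
    exg_threshold: float | None = None  # None -> train the SVM on a seeded mosaic
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("view_angles", "lut_gai_range", "lut_ala_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def parameter_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _default_classifier(config: RunConfig) -> rgb.PixelClassifier:
    """Either the excess-green baseline or an SVM trained on a seeded mosaic."""
    if config.exg_threshold is not None:
        return rgb.PixelClassifier.exg_baseline(config.exg_threshold)
    img, labels, _ = synthetic.gen_mosaic(0.5, size=(64, 64), seed=config.seed)
    return rgb.train_pixel_classifier(img.pixels.reshape(-1, 3), labels.ravel(), seed=config.seed)


def _read_scan_csv(path: Path, role: str) -> spectral.RawScan:
    df = pd.read_csv(path, comment="#")
    return spectral.RawScan(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), role=role)


def _process_plot(
    plot_dir: Path,
    config: RunConfig,
    classifier: rgb.PixelClassifier,
    lut: canopy.LookupTable,
) -> list[dict]:
    pid = plot_dir.name
    rows = []

    def add(trait, value):
        rows.append({"plot_id": pid, "trait": trait, "date": 0, "value": value})

    po = {}
    for angle in config.view_angles:
        img = rgb.read_image(plot_dir / f"image_{int(angle):02d}.png", view_angle=angle)
        img.gray_panel_rgb = (0.5, 0.5, 0.5)
        mask = rgb.classify_green(rgb.white_balance(img), classifier, config.border_margin_px)
        add(f"GCF_{int(angle):02d}", mask.gcf)
        po[angle] = 1.0 - mask.gcf
    est = canopy.invert_gai_ala(canopy.CanopyObservation(po), lut)
    add("GPAI", est.gai)
    add("ALA", est.ala)

    canopy_scan = _read_scan_csv(plot_dir / "canopy.csv", "canopy")
    panel_scan = _read_scan_csv(plot_dir / "panel.csv", "panel")
    spec = spectral.calibrate_reflectance(canopy_scan, panel_scan, config.panel_reflectance)
    add("NDVI", spectral.ndvi(spec, config.band_fwhm_nm))
    add("MTCI", spectral.mtci(spec, config.band_fwhm_nm))
    add("MCARI2", spectral.mcari2(spec, config.band_fwhm_nm))

    cloud = lidar.read_cloud(plot_dir / "cloud.csv", plot_id=pid)
    est_h = lidar.plot_height(cloud, quantile=config.height_quantile)
    add("height_cm", est_h.height_cm)
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Execute segment -> invert -> indices -> height over every plot directory.

    Returns the manifest dict; writes ``traits.csv`` and ``manifest.json``
    into the output directory.  Per-plot failures are recorded in the
    manifest and reflected in its ``n_failed`` count.
    """
    inputs = Path(config.inputs)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plot_dirs = sorted(p for p in inputs.iterdir() if p.is_dir()) if inputs.exists() else []
    manifest = {
        "config": config.to_dict(),
        "parameter_hash": config.parameter_hash(),
        "seed": config.seed,
        "n_plots": len(plot_dirs),
        "errors": {},
    }
    if not plot_dirs:
        manifest["status"] = "nothing to do"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        manifest["n_failed"] = 0
        return manifest

    classifier = _default_classifier(config)
    lut = canopy.build_lut(
        config.view_angles,
        config.lut_gai_range,
        config.lut_ala_range,
        config.lut_gai_step,
        config.lut_ala_step,
    )
    all_rows = []
    for plot_dir in plot_dirs:
        try:
            all_rows.extend(_process_plot(plot_dir, config, classifier, lut))
        except Exception as exc:  # noqa: BLE001 - per-plot isolation contract
            manifest["errors"][plot_dir.name] = f"{type(exc).__name__}: {exc}"
    if all_rows:
        TraitSeries(pd.DataFrame(all_rows)).to_csv(out_dir / "traits.csv")
    manifest["n_failed"] = len(manifest["errors"])
    manifest["status"] = "ok" if not manifest["errors"] else "completed with errors"
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def simulate_trial(
    out_dir: str | Path,
    n_plots: int = 4,
    seed: int = 0,
    image_size: tuple[int, int] = (96, 96),
    cloud_points: int = 8000,
) -> dict:
    """Write a synthetic multi-plot input tree with a truth sidecar.

    Each plot draws its own (GAI, ALA, height, canopy mix) from a seeded
    stream; mosaic green fractions at the two view angles come from the
    forward gap-fraction model so the whole chain is self-consistent.
    Truths are written to ``<out_dir>/truths.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truths = {}
    for i in range(n_plots):
        pid = f"P{i + 1:04d}"
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        gai = float(rng.uniform(0.5, 6.0))
        ala = float(rng.uniform(30.0, 70.0))
        height = float(rng.uniform(0.4, 1.0))
        mix = float(rng.uniform(0.2, 1.0))
        sub = int(rng.integers(0, 2**31 - 1))
        for angle in (0.0, 45.0):
            gcf = 1.0 - float(canopy.forward_po(gai, ala, angle))
            img, _, _ = synthetic.gen_mosaic(gcf, size=image_size, seed=sub + int(angle))
            arr = (img.pixels * 255).round().astype("uint8")
            Image.fromarray(arr).save(pdir / f"image_{int(angle):02d}.png")
        canopy_scan, panel_scan, _ = synthetic.gen_spectrum(mix, seed=sub)
        for scan, name in ((canopy_scan, "canopy"), (panel_scan, "panel")):
            pd.DataFrame({"wavelength_nm": scan.wavelengths, "value": scan.counts}).to_csv(
                pdir / f"{name}.csv", index=False
            )
        cloud, _, _ = synthetic.gen_cloud(height, gai_density=gai, n_points=cloud_points, seed=sub)
        pd.DataFrame(cloud.points, columns=["x", "y", "z"]).to_csv(pdir / "cloud.csv", index=False)
        truths[pid] = {"gai": gai, "ala": ala, "height_m": height, "mix_fraction": mix, "seed": sub}
    (out_dir / "truths.yaml").write_text(yaml.safe_dump(truths))
    return truths
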