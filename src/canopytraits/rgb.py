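"""Green cover fraction from calibrated RGB microplot images.

Images are white-balanced against a reference grey panel, each pixel is
classified green vs non-green, and the green cover fraction (GCF) at the
image's view angle is the exact green-pixel count over the total count.
GCF feeds the gap-fraction inversion as Po = 1 - GCF.

The classifier is a maximum-margin (linear SVM) model over a per-pixel
colour feature vector (R, G, B, excess-green 2G - R - B, hue).  A plain
excess-green threshold is available as a parameter-free fallback.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from skimage.color import rgb2hsv

__all__ = [
    "AnnotatedImage",
    "GreenMask",
    "PixelClassifier",
    "white_balance",
    "train_pixel_classifier",
    "classify_green",
    "pixel_features",
    "excess_green",
    "read_image",
]

STANDARD_VIEW_ANGLES = (0.0, 45.0)


class CalibrationError(ValueError):
    pass


@dataclass
class AnnotatedImage:
    """RGB microplot image in linear [0, 1] floats plus acquisition metadata."""

    pixels: np.ndarray  # H x W x 3
    view_angle: float = 0.0
    plot_id: str | None = None
    date: object | None = None
    gray_panel_rgb: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")


@dataclass
class GreenMask:
    """Boolean green/non-green labels and the exact green cover fraction."""

    labels: np.ndarray
    gcf: float


def read_image(path: str | Path, view_angle: float = 0.0, **meta) -> AnnotatedImage:
    """Read a PNG/TIFF image, rescaling 8/16-bit integers to [0, 1] floats."""
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        arr = arr / 255.0
    elif arr.dtype == np.uint16:
        arr = arr / 65535.0
    else:
        arr = arr.astype(float)
    return AnnotatedImage(arr, view_angle=view_angle, **meta)


def white_balance(img: AnnotatedImage) -> AnnotatedImage:
    """Equalise channel intensities on the reference grey panel.

    Per-channel gain g_c = mean(panel) / panel_c; the panel becomes
    achromatic and the output is clipped to [0, 1].
    """
    if img.gray_panel_rgb is None:
        raise CalibrationError("no grey-panel reference on image")
    panel = np.asarray(img.gray_panel_rgb, dtype=float)
    if np.any(panel <= 0):
        raise CalibrationError(f"grey panel has a non-positive channel: {panel}")
    gains = panel.mean() / panel
    balanced = np.clip(img.pixels * gains[None, None, :], 0.0, 1.0)
    return AnnotatedImage(
        balanced,
        view_angle=img.view_angle,
        plot_id=img.plot_id,
        date=img.date,
        gray_panel_rgb=tuple(panel * gains),
    )


def excess_green(pixels: np.ndarray) -> np.ndarray:
    """Excess-green index 2G - R - B per pixel, in [-2, 2]."""
    return 2.0 * pixels[..., 1] - pixels[..., 0] - pixels[..., 2]


def pixel_features(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel colour features (R, G, B, ExG, hue), flattened to N x 5."""
    flat = pixels.reshape(-1, 3)
    exg = excess_green(flat)
    hue = rgb2hsv(flat[None, :, :])[0, :, 0]
    return np.column_stack([flat, exg, hue])


@dataclass
class PixelClassifier:
    """Trained green/non-green pixel classifier (linear maximum-margin model
    over colour features, or the excess-green threshold fallback)."""

    model: object | None = None
    exg_threshold: float | None = None
    version: str = "1"

    @property
    def trained(self) -> bool:
        return self.model is not None or self.exg_threshold is not None

    def predict(self, pixels: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("classifier not trained")
        if self.model is not None:
            feats = pixel_features(pixels)
            return self.model.predict(feats).astype(bool).reshape(pixels.shape[:-1])
        return excess_green(pixels) > self.exg_threshold

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"version": self.version, "model": self.model, "exg_threshold": self.exg_threshold}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifier":
        with open(path, "rb") as fh:
            d = pickle.load(fh)
        return cls(model=d["model"], exg_threshold=d["exg_threshold"], version=d["version"])

    @classmethod
    def exg_baseline(cls, threshold: float = 0.2) -> "PixelClassifier":
        return cls(exg_threshold=threshold)


def train_pixel_classifier(
    pixels: np.ndarray, labels: np.ndarray, seed: int = 0
) -> PixelClassifier:
    """Fit the maximum-margin pixel classifier on labelled RGB samples.

    ``pixels`` is N x 3 in [0, 1]; ``labels`` boolean (True = green).  Both
    classes must be present.  Deterministic for a fixed seed.
    """
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 3)
    labels = np.asarray(labels, dtype=bool).ravel()
    if pixels.shape[0] != labels.shape[0]:
        raise ValueError("pixels and labels must align")
    if pixels.shape[0] == 0:
        raise ValueError("empty training sample")
    if labels.all() or not labels.any():
        raise ValueError("training sample must contain both classes")
    feats = pixel_features(pixels)
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", LinearSVC(C=1.0, random_state=seed, max_iter=20000)),
        ]
    )
    model.fit(feats, labels)
    return PixelClassifier(model=model)


def classify_green(
    img: AnnotatedImage, classifier: PixelClassifier, border_margin_px: int = 0
) -> GreenMask:
    """Label each pixel green/non-green and return the exact GCF.

    ``border_margin_px`` crops that many pixels off every image edge before
    counting (intra-plot border removal); default 0.
    """
    if not classifier.trained:
        raise RuntimeError("classifier not trained")
    px = img.pixels
    if border_margin_px:
        m = border_margin_px
        if 2 * m >= min(px.shape[:2]):
            raise ValueError("border margin consumes the whole image")
        px = px[m:-m, m:-m]
    labels = classifier.predict(px)
    return GreenMask(labels=labels, gcf=float(labels.sum()) / labels.size)
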