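"""Frame loading, HSV conversion and field-of-view masking.

Capsule endoscopy frames carry a circular optical field of view inside a
black square; the corners hold no tissue information, so every pixel
statistic downstream is restricted to an FOV mask built here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color, measure

logger = logging.getLogger(__name__)

VALID_LABELS = ("normal", "abnormal")


@dataclass
class RawFrame:
    """An integer RGB frame plus its source identifier."""

    pixels: np.ndarray  # H x W x 3, integers in [0, 255]
    path: str = "<memory>"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixels, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"frame too small: {px.shape[:2]} (need at least 8x8)")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class HSVFrame:
    """Three HSV planes in [0, 1] and the boolean FOV mask.

    ``channels[0]`` is hue, ``channels[1]`` saturation, ``channels[2]``
    value.  Hue is treated as a plain scalar in [0, 1] downstream; the
    hue of achromatic pixels is 0.
    """

    channels: np.ndarray  # 3 x H x W floats in [0, 1]
    mask: np.ndarray  # H x W booleans

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if ch.ndim != 3 or ch.shape[0] != 3:
            raise ValueError(f"expected 3xHxW channels, got shape {ch.shape}")
        if m.shape != ch.shape[1:]:
            raise ValueError(f"mask shape {m.shape} != channel shape {ch.shape[1:]}")
        if ch.min() < -1e-9 or ch.max() > 1 + 1e-9:
            raise ValueError("HSV channels must lie in [0, 1]")
        self.channels = np.clip(ch, 0.0, 1.0)
        self.mask = m

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def load_frame(path: str | Path) -> RawFrame:
    """Read a PNG/JPEG/BMP image as an integer RGB frame.

    Grayscale images are replicated to three channels (with a warning);
    an alpha channel, if present, is dropped.
    """
    import imageio.v3 as iio

    path = Path(path)
    try:
        px = iio.imread(path)
    except Exception as exc:  # imageio raises various concrete types
        raise IOError(f"cannot read image {path}: {exc}") from exc
    px = np.asarray(px)
    if px.ndim == 2:
        logger.warning("grayscale input %s replicated to 3 channels", path)
        px = np.stack([px] * 3, axis=-1)
    elif px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    elif px.ndim != 3 or px.shape[2] != 3:
        raise IOError(f"cannot interpret {path} as an RGB image (shape {px.shape})")
    if px.dtype != np.uint8:
        px = np.clip(px, 0, 255).astype(np.uint8)
    return RawFrame(pixels=px, path=str(path))


def rgb_to_hsv(frame: RawFrame, mask: np.ndarray | None = None) -> HSVFrame:
    """Convert a frame to HSV planes in [0, 1] (standard hexcone model).

    If no mask is supplied the inscribed-disc FOV mask is used.
    """
    hsv = color.rgb2hsv(frame.pixels.astype(np.float64) / 255.0)
    if mask is None:
        mask = make_fov_mask(frame, mode="disc")
    return HSVFrame(channels=np.moveaxis(hsv, -1, 0), mask=mask)


def hsv_to_rgb(hsv: HSVFrame) -> np.ndarray:
    """Inverse conversion; returns an integer H x W x 3 array in [0, 255]."""
    rgb = color.hsv2rgb(np.moveaxis(hsv.channels, 0, -1))
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def make_fov_mask(
    frame: RawFrame,
    mode: str = "disc",
    radius_fraction: float = 0.5,
    dark_threshold: float = 0.06,
) -> np.ndarray:
    """Build the boolean field-of-view mask of a frame.

    ``disc`` draws a centred disc of radius ``radius_fraction`` times the
    smaller image dimension (the default 0.5 is the inscribed circle).
    ``threshold`` keeps pixels whose brightness V exceeds
    ``dark_threshold``, retains the largest connected component and
    fills its holes — useful for real frames whose optics are not
    perfectly centred.
    """
    h, w = frame.shape
    if mode == "disc":
        r = radius_fraction * min(h, w)
        yy, xx = np.ogrid[:h, :w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    elif mode == "threshold":
        v = frame.pixels.max(axis=2) / 255.0
        bright = v > dark_threshold
        if not bright.any():
            raise ValueError("empty FOV mask: no pixel above the dark threshold")
        labels = measure.label(bright, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = ndimage.binary_fill_holes(labels == counts.argmax())
    else:
        raise ValueError(f"unknown FOV mask mode {mode!r}")
    if not mask.any():
        raise ValueError("empty FOV mask")
    return mask


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a two-column ``path,label`` CSV with labels in {normal, abnormal}."""
    df = pd.read_csv(path)
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"labels file {path} lacks columns {sorted(missing)}")
    bad = set(df["label"].unique()) - set(VALID_LABELS)
    if bad:
        raise ValueError(f"labels file {path} contains invalid labels {sorted(bad)}")
    return df[["path", "label"]]
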