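"""Two-class endoscopy-like synthetic frames.

Real capsule frames show smooth, warmly colored mucosa inside a
circular field of view, with fine surface texture; tumoral tissue
disrupts that texture locally, changing its frequency content and its
amplitude statistics.  The generator emulates exactly the properties
the feature pipeline measures, nothing more:

* a smooth low-frequency HSV background inside an inscribed-disc FOV,
  black corners outside;
* two additive band-limited noise textures, obtained by filtering white
  noise with ring bandpass filters in the frequency domain — a
  high-frequency band landing in the level-1 wavelet details and a
  mid-frequency band landing in the level-2 details;
* for abnormal frames, a circular lesion patch inside the FOV where the
  two band amplitudes are multiplied up and the texture amplitude is
  passed through a pointwise exponential transform, which skews its
  distribution — injecting signal into both the cross-scale
  second-order moments and the third-order moments.

Setting both multipliers to 1 and the skew to 0 makes the classes
statistically indistinguishable (null configuration).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from skimage import color

from wcetex.image_io import RawFrame

LABELS = ("normal", "abnormal")

#: radial frequency bands (cycles/pixel) feeding wavelet levels 1 and 2.
HIGH_BAND = (0.25, 0.45)
MID_BAND = (0.10, 0.20)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic corpus.

    ``high_mult``/``mid_mult`` scale the band-noise amplitudes inside
    the lesion patch of abnormal frames; ``skew`` is the exponential
    asymmetry parameter of the lesion texture (0 = symmetric);
    ``lesion_fraction`` is the lesion area as a fraction of the FOV
    area.
    """

    n_per_class: int = 200
    size: int = 256
    seed: int = 0
    fov_radius_fraction: float = 0.5
    hue_mean: float = 0.04
    sat_mean: float = 0.55
    val_mean: float = 0.55
    high_amp: float = 0.05
    mid_amp: float = 0.05
    high_mult: float = 2.0
    mid_mult: float = 1.6
    skew: float = 1.5
    lesion_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.high_mult <= 0 or self.mid_mult <= 0:
            raise ValueError("band-energy multipliers must be positive")
        if not 0 < self.lesion_fraction < 1:
            raise ValueError("lesion_fraction must be in (0, 1)")


def _fov_mask(size: int, radius_fraction: float) -> np.ndarray:
    r = radius_fraction * size
    yy, xx = np.ogrid[:size, :size]
    c = (size - 1) / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= r * r


def _ring_noise(rng: np.random.Generator, size: int, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance noise whose spectrum occupies a radial frequency ring."""
    white = rng.standard_normal((size, size))
    f = np.fft.fftfreq(size)
    rad = np.hypot(f[:, None], f[None, :])
    ring = (rad >= band[0]) & (rad < band[1])
    field = np.fft.ifft2(np.fft.fft2(white) * ring).real
    sd = field.std()
    return field / sd if sd > 0 else field


def _smooth_field(rng: np.random.Generator, size: int) -> np.ndarray:
    """Unit-variance low-frequency field (background undulation)."""
    return _ring_noise(rng, size, (0.0, 4.0 / size + 0.02))


def _skew_transform(t: np.ndarray, lam: float) -> np.ndarray:
    """Zero-preserving pointwise map with positive skew for lam > 0."""
    if lam == 0:
        return t
    return (np.exp(lam * t) - 1.0) / lam


def generate_frame(
    cfg: SynthConfig, label: str, rng: np.random.Generator
) -> tuple[RawFrame, str]:
    """Draw one labeled frame from the configured synthetic distribution."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    s = cfg.size
    mask = _fov_mask(s, cfg.fov_radius_fraction)

    hue = np.clip(cfg.hue_mean + 0.012 * _smooth_field(rng, s), 0.0, 1.0)
    sat = np.clip(cfg.sat_mean + 0.06 * _smooth_field(rng, s), 0.0, 1.0)
    val = cfg.val_mean + 0.08 * _smooth_field(rng, s)

    high = _ring_noise(rng, s, HIGH_BAND)
    mid = _ring_noise(rng, s, MID_BAND)
    texture = cfg.high_amp * high + cfg.mid_amp * mid

    if label == "abnormal":
        fov_r = cfg.fov_radius_fraction * s
        lesion_r = fov_r * np.sqrt(cfg.lesion_fraction)
        c = (s - 1) / 2.0
        # lesion centre uniform in the disc that keeps the lesion inside the FOV
        rho = (fov_r - lesion_r) * np.sqrt(rng.random())
        theta = 2 * np.pi * rng.random()
        cy, cx = c + rho * np.sin(theta), c + rho * np.cos(theta)
        yy, xx = np.ogrid[:s, :s]
        lesion = (yy - cy) ** 2 + (xx - cx) ** 2 <= lesion_r**2
        lesion_tex = _skew_transform(
            cfg.high_mult * cfg.high_amp * high + cfg.mid_mult * cfg.mid_amp * mid, cfg.skew
        )
        texture = np.where(lesion, lesion_tex, texture)

    val = np.clip(val + texture, 0.0, 1.0)
    hsv = np.stack([hue, sat, val], axis=-1)
    rgb = color.hsv2rgb(hsv)
    rgb[~mask] = 0.0
    pixels = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    return RawFrame(pixels=pixels, path=f"<synthetic:{label}>"), label


def generate_corpus(cfg: SynthConfig) -> list[tuple[RawFrame, str]]:
    """All frames of the configured corpus, in a deterministic order."""
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for label in LABELS:
        for _ in range(cfg.n_per_class):
            frames.append(generate_frame(cfg, label, rng))
    return frames


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> Path:
    """Write the corpus as PNG files plus ``labels.csv`` and ``manifest.json``.

    Returns the output directory.  The manifest echoes the configuration
    and records a content checksum per file, so equal seeds yield
    byte-identical datasets.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"cannot write to {out}: {exc}") from exc

    rows = []
    checksums = {}
    counters = {label: 0 for label in LABELS}
    for frame, label in generate_corpus(cfg):
        name = f"{label}_{counters[label]:04d}.png"
        counters[label] += 1
        iio.imwrite(out / name, frame.pixels)
        rows.append(f"{name},{label}")
        checksums[name] = hashlib.sha256((out / name).read_bytes()).hexdigest()

    (out / "labels.csv").write_text("path,label\n" + "\n".join(rows) + "\n")
    manifest = {"config": asdict(cfg), "seed": cfg.seed, "checksums": checksums}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


_FIXTURES = {
    "glcm4x4": np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]]),
    "constant8": np.zeros((8, 8), dtype=np.int64),
    "ramp32": np.tile(np.arange(32), (32, 1)),
}


def fixture_plane(name: str) -> np.ndarray:
    """Small hand-enumerable integer planes used by the co-occurrence oracles."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}")
    return _FIXTURES[name].copy()
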