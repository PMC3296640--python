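"""FOV-masked co-occurrence matrices and Haralick descriptors.

A synthesized focus image is quantized to ``n_levels`` gray levels
(min-max dispersion over the unmasked pixels, so the information packed
near zero in a detail reconstruction spreads over the whole level
range), co-occurrence matrices are accumulated at distance ``d`` in the
four directions {0, 45, 90, 135} degrees counting only pixel pairs that
lie entirely inside the field-of-view mask, and four scalar statistics
are taken from each matrix: angular second moment (F1), correlation
(F2), inverse difference moment (F3) and entropy (F4).

Over three HSV channels, two focus levels, four directions and four
measures this yields the 96-value descriptor tensor of a frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from wcetex.config import PipelineConfig
from wcetex.image_io import HSVFrame
from wcetex.wavelet_synthesis import SynthesizedImage, decompose, synthesize_focus_image

#: direction (degrees) -> (row, col) displacement per unit distance.
DIRECTIONS: dict[int, tuple[int, int]] = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
DIRECTION_ORDER = (0, 45, 90, 135)
MEASURE_ORDER = ("f1", "f2", "f3", "f4")
MASK_SENTINEL = -1


@dataclass
class QuantizedPlane:
    """Integer level plane in [0, n_levels-1]; masked pixels hold a sentinel."""

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray


@dataclass
class CooccurrenceMatrix:
    """Normalized gray-level co-occurrence matrix and its marginals."""

    p: np.ndarray  # n_levels x n_levels, sums to 1
    direction: int  # degrees in {0, 45, 90, 135}
    distance: int
    pair_count: int
    symmetric: bool
    mu_x: float = 0.0
    mu_y: float = 0.0
    sigma_x: float = 0.0
    sigma_y: float = 0.0

    def __post_init__(self) -> None:
        g = np.arange(self.p.shape[0], dtype=float)
        px = self.p.sum(axis=1)
        py = self.p.sum(axis=0)
        self.mu_x = float(g @ px)
        self.mu_y = float(g @ py)
        self.sigma_x = float(np.sqrt(((g - self.mu_x) ** 2) @ px))
        self.sigma_y = float(np.sqrt(((g - self.mu_y) ** 2) @ py))


@dataclass
class HaralickVector:
    f1: float  # angular second moment (homogeneity)
    f2: float  # correlation (directional linearity)
    f3: float  # inverse difference moment (smoothness)
    f4: float  # entropy (randomness)

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3, self.f4])


def quantize_plane(
    image: SynthesizedImage | np.ndarray, mask: np.ndarray, n_levels: int = 32
) -> QuantizedPlane:
    """Min-max quantize the unmasked pixels of a plane to ``n_levels`` levels.

    The unmasked values are affinely rescaled to [0, n_levels - 1] and
    floored; the maximum maps to level ``n_levels - 1`` and a constant
    plane maps entirely to level 0.
    """
    plane = image.plane if isinstance(image, SynthesizedImage) else np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if plane.shape != mask.shape:
        raise ValueError(f"plane shape {plane.shape} != mask shape {mask.shape}")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not mask.any():
        raise ValueError("empty mask: nothing to quantize")
    vals = plane[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.full(plane.shape, MASK_SENTINEL, dtype=np.int64)
    # a range at numerical-noise scale is a constant plane, not texture
    if hi - lo > 1e-12 * max(1.0, abs(lo), abs(hi)):
        scaled = (plane - lo) / (hi - lo) * (n_levels - 1)
        levels[mask] = np.clip(np.floor(scaled[mask]), 0, n_levels - 1).astype(np.int64)
    else:
        levels[mask] = 0
    return QuantizedPlane(levels=levels, n_levels=n_levels, mask=mask)


def cooccurrence_matrix(
    q: QuantizedPlane, direction: int, distance: int = 1, symmetric: bool = True
) -> CooccurrenceMatrix:
    """Count level pairs at the given displacement, both pixels unmasked.

    The displacement for direction ``a`` degrees and distance ``d`` is
    ``d * DIRECTIONS[a]`` in (row, col) convention.  In symmetric mode
    each pair is also counted in reversed order.  Counts are normalized
    to a probability matrix after accumulation.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}, got {direction}")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    dr, dc = (distance * o for o in DIRECTIONS[direction])
    h, w = q.levels.shape
    ng = q.n_levels

    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q.levels[r0:r1, c0:c1]
    b = q.levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = q.mask[r0:r1, c0:c1] & q.mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    av, bv = a[valid], b[valid]
    counts = np.bincount(av * ng + bv, minlength=ng * ng).astype(np.float64)
    if symmetric:
        counts += np.bincount(bv * ng + av, minlength=ng * ng)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pairs: mask admits no pixel pair at this displacement")
    return CooccurrenceMatrix(
        p=(counts / total).reshape(ng, ng),
        direction=direction,
        distance=distance,
        pair_count=int(av.size),
        symmetric=symmetric,
    )


def haralick_features(
    c: CooccurrenceMatrix, idm_form: str = "standard", entropy_sign: str = "negative"
) -> HaralickVector:
    """The four Haralick statistics of a normalized co-occurrence matrix.

    F1 = sum p^2; F2 = (sum i*j*p - mu_x*mu_y) / (sigma_x*sigma_y), defined
    as 0 when either marginal is degenerate; F3 in the standard form is
    sum p / (1 + (i-j)^2), while the ``as_printed`` form uses the
    first-power weight 1 / (1 + (i-j)) with the j == i+1 diagonal
    excluded; F4 is the Shannon entropy of p in bits (nonnegative under
    the default sign convention).
    """
    p = c.p
    ng = p.shape[0]
    i = np.arange(ng, dtype=float)[:, None]
    j = np.arange(ng, dtype=float)[None, :]

    f1 = float((p**2).sum())

    denom = c.sigma_x * c.sigma_y
    if denom <= 0:
        f2 = 0.0
    else:
        f2 = float(((i * j * p).sum() - c.mu_x * c.mu_y) / denom)

    if idm_form == "standard":
        f3 = float((p / (1.0 + (i - j) ** 2)).sum())
    elif idm_form == "as_printed":
        w = np.zeros_like(p)
        keep = j != i + 1  # excluded cell would divide by zero
        w[keep] = 1.0 / (1.0 + (i - j))[keep]
        f3 = float((p * w).sum())
    else:
        raise ValueError(f"unknown idm_form {idm_form!r}")

    nz = p[p > 0]
    ent = float((nz * np.log2(nz)).sum())
    if entropy_sign == "negative":
        f4 = -ent
    elif entropy_sign == "as_printed":
        f4 = ent
    else:
        raise ValueError(f"unknown entropy_sign {entropy_sign!r}")

    return HaralickVector(f1=f1, f2=f2, f3=f3, f4=f4)


def descriptor_tensor(frame: HSVFrame, config: PipelineConfig | None = None) -> np.ndarray:
    """The 96-value descriptor tensor of a frame.

    Axes are (measure m=1..4, direction a in {0,45,90,135}, channel
    i=H,S,V, focus j=1,2); the composition is decompose -> synthesize
    (both foci) -> quantize -> four-direction co-occurrence -> Haralick
    per matrix.
    """
    cfg = config or PipelineConfig()
    out = np.empty((4, 4, 3, 2), dtype=np.float64)
    for ci in range(3):
        plane = frame.channels[ci]
        if cfg.transform_variant == "identity":
            focus_images = {1: plane, 2: plane}
        else:
            sb = decompose(plane, wavelet=cfg.wavelet, variant=cfg.transform_variant)
            focus_images = {
                f: synthesize_focus_image(sb, f, channel=ci).plane for f in (1, 2)
            }
        for fj, syn in focus_images.items():
            q = quantize_plane(syn, frame.mask, cfg.n_levels)
            for ai, ang in enumerate(DIRECTION_ORDER):
                com = cooccurrence_matrix(q, ang, cfg.distance, cfg.symmetric)
                hv = haralick_features(com, cfg.idm_form, cfg.entropy_sign)
                out[:, ai, ci, fj - 1] = hv.as_array()
    return out


def descriptor_names() -> list[str]:
    """Column names of the flattened tensor, m-major then direction, channel, focus."""
    chans = ("H", "S", "V")
    return [
        f"m{m}_a{a}_c{c}_f{f}"
        for m in (1, 2, 3, 4)
        for a in DIRECTION_ORDER
        for c in chans
        for f in (1, 2)
    ]
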