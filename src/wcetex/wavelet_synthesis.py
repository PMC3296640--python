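"""Two-level wavelet decomposition and focus-image synthesis.

Each HSV channel is decomposed into six detail bands (three per level)
and a level-2 approximation.  Two focus images are then synthesized by
inverting a band-selected coefficient set: focus 1 keeps the level-1
(high-frequency) details, focus 2 the level-2 (medium-frequency)
details; the approximation is always zeroed, so a synthesized image is
a pure detail reconstruction and may take negative values.

The default transform is the undecimated wavelet frame (stationary
wavelet transform), whose sub-bands retain the source shape and whose
synthesis is shift-covariant; a critically sampled ``decimated``
variant is available.  Both use periodic boundary extension, which
keeps the decimated orthogonal transform energy-preserving and makes
reconstruction exact.  Inputs whose dimensions are not divisible by
four are symmetrically padded first and cropped after inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

#: band index -> (pyramid level, detail orientation): l=1..3 are the
#: level-1 horizontal/vertical/diagonal details, l=4..6 the level-2 ones.
BAND_LEVEL = {1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2}
FOCUS_BANDS = {1: (1, 2, 3), 2: (4, 5, 6)}


@dataclass
class SubbandSet:
    """Six detail planes, the level-2 approximation and transform metadata."""

    details: list[np.ndarray]  # index 0..5 holds bands l=1..6
    approx: np.ndarray
    wavelet: str
    variant: str
    shape: tuple[int, int]  # source shape before padding
    pad: tuple[int, int] = (0, 0)  # rows/cols of symmetric padding added

    def band(self, l: int) -> np.ndarray:
        """Detail plane for band index l in 1..6."""
        if not 1 <= l <= 6:
            raise ValueError(f"band index must be 1..6, got {l}")
        return self.details[l - 1]


@dataclass
class SynthesizedImage:
    """A single-channel detail reconstruction at one focus level."""

    plane: np.ndarray
    channel: int  # 0-based HSV channel index
    focus: int  # 1 (high frequency) or 2 (medium frequency)


def _check_wavelet(name: str) -> pywt.Wavelet:
    try:
        return pywt.Wavelet(name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {name!r}") from exc


def _pad_to_multiple(plane: np.ndarray, m: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = plane.shape
    ph = (-h) % m
    pw = (-w) % m
    if ph or pw:
        plane = np.pad(plane, ((0, ph), (0, pw)), mode="symmetric")
    return plane, (ph, pw)


def decompose(plane: np.ndarray, wavelet: str = "db2", variant: str = "frame") -> SubbandSet:
    """Two-level wavelet decomposition of a single channel plane.

    Parameters
    ----------
    plane
        Float image of at least 8 x 8 pixels.
    wavelet
        PyWavelets filter name.
    variant
        ``"frame"`` (undecimated, shift-covariant; all sub-bands keep the
        padded source shape) or ``"decimated"`` (critically sampled).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2 or min(plane.shape) < 8:
        raise ValueError(f"plane must be 2-D and at least 8x8, got shape {plane.shape}")
    _check_wavelet(wavelet)
    shape = plane.shape
    if variant == "frame":
        padded, pad = _pad_to_multiple(plane, 4)
        # swt2 lists the coarsest level first
        (ca2, d2), (_ca1, d1) = pywt.swt2(padded, wavelet, level=2)
        details = [d1[0], d1[1], d1[2], d2[0], d2[1], d2[2]]
        return SubbandSet(details, ca2, wavelet, variant, shape, pad)
    if variant == "decimated":
        ca2, d2, d1 = pywt.wavedec2(plane, wavelet, level=2, mode="periodization")
        details = [d1[0], d1[1], d1[2], d2[0], d2[1], d2[2]]
        return SubbandSet(details, ca2, wavelet, variant, shape, (0, 0))
    raise ValueError(f"unknown transform variant {variant!r}")


def _invert(sb: SubbandSet, details: list[np.ndarray], approx: np.ndarray) -> np.ndarray:
    d1 = tuple(details[0:3])
    d2 = tuple(details[3:6])
    if sb.variant == "frame":
        rec = pywt.iswt2([(approx, d2), (None, d1)], sb.wavelet)
        h, w = sb.shape
        return rec[:h, :w]
    rec = pywt.waverec2([approx, d2, d1], sb.wavelet, mode="periodization")
    return rec[: sb.shape[0], : sb.shape[1]]


def synthesize_focus_image(sb: SubbandSet, focus: int, channel: int = 0) -> SynthesizedImage:
    """Invert a band-selected coefficient set into a focus image.

    Focus 1 keeps detail bands {1, 2, 3}, focus 2 keeps {4, 5, 6}; every
    other band and the approximation are zeroed before inversion.  The
    result is cropped back to the source shape.
    """
    if focus not in FOCUS_BANDS:
        raise ValueError(f"focus must be 1 or 2, got {focus}")
    keep = FOCUS_BANDS[focus]
    details = [
        sb.details[l - 1] if l in keep else np.zeros_like(sb.details[l - 1]) for l in range(1, 7)
    ]
    plane = _invert(sb, details, np.zeros_like(sb.approx))
    return SynthesizedImage(plane=plane, channel=channel, focus=focus)


def reconstruct(sb: SubbandSet) -> np.ndarray:
    """Full inverse transform of an untouched SubbandSet (perfect reconstruction)."""
    return _invert(sb, list(sb.details), sb.approx)


def synthesize_approx_only(sb: SubbandSet) -> np.ndarray:
    """Inverse transform keeping only the level-2 approximation.

    Together with the two focus images this completes the linear
    partition of the input: focus1 + focus2 + approx-only == source.
    """
    details = [np.zeros_like(d) for d in sb.details]
    return _invert(sb, details, sb.approx)
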