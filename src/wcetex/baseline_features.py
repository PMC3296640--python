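"""Texture-spectrum and histogram baseline features.

The comparison feature set codes each of the six color channels
(R, G, B, H, S, V) either by its texture spectrum — the normalized
histogram of 3x3 texture-unit numbers — or by its plain 256-bin
intensity histogram, and summarizes each distribution with nine
statistics, giving a 54-component vector per frame.

A texture unit compares the eight neighbours of a pixel with its
centre: E_i = 0, 1 or 2 for neighbour below, equal to or above the
centre, scanned clockwise from the top-left corner, and is indexed as
the base-3 number NTU = sum E_i * 3^(i-1) in [0, 6560].

The nine distribution statistics are standard deviation, variance,
skewness, kurtosis, entropy, energy, inverse difference moment,
contrast and covariance.  The source description leaves the last three
underspecified for 1-D spectra, so this module fixes them: IDM weights
each bin by 1/(1 + g^2) with g the bin-index distance from the mode;
contrast is the second central moment; covariance is the cross moment
E[(g - mu)(g - mu_ref)] under the channel's own spectrum, with the
V-channel spectrum of the same frame as the reference (so the V channel
itself reports its variance).
"""

from __future__ import annotations

import numpy as np

from wcetex.image_io import RawFrame, rgb_to_hsv

N_TU = 6561  # 3^8 texture-unit numbers
#: clockwise neighbour scan from the top-left corner, (row, col) offsets.
NEIGHBOR_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))
STAT_NAMES = (
    "std",
    "variance",
    "skew",
    "kurtosis",
    "entropy",
    "energy",
    "idm",
    "contrast",
    "covariance",
)
CHANNEL_NAMES = ("R", "G", "B", "H", "S", "V")


def texture_unit_number(patch: np.ndarray) -> int:
    """Texture-unit number of a single 3x3 integer patch."""
    patch = np.asarray(patch)
    if patch.shape != (3, 3):
        raise ValueError(f"patch must be 3x3, got {patch.shape}")
    center = patch[1, 1]
    ntu = 0
    for i, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        v = patch[1 + dr, 1 + dc]
        e = 0 if v < center else (1 if v == center else 2)
        ntu += e * 3**i
    return int(ntu)


def texture_spectrum(channel: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Normalized histogram of texture-unit numbers over a channel.

    Only interior pixels whose full 3x3 neighbourhood is unmasked
    contribute.
    """
    channel = np.asarray(channel)
    if mask is None:
        mask = np.ones(channel.shape, dtype=bool)
    center = channel[1:-1, 1:-1]
    valid = mask[1:-1, 1:-1].copy()
    codes = np.zeros(center.shape, dtype=np.int64)
    for i, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        neigh = channel[1 + dr : channel.shape[0] - 1 + dr, 1 + dc : channel.shape[1] - 1 + dc]
        valid &= mask[1 + dr : mask.shape[0] - 1 + dr, 1 + dc : mask.shape[1] - 1 + dc]
        e = np.where(neigh < center, 0, np.where(neigh == center, 1, 2))
        codes += e * 3**i
    if not valid.any():
        raise ValueError("no interior pixel has a fully unmasked 3x3 neighbourhood")
    hist = np.bincount(codes[valid], minlength=N_TU).astype(np.float64)
    return hist / hist.sum()


def intensity_histogram(channel: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Normalized 256-bin intensity histogram over unmasked pixels."""
    channel = np.asarray(channel)
    if mask is None:
        mask = np.ones(channel.shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    hist = np.bincount(channel[mask].ravel().astype(np.int64), minlength=256).astype(np.float64)
    return hist / hist.sum()


def spectrum_statistics(dist: np.ndarray, ref: np.ndarray | None = None) -> np.ndarray:
    """The nine distribution statistics of a normalized histogram.

    ``ref`` is the reference spectrum for the covariance cross moment;
    by default the histogram itself (covariance then equals variance).
    Degenerate distributions (zero spread) report 0 skewness/kurtosis.
    """
    h = np.asarray(dist, dtype=np.float64)
    if abs(h.sum() - 1.0) > 1e-8:
        raise ValueError("histogram must be normalized to sum 1")
    if ref is None:
        ref = h
    ref = np.asarray(ref, dtype=np.float64)
    g = np.arange(h.size, dtype=np.float64)
    mu = float(g @ h)
    var = float(((g - mu) ** 2) @ h)
    std = float(np.sqrt(var))
    if std > 0:
        skew = float((((g - mu) / std) ** 3) @ h)
        kurt = float((((g - mu) / std) ** 4) @ h)
    else:
        skew = 0.0
        kurt = 0.0
    nz = h[h > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    energy = float((h**2).sum())
    mode = int(h.argmax())
    idm = float((h / (1.0 + (g - mode) ** 2)).sum())
    contrast = var
    g_ref = np.arange(ref.size, dtype=np.float64)
    mu_ref = float(g_ref @ ref)
    covariance = float(((g - mu) * (g - mu_ref)) @ h)
    return np.array([std, var, skew, kurt, entropy, energy, idm, contrast, covariance])


def baseline_vector(
    frame: RawFrame, scheme: str = "ntu", mask: np.ndarray | None = None
) -> np.ndarray:
    """The 54-component baseline feature vector of a frame.

    For each of R, G, B, H, S, V the texture spectrum (``scheme="ntu"``)
    or the 256-bin intensity histogram (``scheme="histogram"``) is built
    and summarized by the nine statistics, channel-major.
    """
    if scheme not in ("ntu", "histogram"):
        raise ValueError(f"unknown baseline scheme {scheme!r}")
    hsv = rgb_to_hsv(frame, mask=mask)
    channels = [frame.pixels[:, :, k].astype(np.int64) for k in range(3)]
    channels += [
        np.clip(np.round(hsv.channels[k] * 255.0), 0, 255).astype(np.int64) for k in range(3)
    ]
    build = texture_spectrum if scheme == "ntu" else intensity_histogram
    spectra = [build(ch, hsv.mask) for ch in channels]
    ref = spectra[5]  # V-channel spectrum anchors the covariance cross moment
    return np.concatenate([spectrum_statistics(s, ref) for s in spectra])


def baseline_names() -> list[str]:
    return [f"{stat}_{ch}" for ch in CHANNEL_NAMES for stat in STAT_NAMES]
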