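"""Second- and third-order moments over the color-scale space.

The six channel-scale keys {H, S, V, h, s, v} index the descriptor
tensor: an uppercase letter is the high-frequency focus image (level-1
detail bands) of that HSV channel, a lowercase letter the
medium-frequency one (level-2 bands).  For each of the four Haralick
measures, products of descriptor values at the same co-occurrence
direction are summed over the four directions:

* phi   — 21 second-order moments, one per unordered key pair
          (diagonal included), capturing cross-channel and cross-scale
          correlation of a measure;
* gamma — 6 marginal third-order moments (cubed sums), sensitive to the
          skewness of a measure at one key;
* zeta  — 8 joint third-order moments over triples that take one letter
          per color with both cases: HSV, hSV, HsV, HSv, hsv, Hsv, hSv,
          hsV.  Triples mixing two scales of the same color (e.g. HhV)
          are excluded — that correlation is already present in phi.

All moments are raw product sums over directions (no centering or
normalization).  Concatenated over the four measures this gives the
140-component observation vector: 84 phi + 24 gamma + 32 zeta.

A single-scale ablation restricted to {H, S, V} (6 phi + 3 gamma +
1 zeta per measure = 40 components) is provided for comparison runs.
"""

from __future__ import annotations

import numpy as np

KEYS = ("H", "S", "V", "h", "s", "v")
#: key -> (channel index, focus index) into the (4, 4, 3, 2) tensor.
KEY_TO_INDEX = {"H": (0, 0), "S": (1, 0), "V": (2, 0), "h": (0, 1), "s": (1, 1), "v": (2, 1)}

#: the 21 unordered pairs in row-major upper-triangle order over KEYS.
PAIRS = tuple(
    (KEYS[a], KEYS[b]) for a in range(len(KEYS)) for b in range(a, len(KEYS))
)

#: joint third-order triples: one letter per color, both cases, same-color
#: cross-scale combinations excluded.
TRIPLES = ("HSV", "hSV", "HsV", "HSv", "hsv", "Hsv", "hSv", "hsV")

SINGLE_SCALE_KEYS = ("H", "S", "V")
SINGLE_SCALE_PAIRS = tuple(
    (SINGLE_SCALE_KEYS[a], SINGLE_SCALE_KEYS[b])
    for a in range(3)
    for b in range(a, 3)
)
SINGLE_SCALE_TRIPLES = ("HSV",)


def _slice(t: np.ndarray, m: int, key: str) -> np.ndarray:
    """Descriptor values over the 4 directions for measure m and one key."""
    ci, fj = KEY_TO_INDEX[key]
    return t[m, :, ci, fj]


def _check_tensor(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    if t.shape != (4, 4, 3, 2):
        raise ValueError(f"descriptor tensor must have shape (4, 4, 3, 2), got {t.shape}")
    return t


def phi_moments(t: np.ndarray, pairs: tuple = PAIRS) -> np.ndarray:
    """Second-order moments: for each measure and key pair, sum over the
    four directions of the product of the two descriptor values."""
    t = _check_tensor(t)
    return np.array(
        [float(_slice(t, m, a) @ _slice(t, m, b)) for m in range(4) for a, b in pairs]
    )


def gamma_moments(t: np.ndarray, keys: tuple = KEYS) -> np.ndarray:
    """Marginal third-order moments: cubed descriptor values summed over directions."""
    t = _check_tensor(t)
    return np.array(
        [float((_slice(t, m, k) ** 3).sum()) for m in range(4) for k in keys]
    )


def zeta_moments(t: np.ndarray, triples: tuple = TRIPLES) -> np.ndarray:
    """Joint third-order moments over the listed channel-scale triples."""
    t = _check_tensor(t)
    out = []
    for m in range(4):
        for tri in triples:
            a, b, c = (_slice(t, m, k) for k in tri)
            out.append(float((a * b * c).sum()))
    return np.array(out)


def assemble_observation_vector(t: np.ndarray, single_scale: bool = False) -> np.ndarray:
    """Concatenate phi, gamma and zeta into the fixed-order observation vector.

    140 components in the multi-scale layout, 40 in the single-scale
    ablation (keys restricted to the high-frequency focus).
    """
    if single_scale:
        return np.concatenate(
            [
                phi_moments(t, SINGLE_SCALE_PAIRS),
                gamma_moments(t, SINGLE_SCALE_KEYS),
                zeta_moments(t, SINGLE_SCALE_TRIPLES),
            ]
        )
    return np.concatenate([phi_moments(t), gamma_moments(t), zeta_moments(t)])


def observation_names(single_scale: bool = False) -> list[str]:
    """Column names matching :func:`assemble_observation_vector`'s order."""
    pairs = SINGLE_SCALE_PAIRS if single_scale else PAIRS
    keys = SINGLE_SCALE_KEYS if single_scale else KEYS
    triples = SINGLE_SCALE_TRIPLES if single_scale else TRIPLES
    names = [f"phi_m{m}_{a}{b}" for m in (1, 2, 3, 4) for a, b in pairs]
    names += [f"gamma_m{m}_{k}" for m in (1, 2, 3, 4) for k in keys]
    names += [f"zeta_m{m}_{tri}" for m in (1, 2, 3, 4) for tri in triples]
    return names
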