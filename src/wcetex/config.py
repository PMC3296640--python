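"""Pipeline configuration shared by the feature-extraction stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the texture feature extraction pipeline.

    Parameters
    ----------
    wavelet
        PyWavelets filter name used for the two-level decomposition.
        Short-support Daubechies-2 by default, so fine texture is not
        smeared across neighbouring coefficients.
    transform_variant
        ``"frame"`` for the undecimated (stationary) wavelet frame
        transform, ``"decimated"`` for the critically sampled pyramid,
        or ``"identity"`` — a diagnostic mode that skips the wavelet
        stage and feeds the raw channel to both focus levels.
    levels
        Decomposition depth.  The descriptor layout assumes exactly two
        levels (six detail bands per channel); other values are rejected.
    n_levels
        Gray-level count after quantization of a synthesized image.
    distance
        Pixel-pair displacement of the co-occurrence counting.
    symmetric
        Accumulate each pixel pair in both orders (Haralick convention).
    idm_form
        ``"standard"`` uses the squared-difference inverse difference
        moment; ``"as_printed"`` the first-power weight with the
        ``j == i + 1`` cell excluded.
    entropy_sign
        ``"negative"`` yields the conventional nonnegative entropy;
        ``"as_printed"`` flips the sign.
    resize_to
        Optional edge length; frames are resized to this square shape
        before decomposition (resolution regularization).  ``None``
        disables resizing.
    fov_mode
        ``"disc"`` (inscribed circle) or ``"threshold"`` (bright-region)
        field-of-view mask construction.
    fov_radius_fraction
        Disc-mask radius as a fraction of the smaller image dimension.
    fov_dark_threshold
        Brightness cut (on V in [0, 1]) for the threshold mask mode.
    """

    wavelet: str = "db2"
    transform_variant: str = "frame"
    levels: int = 2
    n_levels: int = 32
    distance: int = 1
    symmetric: bool = True
    idm_form: str = "standard"
    entropy_sign: str = "negative"
    resize_to: int | None = None
    fov_mode: str = "disc"
    fov_radius_fraction: float = 0.5
    fov_dark_threshold: float = 0.06

    def __post_init__(self) -> None:
        if self.levels != 2:
            raise ValueError(f"only 2-level decompositions are supported, got levels={self.levels}")
        if self.transform_variant not in ("frame", "decimated", "identity"):
            raise ValueError(f"unknown transform_variant {self.transform_variant!r}")
        if self.idm_form not in ("standard", "as_printed"):
            raise ValueError(f"unknown idm_form {self.idm_form!r}")
        if self.entropy_sign not in ("negative", "as_printed"):
            raise ValueError(f"unknown entropy_sign {self.entropy_sign!r}")
        if self.fov_mode not in ("disc", "threshold"):
            raise ValueError(f"unknown fov_mode {self.fov_mode!r}")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
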