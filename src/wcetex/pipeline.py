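"""Frame-to-feature-table plumbing shared by the CLI, tests and scripts."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from wcetex.baseline_features import baseline_names, baseline_vector
from wcetex.config import PipelineConfig
from wcetex.glcm_features import descriptor_tensor
from wcetex.hos_model import assemble_observation_vector, observation_names
from wcetex.image_io import RawFrame, load_frame, make_fov_mask, read_labels, rgb_to_hsv


def _prepare(frame: RawFrame, cfg: PipelineConfig) -> RawFrame:
    if cfg.resize_to is None:
        return frame
    from skimage.transform import resize

    px = resize(frame.pixels, (cfg.resize_to, cfg.resize_to), anti_aliasing=True)
    return RawFrame(
        pixels=np.clip(np.round(px * 255.0), 0, 255).astype(np.uint8), path=frame.path
    )


def frame_tensor(frame: RawFrame, cfg: PipelineConfig | None = None) -> np.ndarray:
    """The (4, 4, 3, 2) descriptor tensor of a raw frame."""
    cfg = cfg or PipelineConfig()
    frame = _prepare(frame, cfg)
    mask = make_fov_mask(frame, cfg.fov_mode, cfg.fov_radius_fraction, cfg.fov_dark_threshold)
    hsv = rgb_to_hsv(frame, mask=mask)
    return descriptor_tensor(hsv, cfg)


def frame_observation(
    frame: RawFrame, cfg: PipelineConfig | None = None, single_scale: bool = False
) -> np.ndarray:
    """The observation vector (140 components, or 40 single-scale) of a frame."""
    return assemble_observation_vector(frame_tensor(frame, cfg), single_scale=single_scale)


def observation_table(
    frames: Sequence[tuple[RawFrame, str]],
    cfg: PipelineConfig | None = None,
    single_scale: bool = False,
    workers: int = 1,
) -> pd.DataFrame:
    """Observation vectors of labeled frames as a DataFrame.

    Rows keep the input order regardless of the worker count.
    """
    cfg = cfg or PipelineConfig()
    vecs = Parallel(n_jobs=workers)(
        delayed(frame_observation)(f, cfg, single_scale) for f, _ in frames
    )
    df = pd.DataFrame(np.asarray(vecs), columns=observation_names(single_scale))
    df.insert(0, "path", [f.path for f, _ in frames])
    df["label"] = [lab for _, lab in frames]
    return df


def baseline_table(
    frames: Sequence[tuple[RawFrame, str]], scheme: str = "ntu", workers: int = 1
) -> pd.DataFrame:
    """Baseline 54-feature vectors of labeled frames as a DataFrame."""
    vecs = Parallel(n_jobs=workers)(delayed(baseline_vector)(f, scheme) for f, _ in frames)
    df = pd.DataFrame(np.asarray(vecs), columns=baseline_names())
    df.insert(0, "path", [f.path for f, _ in frames])
    df["label"] = [lab for _, lab in frames]
    df["scheme"] = scheme
    return df


def load_labeled_frames(labels_csv: str | Path, root: str | Path | None = None) -> list[
    tuple[RawFrame, str]
]:
    """Read the frames referenced by a ``path,label`` CSV."""
    labels_csv = Path(labels_csv)
    root = Path(root) if root is not None else labels_csv.parent
    df = read_labels(labels_csv)
    return [(load_frame(root / p), lab) for p, lab in zip(df["path"], df["label"])]


def table_to_xy(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature DataFrame into the matrix and 0/1 labels."""
    meta = [c for c in ("path", "label", "scheme") if c in df.columns]
    X = df.drop(columns=meta).to_numpy(dtype=np.float64)
    y = (df["label"] == "abnormal").to_numpy().astype(int)
    return X, y
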