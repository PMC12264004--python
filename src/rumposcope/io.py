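"""File formats: TIFF stacks, CSV tables, YAML configuration."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .camera import CameraModel
from .localize import LOCALIZATION_COLUMNS
from .simulate import FrameStack


def write_stack(path, stack: FrameStack) -> None:
    """Write a movie as multi-page 16-bit grayscale TIFF."""
    tifffile.imwrite(path, stack.frames.astype(np.uint16),
                     metadata={"frame_time_s": stack.frame_time,
                               "pixel_size_nm": stack.camera.pixel_size})


def read_stack(path, camera: CameraModel | None = None,
               frame_time: float = 0.035) -> FrameStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if camera is None:
        camera = CameraModel(sensor_shape=frames.shape[1:])
    return FrameStack(frames=frames.astype(np.uint16), camera=camera,
                      frame_time=frame_time)


def write_localizations(path, table: pd.DataFrame) -> None:
    """Localization table CSV with the fixed schema, floats at 3 decimals."""
    out = table[LOCALIZATION_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.3f", encoding="utf-8")


def read_localizations(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(LOCALIZATION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"localization CSV missing columns: {missing}")
    return table


def write_ground_truth(path, emitters) -> None:
    pd.DataFrame({"molecule_id": emitters.molecule_id,
                  "x_nm": emitters.positions[:, 0],
                  "y_nm": emitters.positions[:, 1],
                  "label": emitters.label}).to_csv(
        path, index=False, float_format="%.3f")


def write_drift(path, drift: np.ndarray) -> None:
    pd.DataFrame({"frame": np.arange(len(drift)),
                  "dx_nm": drift[:, 0],
                  "dy_nm": drift[:, 1]}).to_csv(
        path, index=False, float_format="%.3f")


def read_drift(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["dx_nm", "dy_nm"]].to_numpy()


def write_events(path, event_set) -> None:
    cols = ["event_id", "x_nm", "y_nm", "first_frame", "last_frame",
            "n_locs", "total_photons"]
    event_set.events[cols].to_csv(path, index=False, float_format="%.3f")


def write_profile(path, profile) -> None:
    pd.DataFrame({"arc_nm": profile.arc_nm,
                  "intensity": profile.intensity}).to_csv(
        path, index=False, float_format="%.6g")


def read_path_polyline(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x_nm", "y_nm"]].to_numpy()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
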