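"""Reading and writing the package's on-disk formats.

Profiles travel as CSV with columns ``r_um, value, channel, background``;
model/rate parameters as YAML blocks; images as single-plane TIFF with a
YAML sidecar holding the pixel size and channel mapping; merger and
gliding data as tidy CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import AsterImagePair, ModelParams, RadialProfile, RateParams

__all__ = [
    "write_profile_csv",
    "read_profile_csv",
    "write_params_yaml",
    "read_params_yaml",
    "write_image_pair",
    "read_image_pair",
    "write_ground_truth",
    "read_tracks_csv",
]


def write_profile_csv(profile: RadialProfile, path) -> None:
    pd.DataFrame(
        {
            "r_um": profile.r_centers,
            "value": profile.values,
            "channel": profile.channel,
            "background": profile.background,
        }
    ).to_csv(path, index=False)


def read_profile_csv(path) -> RadialProfile:
    df = pd.read_csv(path)
    return RadialProfile(
        df["r_um"].to_numpy(),
        df["value"].to_numpy(),
        channel=str(df["channel"].iloc[0]),
        background=float(df["background"].iloc[0]),
    )


def write_params_yaml(params, path) -> None:
    """Serialize ModelParams or RateParams as a YAML block."""
    if isinstance(params, ModelParams):
        block = {"model_params": {"Kd": params.Kd, "lambda0_um": params.lambda0, "C": params.C}}
    elif isinstance(params, RateParams):
        block = {
            "rate_params": {
                "kon": params.kon, "koff": params.koff,
                "D_um2_s": params.D, "v_um_s": params.v,
            }
        }
    else:
        raise TypeError("expected ModelParams or RateParams")
    Path(path).write_text(yaml.safe_dump(block))


def read_params_yaml(path):
    doc = yaml.safe_load(Path(path).read_text())
    if "model_params" in doc:
        p = doc["model_params"]
        return ModelParams(Kd=p["Kd"], lambda0=p["lambda0_um"], C=p["C"])
    if "rate_params" in doc:
        p = doc["rate_params"]
        return RateParams(kon=p["kon"], koff=p["koff"], D=p["D_um2_s"], v=p["v_um_s"])
    raise ValueError("no recognized parameter block in YAML")


def write_image_pair(pair: AsterImagePair, directory, stem: str = "aster") -> None:
    """TIFF per channel plus a YAML sidecar with the pixel size."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{stem}_mt.tif", pair.mt_image.astype(np.float32))
    tifffile.imwrite(directory / f"{stem}_motor.tif", pair.motor_image.astype(np.float32))
    sidecar = {
        "pixel_size_um": pair.pixel_size,
        "mt_channel": f"{stem}_mt.tif",
        "motor_channel": f"{stem}_motor.tif",
    }
    (directory / f"{stem}.yaml").write_text(yaml.safe_dump(sidecar))


def read_image_pair(sidecar_path) -> AsterImagePair:
    sidecar_path = Path(sidecar_path)
    meta = yaml.safe_load(sidecar_path.read_text())
    base = sidecar_path.parent
    return AsterImagePair(
        mt_image=tifffile.imread(base / meta["mt_channel"]),
        motor_image=tifffile.imread(base / meta["motor_channel"]),
        pixel_size=float(meta["pixel_size_um"]),
    )


def write_ground_truth(truth_dict: dict, path) -> None:
    """Machine-readable sidecar for a generated dataset."""
    Path(path).write_text(json.dumps(truth_dict, indent=2))


def read_tracks_csv(path) -> list:
    """Track table (t_s, x_um[, y_um], track_id) → list of per-track arrays."""
    df = pd.read_csv(path)
    cols = ["t_s", "x_um"] + (["y_um"] if "y_um" in df.columns else [])
    return [g[cols].to_numpy() for _, g in df.groupby("track_id", sort=True)]
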