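"""NIfTI / CSV / config serialisation helpers."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def save_nifti(volume: np.ndarray, path, pixel_mm: float = 2.0) -> None:
    """Write a 2-D slice, or a dynamic (n_frames, ny, nx) stack, as NIfTI.

    Dynamic stacks are stored with time as the 4th NIfTI dimension.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim == 2:
        data = vol[:, :, None]
    elif vol.ndim == 3:
        data = np.moveaxis(vol, 0, -1)[:, :, None, :]
    else:
        raise ValueError("expected a 2-D image or a (frames, ny, nx) stack")
    affine = np.diag([pixel_mm, pixel_mm, pixel_mm, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_nifti(path) -> np.ndarray:
    """Read a NIfTI written by :func:`save_nifti` back to 2-D or (frames, ny, nx)."""
    data = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    data = np.squeeze(data, axis=2) if data.ndim >= 3 and data.shape[2] == 1 else data
    if data.ndim == 2:
        return data
    if data.ndim == 3:
        return np.moveaxis(data, -1, 0)
    raise ValueError(f"unexpected NIfTI shape {data.shape}")


def save_curve_csv(t_min: np.ndarray, values: np.ndarray, path, value_name: str = "value") -> None:
    pd.DataFrame({"time_min": t_min, value_name: values}).to_csv(path, index=False)


def load_curve_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_config(path) -> dict:
    """Read a JSON or YAML experiment configuration."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
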