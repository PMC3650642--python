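"""ROI measurements: volume, centre of mass, slice span."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ProtocolWarning
from .io_space import Mask3D

__all__ = ["mask_volume", "mask_center_of_mass", "slice_span", "measurement_report"]

_AXES = {"x": 0, "y": 1, "z": 2}


def mask_volume(mask: Mask3D) -> float:
    """ROI volume in mm^3: foreground voxel count times voxel volume."""
    n = mask.n_voxels
    if n == 0:
        warnings.warn("empty mask: volume is 0", ProtocolWarning, stacklevel=2)
        return 0.0
    return float(n * mask.voxel_volume)


def mask_center_of_mass(mask: Mask3D) -> np.ndarray:
    """Unweighted mean of foreground voxel-centre world coordinates (mm).

    The protocol's ROIs are binary, so no intensity weighting is applied.
    """
    idx = np.argwhere(mask.data > 0)
    if idx.size == 0:
        raise ValueError("centre of mass undefined for an empty mask")
    a = np.asarray(mask.affine)
    world = idx @ a[:3, :3].T + a[:3, 3]
    return world.mean(axis=0)


def slice_span(mask: Mask3D, axis: str = "y") -> int:
    """Number of distinct grid slices along ``axis`` with >= 1 foreground voxel."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    ax = _AXES[axis]
    others = tuple(i for i in range(3) if i != ax)
    return int(np.count_nonzero(mask.data.any(axis=others)))


def measurement_report(masks: dict[str, Mask3D],
                       out_csv: str | Path | None = None) -> pd.DataFrame:
    """Tabulate volume, centre of mass and coronal slice span per mask."""
    rows = []
    for label, m in masks.items():
        n = m.n_voxels
        com = mask_center_of_mass(m) if n else (np.nan, np.nan, np.nan)
        rows.append(
            {
                "label": label,
                "n_voxels": n,
                "volume_mm3": mask_volume(m) if n else 0.0,
                "com_x": com[0],
                "com_y": com[1],
                "com_z": com[2],
                "slice_span_y": slice_span(m, "y") if n else 0,
            }
        )
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
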