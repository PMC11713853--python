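"""Reading and writing hybrid stacks, masks and parameter maps.

On-disk dialect: a 4-D NIfTI-1 volume with shape ``(X, Y, Z, M*N)`` whose
4th axis flattens the TE x b grid (TE-major by default: index
``i * N + j`` holds echo time i, b-value j), plus a JSON sidecar

    {"tes_ms": [...], "bvalues_s_mm2": [...], "flattening": "te-major"}

Masks are 3-D NIfTI volumes of 0/1.  Parameter maps are written back as
3-D or 4-D NIfTI with a JSON sidecar recording units and axis meanings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from mahm.core import EigenMapSet
from mahm.grid import AcquisitionGrid, HybridStack

__all__ = [
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_map",
    "write_eigenmaps",
    "eigenmaps_to_frame",
    "write_png",
]

PathLike = Union[str, Path]


def _nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4))


def write_stack(
    stack: HybridStack, volume_path: PathLike, sidecar_path: PathLike
) -> None:
    """Write a stack as 4-D NIfTI (TE-major flattening) + JSON sidecar."""
    X, Y, Z, M, N = stack.signal.shape
    flat = stack.signal.reshape(X, Y, Z, M * N)
    nib.save(_nifti(flat), str(volume_path))
    sidecar = {
        "tes_ms": list(stack.grid.tes),
        "bvalues_s_mm2": list(stack.grid.bvalues),
        "flattening": "te-major",
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_stack(volume_path: PathLike, sidecar_path: PathLike) -> HybridStack:
    """Read a 4-D NIfTI volume + JSON sidecar into a :class:`HybridStack`.

    The sidecar's grid must satisfy the acquisition-grid invariants and
    its M*N must match the volume's 4th dimension; a ``"b-major"``
    flattening is transposed into the package's TE-major memory layout.
    """
    sidecar = json.loads(Path(sidecar_path).read_text())
    try:
        grid = AcquisitionGrid(sidecar["tes_ms"], sidecar["bvalues_s_mm2"])
    except KeyError as err:
        raise ValueError(f"sidecar is missing required key {err}") from err
    flattening = sidecar.get("flattening", "te-major")
    if flattening not in ("te-major", "b-major"):
        raise ValueError(f"unknown flattening {flattening!r}")

    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got {data.ndim}-D")
    X, Y, Z, L = data.shape
    if L != grid.m * grid.n:
        raise ValueError(
            f"volume 4th dimension is {L}, expected M*N = "
            f"{grid.m}*{grid.n} = {grid.m * grid.n} per sidecar"
        )
    if flattening == "te-major":
        signal = data.reshape(X, Y, Z, grid.m, grid.n)
    else:
        signal = data.reshape(X, Y, Z, grid.n, grid.m).transpose(0, 1, 2, 4, 3)
    return HybridStack(signal, grid)


def write_mask(mask: np.ndarray, path: PathLike) -> None:
    m = np.asarray(mask)
    if m.ndim == 2:
        m = m[:, :, None]
    nib.save(nib.Nifti1Image(m.astype(np.uint8), np.eye(4)), str(path))


def read_mask(path: PathLike) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError(f"mask must be 2-D or 3-D, got {data.ndim}-D")
    return data > 0


def write_map(
    values: np.ndarray,
    path: PathLike,
    units: str = "",
    sidecar_path: Optional[PathLike] = None,
    **meta,
) -> None:
    """Write a parameter map (3-D or 4-D) with an optional JSON sidecar
    recording units and extra metadata."""
    nib.save(_nifti(values), str(path))
    if sidecar_path is not None:
        Path(sidecar_path).write_text(
            json.dumps({"units": units, **meta}, indent=2)
        )


def write_eigenmaps(maps: EigenMapSet, out_dir: PathLike, prefix: str = "") -> dict:
    """Write eigenvalue / eigenvector / lambda_r maps to a directory.

    Returns a manifest of written paths.  Eigenvalues go to a 4-D volume
    (4th axis = eigenvalue index, descending); eigenvector components to a
    5-D-flattened 4-D volume (component-major within vector); lambda_r and
    its cap flag to 3-D volumes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    K = maps.k
    manifest = {}

    def save(name, data):
        p = out / f"{prefix}{name}.nii"
        nib.save(_nifti(data), str(p))
        manifest[name] = str(p)

    save("eigenvalues", maps.eigenvalues)
    X, Y, Z = maps.valid.shape
    save("eigenvectors", maps.eigenvectors.reshape(X, Y, Z, K * K))
    save("lambda_r", maps.lambda_r)
    save("lambda_r_capped", maps.capped.astype(float))
    save("valid_mask", maps.valid.astype(float))
    meta = {
        "orientation": maps.orientation,
        "lambda_r_cap": maps.cap,
        "tes_ms": list(maps.grid.tes),
        "bvalues_s_mm2": list(maps.grid.bvalues),
        "eigenvalue_order": "descending",
        "eigenvector_flattening": "vector-major (vec i, component c at i*K+c)",
    }
    (out / f"{prefix}eigenmaps.json").write_text(json.dumps(meta, indent=2))
    manifest["sidecar"] = str(out / f"{prefix}eigenmaps.json")
    return manifest


def eigenmaps_to_frame(maps: EigenMapSet) -> pd.DataFrame:
    """Tabulate valid pixels: index, eigenvalues, lambda_r, flags."""
    idx = np.argwhere(maps.valid)
    rows = {
        "x": idx[:, 0],
        "y": idx[:, 1],
        "z": idx[:, 2],
    }
    for i in range(maps.k):
        rows[f"lambda{i + 1}"] = maps.eigenvalues[maps.valid][:, i]
    rows["lambda_r"] = maps.lambda_r[maps.valid]
    rows["capped"] = maps.capped[maps.valid]
    rows["floored"] = maps.floored[maps.valid]
    return pd.DataFrame(rows)


def write_png(
    image: np.ndarray, path: PathLike, scaling_meta: Optional[dict] = None
) -> None:
    """Write an 8-bit image; optionally record the display scaling bounds
    in a JSON sidecar next to it for reproducibility."""
    iio.imwrite(str(path), np.asarray(image, dtype=np.uint8))
    if scaling_meta is not None:
        Path(path).with_suffix(".json").write_text(
            json.dumps(scaling_meta, indent=2)
        )
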