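"""Plain-text raster and table I/O.

Rasters travel as ESRI ASCII grids (``.asc``): a six-line header followed by
whitespace-separated rows, north-up. Coordinates throughout the package are
projected kilometres; the grid origin is the lower-left corner and cells are
addressed (row, col) with row 0 at the top, matching numpy array order.
A layer stack is a directory of ``.asc`` files plus a ``stack.yml`` manifest.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import yaml

from .errors import InconsistentInputError

NODATA = -9999.0


def write_ascii_grid(path: str | os.PathLike, array: np.ndarray,
                     cell_size_km: float, xll_km: float = 0.0,
                     yll_km: float = 0.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid; NaN becomes the nodata code."""
    arr = np.asarray(array, dtype=float)
    if arr.ndim != 2:
        raise InconsistentInputError(f"expected a 2-D raster, got shape {arr.shape}")
    out = np.where(np.isnan(arr), NODATA, arr)
    header = (
        f"ncols {arr.shape[1]}\n"
        f"nrows {arr.shape[0]}\n"
        f"xllcorner {xll_km}\n"
        f"yllcorner {yll_km}\n"
        f"cellsize {cell_size_km}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: str | os.PathLike) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN.

    Returns ``(array, header)`` with header keys ncols/nrows/xllcorner/
    yllcorner/cellsize/nodata_value.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = np.asarray(data, dtype=float).reshape(nrows, ncols)
    nodata = header.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    return data, header


def save_stack(stack, directory: str | os.PathLike) -> Path:
    """Persist a LayerStack as a directory of .asc grids plus stack.yml."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "rows": int(stack.rows),
        "cols": int(stack.cols),
        "cell_km": float(stack.cell_km),
        "continuous": sorted(stack.continuous),
        "categorical": sorted(stack.categorical),
    }
    for name, arr in stack.continuous.items():
        write_ascii_grid(d / f"{name}.asc", arr, stack.cell_km)
    for name, arr in stack.categorical.items():
        write_ascii_grid(d / f"{name}.asc", arr.astype(float), stack.cell_km)
    write_ascii_grid(d / "validity.asc", stack.validity.astype(float), stack.cell_km)
    write_ascii_grid(d / "sampling.asc", stack.sampling.astype(float), stack.cell_km)
    with open(d / "stack.yml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return d


def load_stack(directory: str | os.PathLike):
    """Inverse of :func:`save_stack`."""
    from .landscape import LayerStack  # local import to avoid a cycle

    d = Path(directory)
    with open(d / "stack.yml") as fh:
        manifest = yaml.safe_load(fh)
    continuous = {}
    for name in manifest["continuous"]:
        arr, _ = read_ascii_grid(d / f"{name}.asc")
        continuous[name] = arr
    categorical = {}
    for name in manifest["categorical"]:
        arr, _ = read_ascii_grid(d / f"{name}.asc")
        categorical[name] = np.where(np.isnan(arr), -1, arr).astype(int)
    validity, _ = read_ascii_grid(d / "validity.asc")
    sampling, _ = read_ascii_grid(d / "sampling.asc")
    return LayerStack(
        rows=manifest["rows"], cols=manifest["cols"], cell_km=manifest["cell_km"],
        continuous=continuous, categorical=categorical,
        validity=validity == 1.0, sampling=sampling == 1.0,
    )
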