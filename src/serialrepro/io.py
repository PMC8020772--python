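"""Plain-text file formats with JSON sidecars.

Every on-disk object is a whitespace/CSV text file plus a small ``.json``
sidecar carrying grid shape and provenance, so round trips are lossless to
full float precision and a second write of a read file is byte-identical.

Formats
-------
DensityField   ``<path>``: whitespace matrix, ``<path>.json``: {shape, ndim}
ChainDataset   ``<path>``: CSV (chain_id, iteration, x[, y], is_dummy),
               ``<path>.json``: stimulus id, provenance, metadata
DPrimeMap      like DensityField plus radius/smoothing metadata
TwoAFCDataset  CSV (probe_x[, probe_y], condition, response) + sidecar
CAMParams      single JSON file
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chains import ChainDataset, ChainRecord
from .discrimination import DPrimeMap, TwoAFCDataset
from .estimators import CAMParams
from .grids import DensityField, Grid, normalize

__all__ = [
    "FormatError",
    "read_density",
    "write_density",
    "read_chains",
    "write_chains",
    "read_dprime_map",
    "write_dprime_map",
    "read_2afc",
    "write_2afc",
    "read_cam_params",
    "write_cam_params",
    "read_image",
]

_FLOAT_FMT = "%.17e"


class FormatError(ValueError):
    """A file does not match its expected schema."""


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_json(path) -> dict:
    try:
        with open(path) as fh:
            return json.load(fh)
    except FileNotFoundError as exc:
        raise FormatError(f"missing sidecar {path}") from exc


# -- DensityField -----------------------------------------------------------


def write_density(field: DensityField, path) -> None:
    np.savetxt(path, np.atleast_2d(field.as_array()), fmt=_FLOAT_FMT)
    _write_json(_sidecar(path), {"kind": "density", "shape": list(field.grid.shape)})


def read_density(path) -> DensityField:
    meta = _read_json(_sidecar(path))
    if meta.get("kind") != "density":
        raise FormatError(f"{path} sidecar is not a density field")
    grid = Grid(tuple(meta["shape"]))
    values = np.loadtxt(path).reshape(-1)
    if values.shape[0] != grid.n_cells:
        raise FormatError(f"{path}: {values.shape[0]} values for grid {grid.shape}")
    return normalize(values, grid)


# -- ChainDataset -----------------------------------------------------------


def write_chains(dataset: ChainDataset, path) -> None:
    rows = []
    coord_cols = ["x", "y"][: dataset.ndim]
    for c in dataset.chains:
        for t in range(c.n_iterations + 1):
            row = {"chain_id": c.chain_id, "iteration": t}
            row.update(dict(zip(coord_cols, c.points[t])))
            row["is_dummy"] = bool(c.is_dummy[t]) if c.is_dummy is not None else False
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    _write_json(
        _sidecar(path),
        {
            "kind": "chains",
            "stimulus_id": dataset.stimulus_id,
            "provenance": dataset.provenance,
            "ndim": dataset.ndim,
            "metadata": _jsonable(dataset.metadata),
        },
    )


def read_chains(path) -> ChainDataset:
    meta = _read_json(_sidecar(path))
    if meta.get("kind") != "chains":
        raise FormatError(f"{path} sidecar is not a chain dataset")
    df = pd.read_csv(path)
    coord_cols = ["x", "y"][: int(meta["ndim"])]
    for col in ("chain_id", "iteration", *coord_cols):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    chains = []
    for cid, grp in df.groupby("chain_id", sort=True):
        grp = grp.sort_values("iteration")
        iters = grp["iteration"].to_numpy()
        if not np.array_equal(iters, np.arange(len(iters))):
            raise FormatError(f"chain {cid}: iterations not contiguous from 0")
        chains.append(
            ChainRecord(
                chain_id=int(cid),
                points=grp[coord_cols].to_numpy(dtype=float),
                is_dummy=(
                    grp["is_dummy"].to_numpy(dtype=bool)
                    if "is_dummy" in grp.columns
                    else None
                ),
            )
        )
    return ChainDataset(
        chains=chains,
        stimulus_id=meta.get("stimulus_id", "unknown"),
        provenance=meta.get("provenance", "observed"),
        metadata=meta.get("metadata", {}),
    )


# -- DPrimeMap --------------------------------------------------------------


def write_dprime_map(dmap: DPrimeMap, path) -> None:
    np.savetxt(path, np.atleast_2d(dmap.as_array()), fmt=_FLOAT_FMT)
    _write_json(
        _sidecar(path),
        {
            "kind": "dprime_map",
            "shape": list(dmap.probe_grid.shape),
            "radius": dmap.radius,
            "kernel_sd": dmap.kernel_sd,
            "interpolated": dmap.interpolated,
        },
    )


def read_dprime_map(path) -> DPrimeMap:
    meta = _read_json(_sidecar(path))
    if meta.get("kind") != "dprime_map":
        raise FormatError(f"{path} sidecar is not a d-prime map")
    grid = Grid(tuple(meta["shape"]))
    values = np.loadtxt(path).reshape(-1)
    return DPrimeMap(
        grid,
        values,
        radius=meta.get("radius"),
        kernel_sd=meta.get("kernel_sd", 0.0),
        interpolated=meta.get("interpolated", False),
    )


# -- TwoAFCDataset ----------------------------------------------------------


def write_2afc(dataset: TwoAFCDataset, path) -> None:
    dataset.frame.to_csv(path, index=False)
    _write_json(
        _sidecar(path),
        {
            "kind": "twoafc",
            "radius": dataset.radius,
            "metadata": _jsonable(dataset.metadata),
        },
    )


def read_2afc(path) -> TwoAFCDataset:
    meta = _read_json(_sidecar(path))
    if meta.get("kind") != "twoafc":
        raise FormatError(f"{path} sidecar is not a 2AFC dataset")
    df = pd.read_csv(path)
    for col in ("probe_x", "condition", "response"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return TwoAFCDataset(
        frame=df, radius=float(meta["radius"]), metadata=meta.get("metadata", {})
    )


# -- CAMParams --------------------------------------------------------------


def write_cam_params(params: CAMParams, path, loss: float | None = None) -> None:
    obj = {
        "kind": "cam_params",
        "w": params.w,
        "c": params.c,
        "prototypes": params.prototypes.tolist(),
        "noise_sd": params.noise_sd,
    }
    if loss is not None:
        obj["loss"] = loss
    _write_json(path, obj)


def read_cam_params(path) -> CAMParams:
    obj = _read_json(path)
    if obj.get("kind") != "cam_params":
        raise FormatError(f"{path} is not a CAM parameter file")
    return CAMParams(
        w=float(obj["w"]),
        c=float(obj["c"]),
        prototypes=np.array(obj["prototypes"], dtype=float),
        noise_sd=float(obj.get("noise_sd", 0.0)),
    )


# -- images -----------------------------------------------------------------


def read_image(path) -> np.ndarray:
    """Grayscale PNG/PGM as a [0, 1] intensity raster."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float)
    return arr / 255.0


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if _is_plain(v)}
    return obj


def _is_plain(v) -> bool:
    return isinstance(v, (str, int, float, bool, type(None), list, dict))
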