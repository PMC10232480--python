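"""HDF5 containers for transient cubes and TIFF/CSV artifact output.

Layout of the cube container::

    /counts   uint32  (Ny, Nx, Nt[, Nc])   measured histograms, OR
    /flux     float64 (Ny, Nx, Nt[, Nc])   recovered / true flux
    /dt       scalar  seconds per bin
    /n_cycle  scalar  laser cycles (counts only)
    /laser/kind, /laser/fwhm or /laser/irf, /laser/dt
    /truth/...                             optional ground-truth group
    /meta     attrs                        config echo, seed, tool version

Round trips are exact: counts are stored losslessly as uint32 and flux as
float64.
"""

from __future__ import annotations

import json
from typing import Any

import h5py
import numpy as np

from .core import FluxCube, LaserPrior, TransientCube

__all__ = ["write_cube", "read_cube", "write_laser", "read_laser", "write_map"]

_FORMAT_VERSION = 1


def write_laser(group: h5py.Group, laser: LaserPrior) -> None:
    group.attrs["kind"] = laser.kind
    group.attrs["dt"] = laser.dt
    if laser.kind == "gaussian":
        group.attrs["fwhm"] = laser.fwhm
    else:
        group.create_dataset("irf", data=laser.irf)


def read_laser(group: h5py.Group) -> LaserPrior:
    kind = group.attrs["kind"]
    if kind == "gaussian":
        return LaserPrior("gaussian", dt=float(group.attrs["dt"]), fwhm=float(group.attrs["fwhm"]))
    return LaserPrior("tabulated", dt=float(group.attrs["dt"]), irf=group["irf"][()])


def write_cube(
    path,
    cube: TransientCube | FluxCube,
    laser: LaserPrior | None = None,
    truth: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a cube (and optional laser prior / ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.create_dataset("dt", data=cube.dt)
        if isinstance(cube, TransientCube):
            f.create_dataset("counts", data=cube.counts.astype(np.uint32))
            f.create_dataset("n_cycle", data=cube.n_cycle)
        else:
            f.create_dataset("flux", data=cube.flux.astype(np.float64))
        if laser is not None:
            write_laser(f.create_group("laser"), laser)
        if truth:
            g = f.create_group("truth")
            for k, v in truth.items():
                g.create_dataset(k, data=v)
        meta = f.create_group("meta")
        for k, v in cube.meta.items():
            try:
                meta.attrs[k] = v
            except TypeError:
                meta.attrs[k] = json.dumps(v, default=str)


def read_cube(path) -> dict[str, Any]:
    """Read a cube container; returns a dict with 'cube', 'laser', 'truth'.

    'cube' is a :class:`TransientCube` or :class:`FluxCube` depending on
    which dataset the file holds.  Missing required datasets raise a
    descriptive error naming the field.
    """
    with h5py.File(path, "r") as f:
        if "dt" not in f:
            raise KeyError("cube container missing required dataset '/dt'")
        dt = float(f["dt"][()])
        meta = dict(f["meta"].attrs) if "meta" in f else {}
        if "counts" in f:
            if "n_cycle" not in f:
                raise KeyError("cube container missing required dataset '/n_cycle'")
            cube: TransientCube | FluxCube = TransientCube(
                f["counts"][()].astype(np.int64), dt, int(f["n_cycle"][()]), meta=meta
            )
        elif "flux" in f:
            cube = FluxCube(f["flux"][()], dt, meta=meta)
        else:
            raise KeyError("cube container missing '/counts' or '/flux'")
        laser = read_laser(f["laser"]) if "laser" in f else None
        truth = {k: f["truth"][k][()] for k in f["truth"]} if "truth" in f else None
    return {"cube": cube, "laser": laser, "truth": truth}


def write_map(path, image: np.ndarray) -> None:
    """Write a 2D map as float32 TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
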