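"""File I/O: YAML configuration, TIFF stacks, volume/PSF containers.

On-disk conventions: 4D/5D data use axis order (u, v, z/t, y, x); multi-
slab volumes are one 32-bit TIFF per slab plus a JSON manifest recording
the grid; configurations round-trip through YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .config import OpticalConfig, ReconstructionOptions
from .errors import ContractError
from .grid import MultiscaleGrid, MultiscaleVolume, Slab

__all__ = [
    "load_config",
    "save_config",
    "read_stack",
    "write_stack",
    "write_volume",
    "read_volume",
    "write_psf",
    "read_psf",
]


# -- configuration ----------------------------------------------------------

def save_config(path, config: OpticalConfig, options: ReconstructionOptions | None = None) -> None:
    doc = {"optics": config.to_dict()}
    if options is not None:
        doc["reconstruction"] = options.to_dict()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path) -> tuple[OpticalConfig, ReconstructionOptions]:
    """Load and validate an optics + reconstruction configuration file."""
    p = Path(path)
    if not p.exists():
        raise ContractError(f"config file not found: {p}")
    doc = yaml.safe_load(p.read_text())
    if not isinstance(doc, dict) or "optics" not in doc:
        raise ContractError(f"{p} does not contain an 'optics' section")
    config = OpticalConfig.from_dict(doc["optics"])
    options = ReconstructionOptions.from_dict(doc.get("reconstruction", {}))
    return config, options


# -- TIFF stacks ------------------------------------------------------------

def write_stack(array: np.ndarray, path, metadata: dict | None = None) -> None:
    """Write an N-D stack as 32-bit float TIFF with JSON metadata in the
    image description."""
    arr = np.asarray(array)
    if arr.dtype not in (np.float32, np.float64, np.uint16):
        raise ContractError(f"unsupported dtype {arr.dtype}; use uint16 or float")
    desc = json.dumps({"axes_order": "uvzyx"[-arr.ndim:], **(metadata or {})})
    tifffile.imwrite(path, arr.astype(np.float32), description=desc, photometric="minisblack")


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack to float, recording the integer scale if promoted."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {"description": desc}
    if arr.dtype == np.uint16:
        meta["source_dtype"] = "uint16"
        meta["source_scale"] = 1.0
        arr = arr.astype(np.float64)
    else:
        arr = arr.astype(np.float64)
    return arr, meta


# -- multiscale volumes -----------------------------------------------------

def _grid_to_dict(grid: MultiscaleGrid) -> dict:
    return {
        "lens_pitch_sample": grid.lens_pitch_sample,
        "num_lenses": list(grid.num_lenses),
        "slabs": [
            {
                "z_start": s.z_start,
                "z_end": s.z_end,
                "axial_step": s.axial_step,
                "lateral_step": s.lateral_step,
                "lateral_shape": list(s.lateral_shape),
            }
            for s in grid.slabs
        ],
    }


def _grid_from_dict(d: dict) -> MultiscaleGrid:
    slabs = tuple(
        Slab(
            s["z_start"], s["z_end"], s["axial_step"], s["lateral_step"],
            tuple(s["lateral_shape"]),
        )
        for s in d["slabs"]
    )
    return MultiscaleGrid(
        slabs=slabs,
        lens_pitch_sample=d["lens_pitch_sample"],
        num_lenses=tuple(d["num_lenses"]),
    )


def write_volume(volume: MultiscaleVolume, out_dir) -> None:
    """One float32 TIFF per slab plus manifest.json describing the grid."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"grid": _grid_to_dict(volume.grid), "slab_files": [], "axes_order": "zyx"}
    for i, data in enumerate(volume.slab_data):
        name = f"slab_{i:02d}.tif"
        tifffile.imwrite(out / name, data.astype(np.float32), photometric="minisblack")
        manifest["slab_files"].append(name)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_volume(in_dir) -> MultiscaleVolume:
    p = Path(in_dir)
    manifest = json.loads((p / "manifest.json").read_text())
    grid = _grid_from_dict(manifest["grid"])
    data = [tifffile.imread(p / name).astype(np.float64) for name in manifest["slab_files"]]
    data = [np.atleast_3d(d.reshape(s.shape)) for d, s in zip(data, grid.slabs)]
    return MultiscaleVolume(grid, data)


# -- phase-space PSFs -------------------------------------------------------

def write_psf(psf, path) -> None:
    """Persist a PhaseSpacePSF to an HDF5 container with config metadata."""
    import h5py

    from .psf import PhaseSpacePSF  # noqa: F401 (type documented)

    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(psf.config.to_dict())
        f.attrs["angular_bins"] = -1 if psf.angular_bins is None else psf.angular_bins
        f.create_dataset("depth_list", data=psf.depth_list)
        f.create_dataset("lateral_factors", data=np.asarray(psf.lateral_factors))
        g = f.create_group("kernels")
        for i, k in enumerate(psf.kernels):
            g.create_dataset(f"{i:04d}", data=k.astype(np.float32))


def read_psf(path):
    import h5py

    from .psf import PhaseSpacePSF

    with h5py.File(path, "r") as f:
        config = OpticalConfig.from_dict(json.loads(f.attrs["config"]))
        ab = int(f.attrs["angular_bins"])
        depth_list = f["depth_list"][()]
        factors = [int(x) for x in f["lateral_factors"][()]]
        kernels = [
            f["kernels"][k][()].astype(np.float64) for k in sorted(f["kernels"])
        ]
    return PhaseSpacePSF(
        config=config,
        depth_list=depth_list,
        kernels=kernels,
        lateral_factors=factors,
        angular_bins=None if ab < 0 else ab,
    )
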