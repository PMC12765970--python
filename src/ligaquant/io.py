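"""File formats: hyperspectral cubes as HDF5, orientation images as
multi-page 32-bit TIFF, tables as CSV.

HDF5 layout: ``/wavenumbers``, ``/absorbance`` (rows x cols x n),
``/mask``, ``/pixel_step_um``; phantom ground truth, when present, under
``/truth`` (``band_areas`` as attribute pairs, ``mask``, ``jitter``).
TIFF layout: page 0 azimuth (degrees), page 1 retardance (a.u.); the
pixel size and longitudinal axis angle travel in a JSON image
description.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .ftir_preprocess import HyperspectralCube
from .qplm_crimp import OrientationImage

__all__ = [
    "write_cube",
    "read_cube",
    "read_cube_truth",
    "write_orientation",
    "read_orientation",
    "write_chemical_image",
    "render_chemical_image",
    "load_reference_csv",
]


def write_cube(
    path: str | Path, cube: HyperspectralCube, truth=None
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("wavenumbers", data=cube.wavenumbers)
        f.create_dataset("absorbance", data=cube.absorbance.astype(np.float32))
        if cube.mask is not None:
            f.create_dataset("mask", data=cube.mask)
        f.create_dataset("pixel_step_um", data=cube.pixel_step)
        if truth is not None:
            g = f.create_group("truth")
            for name, area in truth.band_areas.items():
                g.attrs[name] = area
            g.create_dataset("mask", data=np.asarray(truth.mask))
            g.create_dataset("jitter", data=np.asarray(truth.jitter, np.float32))


def read_cube(path: str | Path) -> HyperspectralCube:
    with h5py.File(path, "r") as f:
        return HyperspectralCube(
            wavenumbers=f["wavenumbers"][()],
            absorbance=f["absorbance"][()].astype(float),
            pixel_step=float(f["pixel_step_um"][()]),
            mask=f["mask"][()] if "mask" in f else None,
        )


def read_cube_truth(path: str | Path) -> dict[str, float]:
    """Ground-truth band areas stored with a phantom cube."""
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            raise KeyError(f"{path} holds no ground truth")
        return dict(f["truth"].attrs)


def write_orientation(path: str | Path, image: OrientationImage) -> None:
    meta = {
        "pixel_size_um": image.pixel_size,
        "longitudinal_axis_angle_deg": image.longitudinal_axis_angle,
    }
    pages = [image.azimuth.astype(np.float32)]
    if image.retardance is not None:
        pages.append(image.retardance.astype(np.float32))
    tifffile.imwrite(path, np.stack(pages), description=json.dumps(meta))


def read_orientation(path: str | Path) -> OrientationImage:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if pages.ndim == 2:
        azimuth, retardance = pages, None
    else:
        azimuth = pages[0]
        retardance = pages[1] if pages.shape[0] > 1 else None
    return OrientationImage(
        azimuth=azimuth.astype(float),
        retardance=None if retardance is None else retardance.astype(float),
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        longitudinal_axis_angle=float(meta.get("longitudinal_axis_angle_deg", 0.0)),
    )


def write_chemical_image(path: str | Path, image) -> None:
    """Save a per-pixel band-integral raster as 32-bit TIFF (background
    pixels NaN)."""
    tifffile.imwrite(
        path,
        image.values.astype(np.float32),
        description=json.dumps({"band": image.band.name}),
    )


def render_chemical_image(path: str | Path, image, cmap: str = "inferno") -> None:
    """Pseudo-colour rendering of a chemical image (documentation aid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(image.values, cmap=cmap)
    ax.set_title(f"{image.band.name} AUC")
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.8, label="a.u. cm$^{-1}$")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def load_reference_csv(path: str | Path, axis: np.ndarray) -> np.ndarray:
    """Load a reference spectrum from a two-column CSV (wavenumber,
    absorbance) and interpolate it onto the working axis."""
    import pandas as pd

    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ValueError("reference CSV needs wavenumber and absorbance columns")
    nu = table.iloc[:, 0].to_numpy(float)
    ab = table.iloc[:, 1].to_numpy(float)
    order = np.argsort(nu)
    return np.interp(np.asarray(axis, float), nu[order], ab[order])
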