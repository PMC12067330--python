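"""Loading and saving of images, stacks and calibration artifacts."""

from __future__ import annotations

import os

import numpy as np


def load_image(path) -> np.ndarray:
    """Load a 2-D grayscale image (TIFF via tifffile, else Pillow) as float."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile
        img = tifffile.imread(path)
    else:
        from PIL import Image
        img = np.asarray(Image.open(path).convert("F"))
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{path}: image contains NaN/Inf")
    return img


def save_image(path, image: np.ndarray, dtype=None) -> None:
    """Save an image, rounding to the requested integer dtype if given."""
    path = os.fspath(path)
    arr = np.asarray(image)
    if dtype is not None:
        info = np.iinfo(dtype) if np.issubdtype(np.dtype(dtype), np.integer) else None
        if info is not None:
            arr = np.clip(np.rint(arr), info.min, info.max)
        arr = arr.astype(dtype)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, arr)
    else:
        from PIL import Image
        if arr.dtype.kind == "f":
            lo, hi = float(arr.min()), float(arr.max())
            scale = 255.0 / (hi - lo) if hi > lo else 1.0
            arr = ((arr - lo) * scale).astype(np.uint8)
        Image.fromarray(arr).save(path)


def load_stack(path, dataset: str | None = None):
    """Open a projection stack: multi-page TIFF or an HDF5 dataset path.

    HDF5 datasets are returned unread (sliceable), so sinogram generation
    touches only the row band it needs.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5", ".nxs"):
        import h5py
        f = h5py.File(path, "r")
        if dataset is None:
            raise ValueError("HDF5 stack needs a dataset path")
        return f[dataset]
    import tifffile
    return tifffile.imread(path)
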