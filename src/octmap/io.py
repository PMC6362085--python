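"""Reading and writing images and tabular artifacts.

Images are 8/16-bit grayscale PNG or TIFF; the physical pixel spacing is
not stored in these formats, so it is supplied by the caller (config or a
per-dataset metadata CSV with columns ``image_id, px_mm_x, px_mm_y``).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .types import AlignedImage, GrayImage

IMAGE_EXTS = (".png", ".tif", ".tiff")


def read_gray_image(path, px_mm_x: float, px_mm_y: float) -> GrayImage:
    """Read a grayscale PNG/TIFF; integer intensities are scaled to [0, 1]."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]   # drop color channels of nominally-gray files
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / float(np.iinfo(arr.dtype).max)
    else:
        arr = arr.astype(float)
    return GrayImage(arr, px_mm_x=px_mm_x, px_mm_y=px_mm_y, image_id=path.stem)


def write_png16(path, pixels: np.ndarray) -> None:
    """Write a [0, 1] image as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))


def write_tiff16(path, pixels: np.ndarray) -> None:
    """Write a [0, 1] image as 16-bit grayscale TIFF."""
    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    tifffile.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))


def list_images(directory) -> list[Path]:
    directory = Path(directory)
    return sorted(p for p in directory.iterdir()
                  if p.suffix.lower() in IMAGE_EXTS)


def read_image_dir(directory, px_mm_x: float, px_mm_y: float,
                   metadata_csv=None) -> list[GrayImage]:
    """Read all PNG/TIFF images in a directory, sorted by filename.

    ``metadata_csv`` (columns image_id, px_mm_x, px_mm_y) overrides the
    default spacing per image.
    """
    spacing = {}
    if metadata_csv is not None:
        meta = pd.read_csv(metadata_csv)
        spacing = {str(r.image_id): (float(r.px_mm_x), float(r.px_mm_y))
                   for r in meta.itertuples()}
    paths = list_images(directory)
    if not paths:
        raise FileNotFoundError(f"no PNG/TIFF images found in {directory}")
    out = []
    for p in paths:
        sx, sy = spacing.get(p.stem, (px_mm_x, px_mm_y))
        out.append(read_gray_image(p, sx, sy))
    return out


def read_aligned_dir(directory, px_mm: float) -> list[AlignedImage]:
    """Read pre-aligned canvases (as written by ``preprocess run``)."""
    paths = list_images(directory)
    if not paths:
        raise FileNotFoundError(f"no canvases found in {directory}")
    out = []
    for p in paths:
        g = read_gray_image(p, px_mm, px_mm)
        out.append(AlignedImage(canvas=g.pixels, px_mm=px_mm, source_id=p.stem))
    return out
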