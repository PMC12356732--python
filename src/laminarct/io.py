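"""File I/O: contour CSVs, slice images (TIFF / NIfTI), and result tables.

Contour CSV layout: comment header lines record the pixel size and the
coordinate convention, followed by columns
``slice_id, border, point_index, x_px, y_px`` with ``border`` one of
``sup`` / ``deep``.  Coordinates are pixel-centered and 0-based.
"""

from __future__ import annotations

import os
from typing import Dict

import numpy as np
import pandas as pd

from .laminar import BoundaryPair

__all__ = ["write_contours", "read_contours", "write_image", "read_image",
           "write_table"]

_COORD_NOTE = "pixel-centered,0-based"


def write_contours(path, boundaries_by_slice: Dict[str, BoundaryPair]) -> None:
    """Write one or more slices' boundary pairs to a contour CSV."""
    pixel_mm = {b.pixel_mm for b in boundaries_by_slice.values()}
    if len(pixel_mm) != 1:
        raise ValueError("all slices in one contour file must share pixel_mm")
    rows = []
    for slice_id, b in boundaries_by_slice.items():
        for border, pts in (("sup", b.superficial), ("deep", b.deep)):
            for i, (x, y) in enumerate(pts):
                rows.append((slice_id, border, i, x, y))
    df = pd.DataFrame(rows, columns=["slice_id", "border", "point_index",
                                     "x_px", "y_px"])
    with open(path, "w", newline="") as fh:
        fh.write(f"# pixel_mm={pixel_mm.pop()!r}\n")
        fh.write(f"# coords={_COORD_NOTE}\n")
        df.to_csv(fh, index=False)


def read_contours(path) -> Dict[str, BoundaryPair]:
    """Read a contour CSV back into per-slice boundary pairs."""
    pixel_mm = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "pixel_mm":
                pixel_mm = float(val)
    if pixel_mm is None:
        raise ValueError(f"{path}: missing '# pixel_mm=' header line")
    df = pd.read_csv(path, comment="#")
    out = {}
    for slice_id, g in df.groupby("slice_id", sort=False):
        sup = g[g.border == "sup"].sort_values("point_index")[["x_px", "y_px"]]
        deep = g[g.border == "deep"].sort_values("point_index")[["x_px", "y_px"]]
        out[str(slice_id)] = BoundaryPair(sup.to_numpy(float),
                                          deep.to_numpy(float), pixel_mm)
    return out


def write_image(path, raster: np.ndarray, pixel_mm: float) -> None:
    """Write a slice raster as 16-bit TIFF (.tif) or single-slice NIfTI (.nii)."""
    path = os.fspath(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile
        lo, hi = float(raster.min()), float(raster.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        data = np.round((raster - lo) * scale).astype(np.uint16)
        tifffile.imwrite(path, data, resolution=(1.0 / pixel_mm, 1.0 / pixel_mm),
                         metadata={"pixel_mm": pixel_mm, "offset": lo,
                                   "scale": scale})
    elif path.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        affine = np.diag([pixel_mm, pixel_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(raster, dtype=np.float32), affine),
                 path)
    else:
        raise ValueError(f"unsupported image extension: {path}")


def read_image(path):
    """Read a slice raster written by :func:`write_image`.

    Returns (raster, pixel_mm).  TIFF rasters are returned on their stored
    16-bit scale (the laminar analysis is invariant to affine intensity
    changes, so no rescaling is attempted without metadata).
    """
    path = os.fspath(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            raster = page.asarray().astype(float)
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        pixel_mm = float(meta.get("pixel_mm", 1.0))
        if "scale" in meta:
            raster = raster / float(meta["scale"]) + float(meta.get("offset", 0.0))
        return raster, pixel_mm
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        img = nib.load(path)
        raster = np.asarray(img.dataobj, dtype=float)
        if raster.ndim == 3 and raster.shape[2] == 1:
            raster = raster[:, :, 0]
        return raster, float(img.header.get_zooms()[0])
    raise ValueError(f"unsupported image extension: {path}")


def write_table(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """RFC-4180 CSV with explicit header; floats at 6 significant digits.

    ``meta`` entries (seed, config hash, ...) are recorded as leading
    comment lines.
    """
    with open(path, "w", newline="") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format="%.6g")
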