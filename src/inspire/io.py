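"""File I/O: images (PNG/TIFF 2-D, NIfTI 3-D), landmarks (CSV), run logs."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np


def read_image(path):
    """Read a 2-D image (PNG/TIFF) or 3-D volume (NIfTI) as float64."""
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    if suffix.endswith((".tif", ".tiff")):
        import tifffile

        return np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    from PIL import Image

    return np.asarray(Image.open(path), dtype=np.float64)


def write_image(path, array):
    """Write an array as TIFF (2-D, float preserved) or NIfTI (3-D)."""
    path = Path(path)
    arr = np.asarray(array)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(arr.astype(np.float32), np.eye(4)), str(path))
    elif suffix.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), arr.astype(np.float32))
    else:
        from PIL import Image

        a = arr.astype(np.float64)
        rng = a.max() - a.min()
        a8 = ((a - a.min()) / rng * 255).astype(np.uint8) if rng > 0 else np.zeros_like(a, np.uint8)
        Image.fromarray(a8).save(path)


def read_landmarks(path) -> np.ndarray:
    """Landmarks CSV: one point per row, physical coordinates."""
    return np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=np.float64))


def write_landmarks(path, points):
    np.savetxt(path, np.atleast_2d(points), delimiter=",", fmt="%.9g")


def write_trace(path, traces):
    """Write the per-iteration objective log of all stages as CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["level", "iteration", "J", "d_ab", "d_ba", "iic_ab", "iic_ba"])
        for li, trace in enumerate(traces):
            for it, (j, comps) in enumerate(zip(trace.J, trace.components)):
                w.writerow([li, it, j, *comps])
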