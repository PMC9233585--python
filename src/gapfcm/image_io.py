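"""Raster image input/output and flattening to feature matrices.

The clustering operates on an m x b feature matrix; for plain grayscale
segmentation b = 1 and row k holds the intensity of pixel k in row-major
order.  PNG and TIFF go through imageio/tifffile, single-slice MRI
volumes through nibabel (NIfTI-1).  Intensities are kept as floats
internally regardless of storage depth.
"""

from __future__ import annotations

import os

import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "image_to_features",
    "features_to_image",
    "labels_to_image",
    "write_labels",
]

# ITU-R BT.709 luminance weights, applied on stored values without rescaling
_LUMA = np.array([0.2125, 0.7154, 0.0721])

_NIFTI_EXT = (".nii", ".nii.gz")


def _is_nifti(path: str) -> bool:
    p = str(path).lower()
    return p.endswith(_NIFTI_EXT)


def read_image(path, fmt: str | None = None) -> np.ndarray:
    """Read a 2-D grayscale image as a float array.

    ``fmt`` overrides extension-based detection ("png", "tiff",
    "nifti").  Multi-channel rasters are converted to luminance; NIfTI
    singleton dimensions are squeezed.  More than two non-singleton
    dimensions is an error.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such image file: {path}")
    use_nifti = fmt == "nifti" or (fmt is None and _is_nifti(path))
    try:
        if use_nifti:
            import nibabel as nib

            arr = np.asanyarray(nib.load(path).dataobj)
        else:
            import imageio.v3 as iio

            arr = np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 — re-raise with the offending path
        raise IOError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if not use_nifti and arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3] @ _LUMA
    arr = np.squeeze(arr)
    if arr.ndim == 0:
        arr = arr.reshape(1, 1)
    elif arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a 2-D image, got {arr.ndim} non-singleton dimensions"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: image contains non-finite intensities")
    return arr


def write_image(path, image: np.ndarray) -> None:
    """Write a 2-D image; PNG as 8-bit, TIFF preserving float values."""
    path = os.fspath(path)
    image = np.asarray(image)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, image.astype(np.float32))
    else:
        import imageio.v3 as iio

        out = np.clip(np.rint(image), 0, 255).astype(np.uint8)
        iio.imwrite(path, out)


def image_to_features(image: np.ndarray, normalize: bool = False) -> np.ndarray:
    """Flatten an H x W image into an (H*W) x 1 feature matrix.

    Row-major pixel order; with ``normalize`` intensities are mapped
    linearly onto [0, 1] (a constant image maps to all zeros).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    feats = image.reshape(-1, 1).copy()
    if normalize:
        lo, hi = feats.min(), feats.max()
        if hi > lo:
            feats = (feats - lo) / (hi - lo)
        else:
            feats = np.zeros_like(feats)
    return feats


def features_to_image(features: np.ndarray, height: int, width: int) -> np.ndarray:
    """Inverse of `image_to_features` (without normalization)."""
    features = np.asarray(features, dtype=float)
    if features.shape != (height * width, 1):
        raise ValueError("feature matrix does not match the image geometry")
    return features.reshape(height, width)


def labels_to_image(labels: np.ndarray, n_clusters: int) -> np.ndarray:
    """Render a label map as an 8-bit grayscale image.

    Label i maps to intensity round(255 * i / (x - 1)); a single class
    renders all black.
    """
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_clusters:
        raise ValueError("labels must lie in [0, n_clusters)")
    if n_clusters == 1:
        return np.zeros(labels.shape, dtype=np.uint8)
    scaled = np.floor(255.0 * labels / (n_clusters - 1) + 0.5)
    return scaled.astype(np.uint8)


def write_labels(path, labels: np.ndarray, n_clusters: int) -> None:
    """Write a label map as an 8-bit grayscale PNG."""
    write_image(path, labels_to_image(labels, n_clusters))
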