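"""Imaging data model, NIfTI round-trips, and per-voxel signal conditioning.

The data model is deliberately small: a 4D BOLD volume with its repetition
time and affine, boolean masks, and integer label atlases, all required to
live on exactly the same voxel grid (no resampling is performed anywhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import signal

from .errors import DataError, GeometryError

__all__ = [
    "BoldImage",
    "BinaryMask",
    "LabelAtlas",
    "load_bold",
    "load_mask",
    "load_atlas",
    "save_bold",
    "save_volume",
    "preprocess",
    "extract_reference",
]


def _check_affine(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {a.shape}")
    return a


@dataclass
class BoldImage:
    """A 4D (X, Y, Z, T) BOLD volume with repetition time and affine."""

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if not np.isfinite(self.data).all():
            raise DataError("BOLD data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        self.affine = _check_affine(self.affine)

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass
class BinaryMask:
    """3D boolean mask on the BOLD grid."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0.5
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.data.ndim}D")
        self.affine = _check_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelAtlas:
    """3D non-negative integer label volume; 0 is background."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"atlas must be 3D, got {arr.ndim}D")
        self.data = np.rint(arr).astype(np.int32)
        if (self.data < 0).any():
            raise ValueError("atlas labels must be non-negative")
        self.affine = _check_affine(self.affine)

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.data)
        return lab[lab > 0]

    @property
    def analysis_mask(self) -> np.ndarray:
        return self.data > 0


def _check_grid(shape, affine, ref_shape, ref_affine, what: str) -> None:
    if tuple(shape) != tuple(ref_shape):
        raise GeometryError(
            f"{what} grid {tuple(shape)} does not match reference grid {tuple(ref_shape)}"
        )
    if not np.allclose(affine, ref_affine, atol=1e-4):
        raise GeometryError(f"{what} affine does not match reference affine")


def load_bold(path, tr_seconds: float | None = None) -> BoldImage:
    """Load a 4D NIfTI; TR is taken from the header unless overridden."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj, dtype=float)
    if arr.ndim != 4:
        raise DataError(f"expected a 4D BOLD volume, got {arr.ndim}D: {path}")
    if not np.isfinite(arr).all():
        raise DataError(f"non-finite voxels in {path}")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr_seconds <= 0:
            raise DataError(f"no usable TR in header of {path}; pass tr_seconds")
    return BoldImage(arr, tr_seconds, img.affine)


def load_mask(path, reference: BoldImage | None = None) -> BinaryMask:
    """Load a 3D mask NIfTI, binarized at > 0.5, grid-checked if a reference is given."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj, dtype=float)
    if arr.ndim != 3:
        raise DataError(f"expected a 3D mask volume, got {arr.ndim}D: {path}")
    if not np.isfinite(arr).all():
        raise DataError(f"non-finite voxels in {path}")
    if reference is not None:
        _check_grid(arr.shape, img.affine, reference.shape3d, reference.affine, "mask")
    return BinaryMask(arr, img.affine)


def load_atlas(path, reference: BoldImage | None = None) -> LabelAtlas:
    """Load a 3D label atlas NIfTI, values rounded to the nearest integer."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj, dtype=float)
    if arr.ndim != 3:
        raise DataError(f"expected a 3D atlas volume, got {arr.ndim}D: {path}")
    if not np.isfinite(arr).all():
        raise DataError(f"non-finite voxels in {path}")
    if reference is not None:
        _check_grid(arr.shape, img.affine, reference.shape3d, reference.affine, "atlas")
    return LabelAtlas(arr, img.affine)


def save_bold(bold: BoldImage, path) -> None:
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], bold.tr_seconds))
    nib.save(img, str(path))


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Save a 3D scalar volume (maps, masks, atlases)."""
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def preprocess(bold: BoldImage, band: tuple[float, float] = (0.01, 0.08)) -> BoldImage:
    """Linearly detrend then zero-phase band-pass filter every voxel series.

    The band must satisfy 0 <= low < high < Nyquist. A second-order
    Butterworth applied forward-backward (zero phase) is used so that the
    filter introduces no temporal delay that would bias lag estimation.
    With low == 0 the filter degenerates to a low-pass.
    """
    low, high = band
    nyq = bold.nyquist_hz
    if not (0 <= low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 <= low < high < Nyquist={nyq:.4f}"
        )
    if low > 0:
        sos = signal.butter(2, [low, high], btype="bandpass", fs=1.0 / bold.tr_seconds,
                            output="sos")
    else:
        sos = signal.butter(2, high, btype="lowpass", fs=1.0 / bold.tr_seconds,
                            output="sos")
    out = signal.detrend(bold.data, axis=-1, type="linear")
    out = signal.sosfiltfilt(sos, out, axis=-1)
    out = out - out.mean(axis=-1, keepdims=True)
    return BoldImage(out, bold.tr_seconds, bold.affine)


def extract_reference(bold: BoldImage, venous_mask: BinaryMask) -> np.ndarray:
    """Mean time series over the venous-mask voxels (the temporal anchor)."""
    _check_grid(venous_mask.data.shape, venous_mask.affine,
                bold.shape3d, bold.affine, "venous mask")
    if venous_mask.n_voxels == 0:
        raise ValueError("venous mask is empty")
    return bold.data[venous_mask.data].mean(axis=0)
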