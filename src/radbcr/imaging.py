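"""Volume/mask I/O and gray-level discretization for texture analysis.

Images are 3-D scalar fields (T2-weighted or ADC) stored as NIfTI; the
tumor region of interest (ROI) is a binary mask on the same voxel grid.
Texture matrices operate on gray levels, so ROI intensities are quantized
either to a fixed number of bins (min-max normalised per lesion) or to
bins of fixed width anchored at the ROI minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "ROIMask",
    "DiscretizationScheme",
    "DiscretizedROI",
    "LoadError",
    "load_volume",
    "load_mask",
    "save_volume",
    "masked_intensities",
    "discretize",
]


class LoadError(ValueError):
    """Raised when a NIfTI file cannot be used as an image or mask."""


@dataclass
class ImageVolume:
    """A 3-D scalar image with voxel spacing in millimetres."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    identifier: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise LoadError(
                f"volume {self.identifier!r} must be 3-D, got {self.data.ndim}-D"
            )
        if np.isnan(self.data).any():
            raise LoadError(f"volume {self.identifier!r} contains NaN voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise LoadError(
                f"volume {self.identifier!r} has invalid spacing {self.spacing}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class ROIMask:
    """Binary tumor mask aligned with its parent volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        if self.data.ndim != 3:
            raise LoadError(f"mask must be 3-D, got {self.data.ndim}-D")
        if not self.data.any():
            raise LoadError("mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class DiscretizationScheme:
    """Gray-level quantization rule.

    method
        ``"fixed-bin-number"`` — ``parameter`` is the bin count G (int >= 2);
        intensities are min-max scaled inside the ROI before binning.
    method
        ``"fixed-bin-size"`` — ``parameter`` is the bin width (> 0); bins are
        anchored at the ROI minimum.
    """

    method: str
    parameter: float

    def __post_init__(self) -> None:
        if self.method == "fixed-bin-number":
            if int(self.parameter) != self.parameter or self.parameter < 2:
                raise ValueError("fixed-bin-number needs an integer bin count >= 2")
        elif self.method == "fixed-bin-size":
            if self.parameter <= 0:
                raise ValueError("fixed-bin-size needs a bin width > 0")
        else:
            raise ValueError(f"unknown discretization method {self.method!r}")

    @property
    def label(self) -> str:
        if self.method == "fixed-bin-number":
            return f"FBN{int(self.parameter)}"
        return f"FBS{self.parameter:g}"

    @classmethod
    def fbn(cls, n_bins: int) -> "DiscretizationScheme":
        return cls("fixed-bin-number", int(n_bins))

    @classmethod
    def fbs(cls, width: float) -> "DiscretizationScheme":
        return cls("fixed-bin-size", float(width))


@dataclass
class DiscretizedROI:
    """ROI quantized to integer gray levels; 0 marks background.

    ``levels`` holds 1..G inside the ROI and 0 outside; ``n_levels`` is the
    nominal level count G of the scheme (some levels may be unoccupied).
    """

    levels: np.ndarray
    n_levels: int
    scheme: DiscretizationScheme
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())


def load_volume(path: str | Path, identifier: str | None = None) -> ImageVolume:
    """Read a 3-D NIfTI image; spacing comes from the header zooms.

    Rejects non-3-D data and NaN voxels with a :class:`LoadError` naming
    the file.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise LoadError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise LoadError(f"{path}: expected 3-D data, got shape {data.shape}")
    if np.isnan(data).any():
        raise LoadError(f"{path}: contains NaN voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data, spacing, identifier or path.name)


def load_mask(path: str | Path) -> ROIMask:
    """Read a binary ROI mask from NIfTI (any non-zero voxel is foreground)."""
    vol = load_volume(path)
    values = np.unique(vol.data)
    if not np.all(np.isin(values, (0.0, 1.0))):
        raise LoadError(f"{path}: mask voxels must be 0/1, found {values[:5]}")
    return ROIMask(vol.data)


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume (or 0/1 mask array wrapped as a volume) to NIfTI."""
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.data, affine), str(path))


def masked_intensities(volume: ImageVolume, mask: ROIMask) -> np.ndarray:
    """Intensities at foreground voxels, first array axis varying fastest."""
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )
    flat = volume.data.ravel(order="F")
    sel = mask.data.ravel(order="F")
    return flat[sel]


def discretize(
    volume: ImageVolume, mask: ROIMask, scheme: DiscretizationScheme
) -> DiscretizedROI:
    """Quantize ROI intensities to integer gray levels.

    Fixed bin number: ``level = min(G, floor(G*(x - min)/(max - min)) + 1)``;
    a constant ROI maps entirely to level 1.  Fixed bin size:
    ``level = floor((x - min)/width) + 1``.  Min/max are computed on ROI
    voxels only.
    """
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )
    m = mask.data
    vals = volume.data[m]
    lo = vals.min()
    hi = vals.max()
    levels = np.zeros(volume.shape, dtype=np.int32)
    if scheme.method == "fixed-bin-number":
        g = int(scheme.parameter)
        if hi == lo:
            levels[m] = 1
            n_levels = g
        else:
            lv = np.floor(g * (vals - lo) / (hi - lo)).astype(np.int32) + 1
            np.minimum(lv, g, out=lv)
            levels[m] = lv
            n_levels = g
    else:
        width = float(scheme.parameter)
        lv = np.floor((vals - lo) / width).astype(np.int32) + 1
        levels[m] = lv
        n_levels = int(lv.max())
    return DiscretizedROI(levels, n_levels, scheme, volume.spacing)
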