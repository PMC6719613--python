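"""Undecimated 3-D wavelet sub-band filtering.

One pass of the coiflet-1 low-pass (L) and high-pass (H) decomposition
filters is applied along each of the three array axes, without
down-sampling (stationary / a-trous transform), producing the eight
sub-bands LLL, LLH, LHL, LHH, HLL, HLH, HHL, HHH on the original voxel
grid.  Together with the untouched original image that gives nine aligned
images per sequence, so the tumor mask applies to every sub-band
unchanged.

Label convention: the first letter names the filter applied along the
first array axis, the second letter the second axis, and so on.  Boundary
handling is whole-sample symmetric (mirror) padding.  Filtering is
separable, so the axis order does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pywt
from scipy import ndimage

from .imaging import ImageVolume, save_volume

__all__ = ["SUBBAND_LABELS", "WaveletBank", "decompose", "filter_kernels"]

#: The nine aligned images derived from one volume.
SUBBAND_LABELS: tuple[str, ...] = (
    "ORIG",
    "LLL",
    "LLH",
    "LHL",
    "LHH",
    "HLL",
    "HLH",
    "HHL",
    "HHH",
)


def filter_kernels(wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Decomposition filter taps: ``{"L": low-pass, "H": high-pass}``."""
    w = pywt.Wavelet(wavelet)
    return {"L": np.asarray(w.dec_lo), "H": np.asarray(w.dec_hi)}


@dataclass
class WaveletBank:
    """The original image plus its eight single-level sub-bands."""

    images: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(SUBBAND_LABELS) - set(self.images)
        if missing or len(self.images) != len(SUBBAND_LABELS):
            raise ValueError(f"bank must hold exactly {SUBBAND_LABELS}, missing {missing}")
        shapes = {img.shape for img in self.images.values()}
        if len(shapes) != 1:
            raise ValueError(f"sub-band shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.images["ORIG"].shape

    def __getitem__(self, label: str) -> np.ndarray:
        return self.images[label]

    def export_niftis(self, base: str | Path, spacing) -> list[Path]:
        """Debug export of every sub-band as ``<base>_<LABEL>.nii.gz``."""
        base = Path(base)
        out = []
        for label, img in self.images.items():
            path = base.parent / f"{base.name}_{label}.nii.gz"
            save_volume(ImageVolume(img, spacing, label), path)
            out.append(path)
        return out


def _filter_axis(data: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    # convolve1d with mode="reflect" implements whole-sample symmetric
    # (mirror) padding: ... d c b a | a b c d ...
    return ndimage.convolve1d(data, taps, axis=axis, mode="reflect")


def decompose(volume: ImageVolume | np.ndarray, wavelet: str = "coif1") -> WaveletBank:
    """Produce the nine aligned images for one volume.

    Volumes smaller than the filter length (6 taps for coiflet-1) along any
    axis are symmetrically padded before filtering and cropped back, so the
    output always matches the input shape.
    """
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume, float)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D input, got {data.ndim}-D")
    kernels = filter_kernels(wavelet)
    ntaps = len(kernels["L"])

    pad = [(0, 0)] * 3
    needs_pad = False
    for ax in range(3):
        if data.shape[ax] < ntaps:
            extra = ntaps - data.shape[ax]
            pad[ax] = ((extra + 1) // 2, extra // 2)
            needs_pad = True
    work = np.pad(data, pad, mode="symmetric") if needs_pad else data

    images: dict[str, np.ndarray] = {"ORIG": data.copy()}
    for combo in product("LH", repeat=3):
        sub = work
        for ax, letter in enumerate(combo):
            sub = _filter_axis(sub, kernels[letter], axis=ax)
        if needs_pad:
            sl = tuple(
                slice(p[0], p[0] + data.shape[ax]) for ax, p in enumerate(pad)
            )
            sub = sub[sl]
        images["".join(combo)] = sub
    return WaveletBank(images)
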