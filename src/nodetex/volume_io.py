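"""Volume / mask I/O and grey-level normalization.

Images are 3D arrays indexed ``(row, col, slice)``: texture is computed
in-plane on ``voxels[:, :, k]`` and pooled across slices. On disk,
volumes and masks are NIfTI files (``.nii`` / ``.nii.gz``); a mask is
any integer or byte volume where nonzero marks in-ROI voxels.

Before any feature computation the ROI is normalized with the
"mu +/- 3 sigma" rule: intensities are clipped to ``[mu - 3s, mu + 3s]``
(statistics over in-ROI voxels only) and mapped linearly onto ``Ng =
2**bits`` discrete grey levels, with ``mu - 3s`` at level 1 and
``mu + 3s`` at level ``Ng``. This absorbs affine intensity changes
(scanner gain/offset), which is why downstream features are invariant to
them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "ROIMask",
    "NormalizationParams",
    "QuantizedROI",
    "load_volume_and_mask",
    "save_volume",
    "normalize_quantize",
]

#: Sentinel level for out-of-ROI voxels in a quantized volume.
OUTSIDE = 0


@dataclass
class Volume:
    """A 3D grey-scale image with optional per-axis spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class ROIMask:
    """Binary mask with the same grid as its volume; nonzero = in-ROI."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask) != 0
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.mask.shape}")
        if not self.mask.any():
            raise ValueError("empty ROI: mask selects no voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class NormalizationParams:
    """ROI grey-level statistics and quantization depth.

    ``mu`` and ``sigma`` follow the population (divide-by-N) convention,
    the usual choice for image statistics; ``ddof`` makes the sample
    convention available.
    """

    mu: float
    sigma: float
    bits: int

    def __post_init__(self) -> None:
        if not 4 <= self.bits <= 8:
            raise ValueError(f"bits must be in [4, 8], got {self.bits}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def n_levels(self) -> int:
        return 2 ** self.bits


@dataclass
class QuantizedROI:
    """ROI voxels mapped to integer grey levels in ``[1, Ng]``.

    ``levels`` has the sentinel 0 outside the ROI; all statistics are
    computed over in-ROI voxels only.
    """

    levels: np.ndarray
    mask: np.ndarray
    params: NormalizationParams

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("empty ROI")
        if inside.min() < 1 or inside.max() > self.params.n_levels:
            raise ValueError("in-ROI levels must lie in [1, Ng]")

    @property
    def roi_levels(self) -> np.ndarray:
        """The in-ROI levels as a flat array."""
        return self.levels[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def load_volume_and_mask(volume_path, mask_path) -> tuple[Volume, ROIMask]:
    """Read a NIfTI volume and its binary ROI mask.

    The mask grid must match the volume grid exactly; any nonzero mask
    value marks an in-ROI voxel.
    """
    vol_img = nib.load(str(volume_path))
    mask_img = nib.load(str(mask_path))
    voxels = np.asarray(vol_img.dataobj, dtype=float)
    mask = np.asarray(mask_img.dataobj)
    if voxels.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: volume {voxels.shape} vs mask {mask.shape}"
        )
    spacing = tuple(float(z) for z in vol_img.header.get_zooms()[:3])
    return Volume(voxels, spacing=spacing), ROIMask(mask)


def save_volume(path, volume: Volume | np.ndarray) -> None:
    """Write a volume (or raw 3D array) as NIfTI with identity affine."""
    data = volume.voxels if isinstance(volume, Volume) else np.asarray(volume)
    affine = np.eye(4)
    if isinstance(volume, Volume) and volume.spacing is not None:
        affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def normalize_quantize(
    volume: Volume, mask: ROIMask, bits: int = 6, ddof: int = 0
) -> QuantizedROI:
    """Clip ROI intensities to ``mu +/- 3 sigma`` and quantize to ``2**bits`` levels.

    The mapping is ``level = 1 + floor((clip(x) - (mu-3s)) / (6s) * (Ng-1)
    + 0.5)``: monotone, symmetric, and exact at both endpoints
    (``mu - 3s`` -> 1, ``mu + 3s`` -> ``Ng``). A constant ROI
    (``sigma = 0``) maps every voxel to the mid-scale level with a
    warning rather than dividing by zero.
    """
    if volume.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {volume.shape} vs mask {mask.shape}")
    inside = volume.voxels[mask.mask]
    mu = float(inside.mean())
    sigma = float(inside.std(ddof=ddof))
    params = NormalizationParams(mu=mu, sigma=sigma, bits=bits)
    ng = params.n_levels
    levels = np.zeros(volume.shape, dtype=np.int64)
    if sigma == 0.0:
        warnings.warn("constant ROI (sigma = 0): all voxels map to mid-scale level")
        levels[mask.mask] = (ng + 1) // 2
        return QuantizedROI(levels=levels, mask=mask.mask, params=params)
    lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
    clipped = np.clip(inside, lo, hi)
    # floor(t + 0.5) rounds half-up, keeping the map monotone and endpoint-exact
    lv = 1 + np.floor((clipped - lo) / (hi - lo) * (ng - 1) + 0.5).astype(np.int64)
    levels[mask.mask] = np.clip(lv, 1, ng)
    return QuantizedROI(levels=levels, mask=mask.mask, params=params)
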