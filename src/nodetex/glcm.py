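"""Grey-level co-occurrence matrices and Haralick features.

GLCMs are built in-plane at one of four directions (H, V, Z = 45
degrees, N = 135 degrees) and an integer inter-pixel distance; counts
are accumulated per axial slice, restricted to voxel pairs whose both
ends are in-ROI, and pooled over all slices of the 3D ROI before
normalization. With symmetric accumulation (the default, as in most
texture packages) each ordered pair is counted in both orders.

Entropies use the natural logarithm by default with the ``0 log 0 := 0``
convention; the base is configurable because texture tools disagree on
it. ``DifVarnc`` is the variance of the grey-level difference
distribution ``p_{x-y}`` about its own mean — the other common reading
(dispersion about zero) can be had from ``Contrast``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .names import DIRECTIONS, FeatureKey
from .volume_io import NormalizationParams, QuantizedROI, ROIMask, Volume

__all__ = [
    "GLCMConfig",
    "GLCM",
    "DegenerateROIError",
    "compute_glcm",
    "glcm_features",
    "feature_map",
    "GLCM_FEATURE_NAMES",
]

GLCM_FEATURE_NAMES = (
    "AngScMom",
    "Contrast",
    "Correlat",
    "SumOfSqs",
    "InvDfMom",
    "SumAverg",
    "SumVarnc",
    "SumEntrp",
    "Entropy",
    "DifVarnc",
    "DifEntrp",
)


class DegenerateROIError(ValueError):
    """No valid in-ROI voxel pair exists at the requested offset."""


@dataclass(frozen=True)
class GLCMConfig:
    """Direction code, inter-pixel distance and accumulation symmetry."""

    direction: str = "H"
    distance: int = 1
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}, got {self.direction!r}")
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")

    @property
    def offset(self) -> tuple[int, int]:
        dr, dc = DIRECTIONS[self.direction]
        return dr * self.distance, dc * self.distance


@dataclass
class GLCM:
    """Normalized co-occurrence probabilities ``p[i-1, j-1] = p(i, j)``."""

    p: np.ndarray
    config: GLCMConfig
    pair_count: int


def _pair_levels(roi: QuantizedROI, offset: tuple[int, int]):
    """Levels of all in-ROI ordered pairs at ``offset``, pooled over slices."""
    dr, dc = offset
    nrow, ncol, _ = roi.levels.shape
    r0, r1 = max(0, -dr), min(nrow, nrow - dr)
    c0, c1 = max(0, -dc), min(ncol, ncol - dc)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    a_mask = roi.mask[r0:r1, c0:c1, :]
    b_mask = roi.mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc, :]
    valid = a_mask & b_mask
    a = roi.levels[r0:r1, c0:c1, :][valid]
    b = roi.levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc, :][valid]
    return a, b


def compute_glcm(roi: QuantizedROI, config: GLCMConfig = GLCMConfig()) -> GLCM:
    """Accumulate the co-occurrence matrix of a quantized ROI.

    Raises :class:`DegenerateROIError` when no voxel pair with both ends
    in-ROI exists at the configured offset.
    """
    ng = roi.params.n_levels
    a, b = _pair_levels(roi, config.offset)
    if a.size == 0:
        raise DegenerateROIError(
            f"degenerate ROI for offset {config.offset}: no valid in-ROI pair"
        )
    counts = np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng).reshape(ng, ng)
    counts = counts.astype(float)
    if config.symmetric:
        counts = counts + counts.T
    pair_count = int(counts.sum())
    return GLCM(p=counts / counts.sum(), config=config, pair_count=pair_count)


def _xlogx(p: np.ndarray, base: float | None) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * (np.log(p[nz]) if base is None else np.log(p[nz]) / np.log(base))
    return out


def glcm_features(glcm: GLCM, log_base: float | None = None) -> dict[str, float | None]:
    """The 11-feature Haralick set from one GLCM.

    ``log_base=None`` means natural log. ``Correlat`` is ``None``
    (missing) when either marginal is degenerate (zero variance), never
    NaN.
    """
    p = glcm.p
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)

    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj

    # difference distribution p_{x-y}(k), k = |i - j| in 0..Ng-1
    k_diff = np.arange(ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(diff), p)
    # sum distribution p_{x+y}(k), k = i + j in 2..2Ng
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, ii + jj - 2, p)

    feats: dict[str, float | None] = {}
    feats["AngScMom"] = float((p ** 2).sum())
    feats["Contrast"] = float((diff ** 2 * p).sum())
    if var_x <= 0 or var_y <= 0:
        feats["Correlat"] = None
    else:
        feats["Correlat"] = float(((ii * jj * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    feats["SumOfSqs"] = float((((ii - mu_x) ** 2) * p).sum())
    feats["InvDfMom"] = float((p / (1.0 + diff ** 2)).sum())
    sum_avg = float(k_sum @ p_sum)
    feats["SumAverg"] = sum_avg
    feats["SumVarnc"] = float(((k_sum - sum_avg) ** 2) @ p_sum)
    feats["SumEntrp"] = float(-_xlogx(p_sum, log_base).sum())
    feats["Entropy"] = float(-_xlogx(p, log_base).sum())
    diff_mean = float(k_diff @ p_diff)
    feats["DifVarnc"] = float(((k_diff - diff_mean) ** 2) @ p_diff)
    feats["DifEntrp"] = float(-_xlogx(p_diff, log_base).sum())
    return feats


def feature_map(
    volume: Volume,
    mask: ROIMask,
    key: FeatureKey,
    window: int = 7,
    log_base: float | None = None,
) -> np.ndarray:
    """Per-pixel GLCM feature map over a sliding in-plane window.

    Every in-ROI pixel carries the value of ``key``'s GLCM feature
    computed from its ``window x window`` in-plane neighbourhood,
    quantized with the *global* ROI mean/sigma so maps are comparable
    across the image. Pixels whose window holds no valid pair, and all
    out-of-ROI pixels, are NaN.
    """
    from .volume_io import normalize_quantize

    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if key.direction is None or key.distance is None or key.feature not in GLCM_FEATURE_NAMES:
        raise ValueError(f"feature map requires a GLCM feature key, got {key}")

    q = normalize_quantize(volume, mask, bits=key.bits if key.bits is not None else 6)
    cfg = GLCMConfig(direction=key.direction, distance=key.distance)
    half = window // 2
    out = np.full(volume.shape, np.nan)
    nrow, ncol, nslc = volume.shape
    for s in range(nslc):
        sl_mask = mask.mask[:, :, s]
        if not sl_mask.any():
            continue
        rows, cols = np.nonzero(sl_mask)
        for r, c in zip(rows, cols):
            r0, r1 = max(0, r - half), min(nrow, r + half + 1)
            c0, c1 = max(0, c - half), min(ncol, c + half + 1)
            win_levels = q.levels[r0:r1, c0:c1, s : s + 1]
            win_mask = q.mask[r0:r1, c0:c1, s : s + 1]
            if not win_mask.any():
                continue
            sub = QuantizedROI(levels=win_levels, mask=win_mask, params=q.params)
            try:
                g = compute_glcm(sub, cfg)
            except DegenerateROIError:
                continue
            val = glcm_features(g, log_base=log_base)[key.feature]
            if val is not None:
                out[r, c, s] = val
    return out
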