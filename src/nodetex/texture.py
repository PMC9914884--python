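"""Run-length, histogram, gradient, autoregressive and wavelet features.

All families operate on a :class:`~nodetex.volume_io.QuantizedROI`
(grey levels 1..Ng, sentinel outside the ROI) and, like the GLCM family,
work slice-wise in-plane with statistics pooled over the slices of the
3D ROI. Missing values — a family that cannot be computed on a given
ROI (too small, zero variance, rank-deficient fit) — are reported as
``None`` in feature dictionaries and become NaN in tabular output; a
failure of one feature never aborts the extraction of the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage, stats

from .glcm import (
    GLCM_FEATURE_NAMES,
    DegenerateROIError,
    GLCMConfig,
    compute_glcm,
    glcm_features,
)
from .names import DIRECTIONS, FeatureKey
from .volume_io import QuantizedROI

__all__ = [
    "FeatureGrid",
    "FeatureVector",
    "run_length_features",
    "histogram_features",
    "gradient_features",
    "ar_model_params",
    "wavelet_features",
    "extract_all",
    "features_table",
    "RUN_LENGTH_FEATURE_NAMES",
    "HISTOGRAM_FEATURE_NAMES",
    "GRADIENT_FEATURE_NAMES",
    "AR_FEATURE_NAMES",
]

RUN_LENGTH_FEATURE_NAMES = ("ShrtREmp", "LngREmph", "GLevNonU", "RLNonUni", "Fraction")
HISTOGRAM_FEATURE_NAMES = (
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Perc01",
    "Perc10",
    "Perc50",
    "Perc90",
    "Perc99",
)
GRADIENT_FEATURE_NAMES = ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros")
AR_FEATURE_NAMES = ("Teta1", "Teta2", "Teta3", "Teta4", "SigmaAR")
WAVELET_SUBBANDS = ("LL", "HL", "LH", "HH")  # first letter: row axis, second: column axis


# ---------------------------------------------------------------------------
# run-length


def _iter_lines(levels2d: np.ndarray, mask2d: np.ndarray, direction: str):
    """Yield (levels, mask) 1D lines of a slice along a direction code."""
    if direction == "H":
        for r in range(levels2d.shape[0]):
            yield levels2d[r, :], mask2d[r, :]
    elif direction == "V":
        for c in range(levels2d.shape[1]):
            yield levels2d[:, c], mask2d[:, c]
    else:
        # Z = 45 deg: anti-diagonals; N = 135 deg: main diagonals
        a = np.fliplr(levels2d) if direction == "Z" else levels2d
        m = np.fliplr(mask2d) if direction == "Z" else mask2d
        nrow, ncol = a.shape
        for off in range(-(nrow - 1), ncol):
            yield np.diagonal(a, offset=off), np.diagonal(m, offset=off)


def _runs_in_line(levels: np.ndarray, mask: np.ndarray):
    """Maximal runs of equal level among contiguous in-ROI cells."""
    runs = []
    n = len(levels)
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i + 1
        while j < n and mask[j] and levels[j] == levels[i]:
            j += 1
        runs.append((int(levels[i]), j - i))
        i = j
    return runs


def run_length_matrix(roi: QuantizedROI, direction: str) -> np.ndarray:
    """R[g-1, r-1] = number of maximal runs of level g and length r, pooled over slices."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")
    ng = roi.params.n_levels
    max_len = max(roi.levels.shape[0], roi.levels.shape[1])
    rlm = np.zeros((ng, max_len), dtype=np.int64)
    for s in range(roi.levels.shape[2]):
        m = roi.mask[:, :, s]
        if not m.any():
            continue
        for line, lm in _iter_lines(roi.levels[:, :, s], m, direction):
            for g, r in _runs_in_line(line, lm):
                rlm[g - 1, r - 1] += 1
    return rlm


def run_length_features(roi: QuantizedROI, direction: str) -> dict[str, float | None]:
    """Five-feature run-length set for one direction.

    ``RLNonUni`` and ``GLevNonU`` are the run-length and grey-level
    non-uniformities ``sum_r (sum_g R)^2 / N`` and ``sum_g (sum_r R)^2 /
    N``; ``Fraction`` is the run-percentage ``N_runs / N_voxels``.
    """
    rlm = run_length_matrix(roi, direction)
    n_runs = int(rlm.sum())
    if n_runs == 0:
        return {name: None for name in RUN_LENGTH_FEATURE_NAMES}
    r = np.arange(1, rlm.shape[1] + 1, dtype=float)
    by_len = rlm.sum(axis=0).astype(float)
    by_lev = rlm.sum(axis=1).astype(float)
    return {
        "ShrtREmp": float((by_len / r ** 2).sum() / n_runs),
        "LngREmph": float((by_len * r ** 2).sum() / n_runs),
        "GLevNonU": float((by_lev ** 2).sum() / n_runs),
        "RLNonUni": float((by_len ** 2).sum() / n_runs),
        "Fraction": float(n_runs / roi.n_voxels),
    }


# ---------------------------------------------------------------------------
# histogram


def histogram_features(roi: QuantizedROI) -> dict[str, float | None]:
    """First-order statistics of the in-ROI level histogram.

    Variance is the population variance; skewness and excess kurtosis
    are missing for a constant ROI. Percentiles use linear
    interpolation.
    """
    x = roi.roi_levels.astype(float)
    var = float(x.var())
    feats: dict[str, float | None] = {
        "Mean": float(x.mean()),
        "Variance": var,
    }
    if var > 0:
        feats["Skewness"] = float(stats.skew(x))
        feats["Kurtosis"] = float(stats.kurtosis(x))  # excess (Fisher) kurtosis
    else:
        feats["Skewness"] = None
        feats["Kurtosis"] = None
    for q, name in ((1, "Perc01"), (10, "Perc10"), (50, "Perc50"), (90, "Perc90"), (99, "Perc99")):
        feats[name] = float(np.percentile(x, q))
    return feats


# ---------------------------------------------------------------------------
# absolute gradient


def gradient_features(roi: QuantizedROI) -> dict[str, float | None]:
    """Absolute-gradient statistics over interior ROI voxels.

    The gradient is the in-plane central difference
    ``((x_{r,c+1}-x_{r,c-1})/2, (x_{r+1,c}-x_{r-1,c})/2)`` evaluated at
    voxels whose four in-plane neighbours are all in-ROI; its magnitude
    is summarized by mean, population variance, skewness, excess
    kurtosis and the fraction of nonzero magnitudes.
    """
    mags = []
    for s in range(roi.levels.shape[2]):
        lv = roi.levels[:, :, s].astype(float)
        m = roi.mask[:, :, s]
        interior = (
            m
            & np.roll(m, 1, axis=0)
            & np.roll(m, -1, axis=0)
            & np.roll(m, 1, axis=1)
            & np.roll(m, -1, axis=1)
        )
        interior[0, :] = interior[-1, :] = False
        interior[:, 0] = interior[:, -1] = False
        if not interior.any():
            continue
        gx = (np.roll(lv, -1, axis=1) - np.roll(lv, 1, axis=1)) / 2.0
        gy = (np.roll(lv, -1, axis=0) - np.roll(lv, 1, axis=0)) / 2.0
        mags.append(np.hypot(gx, gy)[interior])
    if not mags:
        return {name: None for name in GRADIENT_FEATURE_NAMES}
    g = np.concatenate(mags)
    var = float(g.var())
    feats: dict[str, float | None] = {
        "GrMean": float(g.mean()),
        "GrVariance": var,
        "GrSkewness": float(stats.skew(g)) if var > 0 else None,
        "GrKurtosis": float(stats.kurtosis(g)) if var > 0 else None,
        "GrNonZeros": float((g > 0).mean()),
    }
    return feats


# ---------------------------------------------------------------------------
# autoregressive model


def ar_model_params(roi: QuantizedROI, min_voxels: int = 20) -> dict[str, float | None]:
    """Causal 2D autoregressive model parameters Teta1..Teta4 and SigmaAR.

    Fits ``x(r, c) ~ t1*x(r, c-1) + t2*x(r-1, c-1) + t3*x(r-1, c) +
    t4*x(r-1, c+1)`` (west, northwest, north, northeast neighbours) by
    least squares on mean-centred levels, pooled over slices; SigmaAR is
    the residual standard deviation. Missing when fewer than
    ``min_voxels`` voxels have all four causal neighbours in-ROI or when
    the design is rank deficient.
    """
    missing = {name: None for name in AR_FEATURE_NAMES}
    rows_y = []
    rows_X = []
    center = float(roi.roi_levels.mean())
    nrow, ncol, nslc = roi.levels.shape
    for s in range(nslc):
        m = roi.mask[:, :, s]
        if not m.any():
            continue
        lv = roi.levels[:, :, s].astype(float) - center
        usable = m.copy()
        usable[0, :] = False
        usable[:, 0] = False
        usable[:, -1] = False
        usable &= (
            np.roll(m, 1, axis=1)  # west
            & np.roll(np.roll(m, 1, axis=0), 1, axis=1)  # northwest
            & np.roll(m, 1, axis=0)  # north
            & np.roll(np.roll(m, 1, axis=0), -1, axis=1)  # northeast
        )
        if not usable.any():
            continue
        rows_y.append(lv[usable])
        w = np.roll(lv, 1, axis=1)[usable]
        nw = np.roll(np.roll(lv, 1, axis=0), 1, axis=1)[usable]
        n = np.roll(lv, 1, axis=0)[usable]
        ne = np.roll(np.roll(lv, 1, axis=0), -1, axis=1)[usable]
        rows_X.append(np.column_stack([w, nw, n, ne]))
    if not rows_y:
        return missing
    y = np.concatenate(rows_y)
    X = np.vstack(rows_X)
    if y.size < min_voxels:
        return missing
    if np.linalg.matrix_rank(X) == 0:
        # fully degenerate design (constant ROI); partially collinear
        # neighbourhoods get the minimum-norm least-squares solution
        return missing
    theta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    out: dict[str, float | None] = {f"Teta{i+1}": float(theta[i]) for i in range(4)}
    out["SigmaAR"] = float(resid.std())
    return out


# ---------------------------------------------------------------------------
# wavelet


def wavelet_energy_names(scales: int) -> list[str]:
    return [f"WavEn{band}{s}" for s in range(1, scales + 1) for band in WAVELET_SUBBANDS]


def wavelet_features(roi: QuantizedROI, scales: int = 5) -> dict[str, float | None]:
    """Haar subband energies of the ROI, per scale.

    Each slice's mask bounding box is decomposed with the 2D Haar
    transform; out-of-ROI voxels inside the box are filled with the
    slice ROI mean to limit edge artefacts. The energy of a subband is
    the mean squared coefficient over coefficients whose spatial support
    intersects the ROI, pooled over slices. Subband names ``XY`` use X
    for the row-axis filter and Y for the column-axis filter (low/high),
    so period-2 stripes along columns load on ``LH`` at scale 1. Scales
    larger than the bounding box allows are missing.
    """
    names = wavelet_energy_names(scales)
    sums = {name: 0.0 for name in names}
    counts = {name: 0 for name in names}
    # map our (row-filter, col-filter) names onto pywt's (cA, (cH, cV, cD))
    # where cH is high-pass along rows and cV high-pass along columns
    band_of = {"LL": "a", "HL": "h", "LH": "v", "HH": "d"}
    for s in range(roi.levels.shape[2]):
        m = roi.mask[:, :, s]
        if not m.any():
            continue
        rows = np.nonzero(m.any(axis=1))[0]
        cols = np.nonzero(m.any(axis=0))[0]
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
        patch = roi.levels[r0:r1, c0:c1, s].astype(float)
        pm = m[r0:r1, c0:c1]
        patch = np.where(pm, patch, patch[pm].mean())
        cur = patch
        cur_mask = pm
        bbox_min = min(pm.shape)
        for scale in range(1, scales + 1):
            # a scale-s subband needs a bounding box of at least 2**s voxels
            if bbox_min < 2 ** scale or min(cur.shape) < 2:
                break
            cA, (cH, cV, cD) = pywt.dwt2(cur, "haar")
            # a coefficient supports the ROI if any voxel of its 2x2 block is in-ROI
            mr, mc = cur_mask.shape
            pad = np.zeros((mr + mr % 2, mc + mc % 2), dtype=bool)
            pad[:mr, :mc] = cur_mask
            block = pad.reshape(pad.shape[0] // 2, 2, pad.shape[1] // 2, 2).any(axis=(1, 3))
            for band, coef in (("LL", cA), ("HL", cH), ("LH", cV), ("HH", cD)):
                sel = coef[block]
                if sel.size:
                    sums[f"WavEn{band}{scale}"] += float((sel ** 2).sum())
                    counts[f"WavEn{band}{scale}"] += sel.size
            cur = cA
            cur_mask = block
    return {
        name: (sums[name] / counts[name] if counts[name] > 0 else None) for name in names
    }


# ---------------------------------------------------------------------------
# full extraction grid


@dataclass(frozen=True)
class FeatureGrid:
    """The extraction grid: which configurations of each family to compute."""

    directions: tuple[str, ...] = ("H", "V", "Z", "N")
    distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    glcm_symmetric: bool = True
    log_base: float | None = None  # natural log
    wavelet_scales: int = 5
    include_ar: bool = True

    def n_keys(self) -> int:
        n = len(self.directions) * len(self.distances) * len(GLCM_FEATURE_NAMES)
        n += len(self.directions) * len(RUN_LENGTH_FEATURE_NAMES)
        n += len(HISTOGRAM_FEATURE_NAMES) + len(GRADIENT_FEATURE_NAMES)
        n += len(AR_FEATURE_NAMES) if self.include_ar else 0
        n += 4 * self.wavelet_scales
        return n


@dataclass
class FeatureVector:
    """All texture features of one lesion, keyed by :class:`FeatureKey`."""

    lesion_id: str
    values: dict[FeatureKey, float | None]

    @property
    def n_missing(self) -> int:
        return sum(1 for v in self.values.values() if v is None)

    def as_named_dict(self) -> dict[str, float]:
        """Serialized-name -> value mapping with NaN for missing."""
        return {str(k): (np.nan if v is None else v) for k, v in self.values.items()}


def extract_all(
    roi: QuantizedROI, grid: FeatureGrid = FeatureGrid(), lesion_id: str = "lesion"
) -> FeatureVector:
    """Compute every feature of the grid on one quantized ROI.

    Individual family failures (degenerate offsets, too-small ROIs) are
    recorded as missing values; the batch never aborts.
    """
    bits = roi.params.bits
    values: dict[FeatureKey, float | None] = {}

    for direction in grid.directions:
        for distance in grid.distances:
            cfg = GLCMConfig(direction=direction, distance=distance, symmetric=grid.glcm_symmetric)
            try:
                feats = glcm_features(compute_glcm(roi, cfg), log_base=grid.log_base)
            except DegenerateROIError:
                feats = {name: None for name in GLCM_FEATURE_NAMES}
            for name in GLCM_FEATURE_NAMES:
                key = FeatureKey(feature=name, direction=direction, distance=distance, bits=bits)
                values[key] = feats[name]

    for direction in grid.directions:
        feats = run_length_features(roi, direction)
        for name in RUN_LENGTH_FEATURE_NAMES:
            values[FeatureKey(feature=name, direction=direction, bits=bits)] = feats[name]

    for name, v in histogram_features(roi).items():
        values[FeatureKey(feature=name, bits=bits)] = v
    for name, v in gradient_features(roi).items():
        values[FeatureKey(feature=name, bits=bits)] = v
    if grid.include_ar:
        for name, v in ar_model_params(roi).items():
            values[FeatureKey(feature=name)] = v
    for name, v in wavelet_features(roi, scales=grid.wavelet_scales).items():
        values[FeatureKey(feature=name, bits=bits)] = v
    return FeatureVector(lesion_id=lesion_id, values=values)


def features_table(vectors, labels=None):
    """Stack FeatureVectors into a DataFrame (one row per lesion).

    Columns are serialized feature names; missing values are NaN. When
    ``labels`` is given (mapping or sequence aligned with ``vectors``) a
    ``class`` column is prepended.
    """
    import pandas as pd

    rows = {v.lesion_id: v.as_named_dict() for v in vectors}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "lesion_id"
    if labels is not None:
        if isinstance(labels, dict):
            lab = [labels[v.lesion_id] for v in vectors]
        else:
            lab = list(labels)
        df.insert(0, "class", lab)
    return df
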